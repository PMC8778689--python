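"""Independent oracles used by the test suite.

These deliberately avoid the package's own algorithms: ORFs by direct
enumeration of every ATG, alignment scores by exhaustive enumeration of all
global alignments. They are slow and only suitable for small inputs.
"""

import itertools

from viroscreen import annotate
from viroscreen.seqio import reverse_complement

CODE_TABLES = {
    code: annotate._code_tables(code) for code in ("standard", "mold_mitochondrial")
}


def brute_force_orfs(seq: str, code: str, min_aa: int):
    """Enumerate every ATG on both strands; scan to the next in-frame stop."""
    fwd, stops = CODE_TABLES[code]
    found = set()
    L = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else reverse_complement(seq)
        for i in range(L - 2):
            if s[i : i + 3] != "ATG":
                continue
            j = i + 3
            stop_found = False
            while j + 3 <= L:
                if s[j : j + 3] in stops:
                    stop_found = True
                    break
                j += 3
            if not stop_found:
                continue
            n_aa = (j - i) // 3
            if n_aa < min_aa:
                continue
            if strand == "+":
                start, end = i + 1, j + 3
            else:
                start, end = L - (j + 3) + 1, L - i
            protein = "".join(fwd.get(s[q : q + 3], "X") for q in range(i, j, 3))
            found.add((start, end, strand, protein))
    return found


def enumerate_alignments(a, b):
    """All global alignments of two short strings, as aligned-string pairs."""
    results = []

    def rec(i, j, xa, xb):
        if i == len(a) and j == len(b):
            results.append(("".join(xa), "".join(xb)))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, xa + [a[i]], xb + [b[j]])
        if i < len(a):
            rec(i + 1, j, xa + [a[i]], xb + ["-"])
        if j < len(b):
            rec(i, j + 1, xa + ["-"], xb + [b[j]])

    rec(0, 0, [], [])
    return results


def score_alignment(xa, xb, scoring):
    """Substitution columns plus per-run affine gap costs (open + (g-1)*extend)."""
    total = 0.0
    for run_is_gap, group in itertools.groupby(zip(xa, xb), key=lambda col: "-" in col):
        cols = list(group)
        if run_is_gap:
            for _side, sub in itertools.groupby(cols, key=lambda col: col.index("-")):
                g = len(list(sub))
                total += scoring.gap_open + (g - 1) * scoring.gap_extend
        else:
            for x, y in cols:
                total += scoring.match if x == y else scoring.mismatch
    return total


def oracle_best_score(a, b, scoring):
    return max(score_alignment(xa, xb, scoring) for xa, xb in enumerate_alignments(a, b))
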