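"""ICTV demarcation thresholds as a rule engine, plus infection summaries.

Species and genus demarcation for the virus groups this pipeline encounters
reduce to percent-identity thresholds on a marker protein (RdRp or CP):

* genus *Narnavirus* — 50% RdRp aa identity separates species;
* genus *Mitovirus* — 40% RdRp aa identity separates species;
* family *Totiviridae* — species share >= 50% aa identity (plus host
  specificity, which is carried as metadata only — it is not computable
  from sequence and never decides a verdict automatically);
* family *Partitiviridae* — species thresholds 80% (CP aa) and 90%
  (RdRp aa); genera are separated below 24% RdRp aa identity.

The rules ship as editable data (``data/demarcation_rules.tsv``); verdicts
are *candidate* labels citing the rule applied, never authoritative
taxonomy. "Below" relations are strict (<), matching how the thresholds are
stated.

The module also summarises per-strain infection tables (virus detections
with real-time PCR threshold cycles): infected strains, mixed infections
(two or more distinct virus columns detected — a helper virus plus its
satellite counts as mixed), and per-virus strain counts. A transcription of
the study's detection table for 24 oenological yeast strains ships as
``data/oeno_yeast_infections.tsv``.
"""

from __future__ import annotations

import csv
import io
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

from .seqio import InfectionTableRow, read_infection_table

__all__ = [
    "DemarcationRule",
    "CandidateStats",
    "Classification",
    "InfectionSummary",
    "default_rules",
    "load_rules",
    "classify",
    "build_summary",
    "load_infection_fixture",
]

VERDICTS = (
    "variant_of_known_species",
    "new_species_candidate",
    "new_genus_candidate",
    "unresolved",
)

# genus names folded onto the taxon scope whose rules govern them
_SCOPE_ALIASES = {"cryspovirus": "partitivirus"}


@dataclass(frozen=True)
class DemarcationRule:
    taxon_scope: str   # genus or family name, lowercase
    marker: str        # "RdRp_aa" | "CP_aa" | "nt"
    threshold: float   # percent identity
    relation: str      # "below_means_new_species" | "below_means_new_genus"
    source_note: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 100:
            raise ValueError("threshold must be in (0, 100)")
        if self.relation not in ("below_means_new_species", "below_means_new_genus"):
            raise ValueError(f"unknown relation {self.relation!r}")


def load_rules(path_or_text) -> list[DemarcationRule]:
    """Load rules from a TSV with columns taxon_scope, marker, threshold, relation, source_note."""
    if hasattr(path_or_text, "read"):
        handle = path_or_text
    else:
        handle = open(path_or_text, "rt")
    with handle:
        reader = csv.DictReader(handle, delimiter="\t")
        return [
            DemarcationRule(
                taxon_scope=row["taxon_scope"].strip().lower(),
                marker=row["marker"].strip(),
                threshold=float(row["threshold"]),
                relation=row["relation"].strip(),
                source_note=row.get("source_note", "").strip(),
            )
            for row in reader
        ]


def default_rules() -> list[DemarcationRule]:
    """The shipped rule set (see module docstring)."""
    text = resources.files("viroscreen.data").joinpath("demarcation_rules.tsv").read_text()
    return load_rules(io.StringIO(text))


@dataclass
class CandidateStats:
    """Identity evidence for one candidate virus against reference sequences."""

    candidate_id: str
    genus_hypothesis: str
    best_hits: list = field(default_factory=list)  # (reference_id, marker, pct_identity)
    host_note: str = ""  # metadata only; reported, never decides a verdict

    def __post_init__(self) -> None:
        for ref, marker, pct in self.best_hits:
            if not 0 <= pct <= 100:
                raise ValueError(f"{self.candidate_id} vs {ref} ({marker}): identity outside [0,100]")

    def best_for_marker(self, marker: str):
        hits = [(ref, pct) for ref, m, pct in self.best_hits if m == marker]
        if not hits:
            return None
        return max(hits, key=lambda t: t[1])


@dataclass
class Classification:
    verdict: str
    rules_applied: list = field(default_factory=list)
    best_reference: Optional[str] = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


def classify(stats: CandidateStats, rules: Optional[list[DemarcationRule]] = None) -> Classification:
    """Apply the demarcation rules for the candidate's genus hypothesis.

    Any marker identity at or above its species threshold makes the
    candidate a variant of the known species; otherwise, if a genus-level
    rule exists and the best identity for its marker falls strictly below
    the genus threshold, the candidate may represent a new genus; otherwise
    it is a new-species candidate. With no applicable rules the verdict is
    unresolved.
    """
    if rules is None:
        rules = default_rules()
    scope = stats.genus_hypothesis.strip().lower()
    scope = _SCOPE_ALIASES.get(scope, scope)
    applicable = [r for r in rules if r.taxon_scope == scope]
    if not applicable:
        return Classification(
            verdict="unresolved",
            note=f"no demarcation rules for taxon scope {scope!r}",
        )
    species_rules = [r for r in applicable if r.relation == "below_means_new_species"]
    genus_rules = [r for r in applicable if r.relation == "below_means_new_genus"]

    evaluated = []
    for rule in species_rules:
        best = stats.best_for_marker(rule.marker)
        if best is None:
            continue
        ref, pct = best
        evaluated.append((rule, ref, pct))
        if pct >= rule.threshold:
            return Classification(
                verdict="variant_of_known_species",
                rules_applied=[rule],
                best_reference=ref,
                note=f"{rule.marker} identity {pct:g}% >= {rule.threshold:g}% ({rule.taxon_scope})",
            )
    if not evaluated:
        return Classification(
            verdict="unresolved",
            note=f"no identity evidence for the markers the {scope!r} rules use",
        )
    for rule in genus_rules:
        best = stats.best_for_marker(rule.marker)
        if best is not None and best[1] < rule.threshold:
            return Classification(
                verdict="new_genus_candidate",
                rules_applied=[rule],
                best_reference=best[0],
                note=f"{rule.marker} identity {best[1]:g}% < {rule.threshold:g}% ({rule.taxon_scope} genus rule)",
            )
    rules_used = [r for r, _, _ in evaluated]
    best_rule, best_ref, best_pct = max(evaluated, key=lambda t: t[2])
    note = "; ".join(
        f"{r.marker} {pct:g}% < {r.threshold:g}%" for r, _, pct in evaluated
    )
    if stats.host_note:
        note += f" [host note: {stats.host_note}]"
    return Classification(
        verdict="new_species_candidate",
        rules_applied=rules_used,
        best_reference=best_ref,
        note=note,
    )


@dataclass
class InfectionSummary:
    n_strains: int
    n_infected: int
    n_mixed: int
    per_virus_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.n_mixed <= self.n_infected <= self.n_strains:
            raise ValueError("expected n_mixed <= n_infected <= n_strains")


def build_summary(table: Iterable[InfectionTableRow], total_strains: int = 24) -> InfectionSummary:
    """Summarise a detection table; uninfected strains may be absent from it."""
    rows = list(table)
    strains = [r.strain for r in rows]
    if len(set(strains)) != len(strains):
        dup = [s for s, n in Counter(strains).items() if n > 1]
        raise ValueError(f"duplicate strain row(s): {dup}")
    if total_strains < len(rows):
        raise ValueError("total_strains smaller than the number of table rows")
    n_infected = sum(1 for r in rows if r.detections)
    n_mixed = sum(1 for r in rows if len(r.detections) >= 2)
    per_virus: Counter = Counter()
    for r in rows:
        per_virus.update(r.detections.keys())
    return InfectionSummary(
        n_strains=total_strains,
        n_infected=n_infected,
        n_mixed=n_mixed,
        per_virus_counts=dict(per_virus),
    )


def load_infection_fixture() -> list[InfectionTableRow]:
    """The shipped 24-strain oenological yeast detection table (infected rows)."""
    path = resources.files("viroscreen.data").joinpath("oeno_yeast_infections.tsv")
    with resources.as_file(path) as p:
        return read_infection_table(p)
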