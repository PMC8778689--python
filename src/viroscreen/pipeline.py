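"""End-to-end convenience: synthetic virome -> strand mapping -> ORFan screen."""

from __future__ import annotations

from dataclasses import dataclass, field

from .mapping import StrandCounts, build_index, count_strands
from .orfan import OrfanParams, OrfanVerdict, screen
from .seqio import HitRecord, ReadRecord, SequenceRecord
from .synthetic import SyntheticConfig, TruthManifest, emit_hit_table, generate_virome, simulate_reads

__all__ = ["PipelineResult", "run_orfan_pipeline"]


@dataclass
class PipelineResult:
    contigs: list[SequenceRecord]
    truth: TruthManifest
    reads: list[ReadRecord]
    hits: list[HitRecord]
    counts: StrandCounts
    verdicts: list[OrfanVerdict]
    params: OrfanParams = field(default_factory=OrfanParams)

    @property
    def passed_ids(self) -> list[str]:
        return [v.contig_id for v in self.verdicts if v.passed]

    @property
    def planted_orfan_ids(self) -> list[str]:
        return sorted(
            cid for cid, t in self.truth.contigs.items() if t.kind == "orfan_like"
        )


def run_orfan_pipeline(config: SyntheticConfig,
                       params: OrfanParams = OrfanParams(),
                       k: int = 21, min_frac: float = 0.5) -> PipelineResult:
    """Generate a virome, map reads with orientation, run the ORFan screen."""
    contigs, truth = generate_virome(config)
    reads = simulate_reads(contigs, truth, config)
    hits = emit_hit_table(truth)
    index = build_index(contigs, k=k)
    counts = count_strands(index, reads, min_frac=min_frac)
    verdicts = screen(contigs, hits, counts, params)
    return PipelineResult(
        contigs=contigs, truth=truth, reads=reads, hits=hits,
        counts=counts, verdicts=verdicts, params=params,
    )
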