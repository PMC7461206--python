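"""Subgenome retention and synteny percentages.

Retention of subgenome s is 100 * count(s) / (3 * reference_gene_count):
each of the three post-triplication subgenomes could in principle carry one
copy of every reference-family gene, so the denominator is the triplicated
reference family.  The per-copy variant (100 * count / reference count) is
also reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._util import round_half_up

SUBGENOMES = ("LF", "MF1", "MF2")


class SubgenomeError(ValueError):
    pass


@dataclass
class SubgenomeMap:
    assignments: dict[str, str]       # gene_id -> LF | MF1 | MF2
    reference_gene_count: int

    def __post_init__(self):
        if self.reference_gene_count <= 0:
            raise SubgenomeError("reference_gene_count must be positive")
        bad = {s for s in self.assignments.values() if s not in SUBGENOMES}
        if bad:
            raise SubgenomeError(f"unknown subgenome labels {sorted(bad)}")

    def counts(self) -> dict[str, int]:
        out = {s: 0 for s in SUBGENOMES}
        for s in self.assignments.values():
            out[s] += 1
        return out


@dataclass
class RetentionReport:
    counts: dict[str, int]
    total_mapped: int
    retention_pct: dict[str, float]          # triplicate-denominator convention
    retention_pct_per_copy: dict[str, float] = field(default_factory=dict)


def retention_proportions(subgenome_map: SubgenomeMap) -> RetentionReport:
    counts = subgenome_map.counts()
    ref = subgenome_map.reference_gene_count
    pct = {s: round_half_up(100.0 * c / (3 * ref), 1) for s, c in counts.items()}
    pct_per_copy = {s: round_half_up(100.0 * c / ref, 1) for s, c in counts.items()}
    return RetentionReport(counts, sum(counts.values()), pct, pct_per_copy)


def synteny_percentages(reference_hits: int, reference_total: int,
                        query_mapped: int, query_total: int) -> tuple[float, float]:
    """(reference syntenic %, query mappable %), half-up to one decimal."""
    if reference_total <= 0 or query_total <= 0:
        raise SubgenomeError("totals must be positive")
    if reference_hits > reference_total or query_mapped > query_total:
        raise SubgenomeError("hits exceed totals")
    return (round_half_up(100.0 * reference_hits / reference_total, 1),
            round_half_up(100.0 * query_mapped / query_total, 1))
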