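"""Exon/intron architecture: intron phases and chromosome distribution.

Intron phase is computed from coding (CDS) exon lengths only: the phase of
intron k is the cumulative coding length of exons 1..k modulo 3 (0 =
between codons, 1 = after the first codon nucleotide, 2 = after the
second).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .formats_io import GeneModel


@dataclass
class IntronPhaseProfile:
    gene_id: str
    exon_count: int
    phases: list[int]
    frame_warning: bool = False  # total coding length not divisible by 3


@dataclass
class ChromosomeSummary:
    per_chromosome: dict[str, int] = field(default_factory=dict)
    scaffold_genes: int = 0
    chromosome_genes: int = 0
    total_genes: int = 0
    plus_strand: int = 0
    minus_strand: int = 0


def intron_phases(model: GeneModel) -> IntronPhaseProfile:
    """Phases of the introns of one gene, from CDS exons in transcription
    order.  A coding length not divisible by 3 is recorded as a warning but
    phases are still returned."""
    lengths = model.exon_lengths
    total = sum(lengths)
    frame_warning = total % 3 != 0
    if frame_warning:
        warnings.warn(f"{model.gene_id}: coding length {total} not divisible by 3",
                      stacklevel=2)
    phases = []
    cum = 0
    for length in lengths[:-1]:
        cum += length
        phases.append(cum % 3)
    return IntronPhaseProfile(model.gene_id, len(lengths), phases, frame_warning)


def chromosome_summary(models: list[GeneModel],
                       chromosome_prefix: str = "C") -> ChromosomeSummary:
    """Per-chromosome and per-strand counts.  Sequences whose name starts
    with ``chromosome_prefix`` count as named chromosomes, everything else
    as scaffolds."""
    summary = ChromosomeSummary()
    for m in models:
        summary.total_genes += 1
        if m.chromosome.startswith(chromosome_prefix):
            summary.per_chromosome[m.chromosome] = \
                summary.per_chromosome.get(m.chromosome, 0) + 1
            summary.chromosome_genes += 1
            if m.strand == "+":
                summary.plus_strand += 1
            else:
                summary.minus_strand += 1
        else:
            summary.scaffold_genes += 1
    summary.per_chromosome = dict(sorted(summary.per_chromosome.items()))
    return summary
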