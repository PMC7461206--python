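"""Promoter scanning for named cis-regulatory elements given as IUPAC
consensus strings, on both strands, with promoter-level summaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class CisElementError(ValueError):
    pass


@dataclass(frozen=True)
class MotifDefinition:
    name: str
    category: str
    consensus: str

    def __post_init__(self):
        bad = set(self.consensus.upper()) - set(IUPAC)
        if not self.consensus or bad:
            raise CisElementError(
                f"{self.name}: invalid IUPAC consensus {self.consensus!r}")


@dataclass(frozen=True)
class MotifHit:
    name: str
    position: int   # 1-based start of the match on the + strand
    strand: str     # "+" or "-"


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def load_motif_dictionary(path: str | Path | None = None) -> list[MotifDefinition]:
    """Load the motif TSV (name, category, consensus); defaults to the
    dictionary shipped with the package."""
    if path is None:
        text = (resources.files("pgfam") / "data" / "cis_element_motifs.tsv").read_text()
    else:
        text = Path(path).read_text()
    motifs = []
    header_seen = False
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if not header_seen:
            if cols[:3] != ["name", "category", "consensus"]:
                raise CisElementError("motif TSV must have name/category/consensus header")
            header_seen = True
            continue
        if len(cols) < 3:
            raise CisElementError(f"bad motif row {line!r}")
        motifs.append(MotifDefinition(cols[0], cols[1], cols[2].upper()))
    names = [m.name for m in motifs]
    if len(names) != len(set(names)):
        raise CisElementError("duplicate motif names")
    return motifs


def _iupac_regex(consensus: str) -> re.Pattern:
    parts = []
    for c in consensus.upper():
        opts = IUPAC[c]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    # lookahead so overlapping matches are all reported
    return re.compile("(?=" + "".join(parts) + ")")


def scan_promoter(promoter_seq: str, motifs: Iterable[MotifDefinition]
                  ) -> list[MotifHit]:
    """Every IUPAC-consistent match of every motif on both strands, with the
    1-based position of the match's leftmost base on the + strand."""
    seq = promoter_seq.upper()
    if set(seq) - set("ACGTN"):
        raise CisElementError("promoter must be over A/C/G/T/N")
    rc = reverse_complement(seq)
    n = len(seq)
    hits = []
    for motif in motifs:
        pattern = _iupac_regex(motif.consensus)
        mlen = len(motif.consensus)
        for m in pattern.finditer(seq):
            hits.append(MotifHit(motif.name, m.start() + 1, "+"))
        for m in pattern.finditer(rc):
            hits.append(MotifHit(motif.name, n - m.start() - mlen + 1, "-"))
    return sorted(hits, key=lambda h: (h.position, h.name, h.strand))


@dataclass
class ElementSummary:
    promoters_per_element: dict[str, int]
    promoters_per_category: dict[str, int]
    n_promoters: int


def summarize_elements(per_gene_hits: Mapping[str, list[MotifHit]],
                       motifs: Iterable[MotifDefinition]) -> ElementSummary:
    """Promoter-presence counts: per element and per functional category the
    number of promoters with at least one hit."""
    motifs = list(motifs)
    category_of = {m.name: m.category for m in motifs}
    per_element = {m.name: 0 for m in motifs}
    categories = sorted({m.category for m in motifs})
    per_category = {c: 0 for c in categories}
    for hits in per_gene_hits.values():
        names = {h.name for h in hits}
        for name in names:
            if name in per_element:
                per_element[name] += 1
        cats = {category_of[name] for name in names if name in category_of}
        for c in cats:
            per_category[c] += 1
    return ElementSummary(per_element, per_category, len(per_gene_hits))
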