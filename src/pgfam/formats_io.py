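"""Readers and writers for FASTA, GFF3 and Newick with strict validation.

Malformed input is rejected, never silently repaired.  Coordinates are
1-based inclusive (GFF3 convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .tree import NewickError, Tree, TreeNode, parse_newick, write_newick

__all__ = [
    "SequenceRecord", "GeneModel", "FormatError",
    "read_fasta", "write_fasta", "read_gene_models", "write_gene_models",
    "parse_newick", "write_newick", "Tree", "TreeNode", "NewickError",
]

_ALPHABETS = {
    "protein": set("ACDEFGHIKLMNPQRSTVWYX*"),
    "cds": set("ACGTN"),
    "promoter": set("ACGTN"),
}


class FormatError(ValueError):
    """Raised on malformed input files."""


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record; ``kind`` selects the allowed alphabet."""

    id: str
    seq: str
    kind: str | None = None

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid sequence id {self.id!r}")
        if not self.seq:
            raise FormatError(f"empty sequence for {self.id}")
        if any(c.isspace() for c in self.seq):
            raise FormatError(f"whitespace inside sequence {self.id}")
        if self.kind is not None:
            if self.kind not in _ALPHABETS:
                raise FormatError(f"unknown sequence kind {self.kind!r}")
            bad = set(self.seq.upper()) - _ALPHABETS[self.kind]
            if bad:
                raise FormatError(
                    f"{self.id}: characters {sorted(bad)} not allowed for kind {self.kind}")
            if self.kind == "cds" and len(self.seq) % 3 != 0:
                raise FormatError(f"{self.id}: CDS length {len(self.seq)} not divisible by 3")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """A gene's chromosome, strand, and exons in transcription (5'->3') order.

    Exon coordinates are 1-based inclusive genomic positions; for minus-strand
    genes the first exon is the one with the largest coordinates.
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise FormatError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise FormatError(f"{self.gene_id}: gene needs at least one exon")
        for s, e in self.exons:
            if s <= 0 or e <= 0 or e < s:
                raise FormatError(f"{self.gene_id}: bad exon coordinates ({s}, {e})")
        ordered = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise FormatError(f"{self.gene_id}: overlapping exons")
        expect = ordered if self.strand == "+" else ordered[::-1]
        if list(self.exons) != expect:
            raise FormatError(f"{self.gene_id}: exons not in transcription order")

    @property
    def exon_lengths(self) -> list[int]:
        return [e - s + 1 for s, e in self.exons]

    @property
    def span(self) -> tuple[int, int]:
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, kind: str | None = None) -> list[SequenceRecord]:
    """Read a multi-FASTA file into validated records (order preserved)."""
    path = Path(path)
    text = path.read_text()
    if not text.lstrip().startswith(">"):
        raise FormatError(f"{path}: not FASTA (no '>' header)")
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(), kind))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_COLS = 9


def _gff_attributes(raw: str) -> dict[str, str]:
    out = {}
    for item in raw.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            raise FormatError(f"bad GFF3 attribute {item!r}")
        key, val = item.split("=", 1)
        out[key.strip()] = val.strip()
    return out


def read_gene_models(path: str | Path, coding_feature: str = "CDS") -> list[GeneModel]:
    """Read gene models from GFF3, taking ``coding_feature`` rows as exons.

    Genes are returned in file order with exons re-ordered into
    transcription order for minus-strand genes.  A gene feature without any
    coding feature, or a coding feature whose Parent is not a declared gene,
    is an error.
    """
    path = Path(path)
    genes: dict[str, dict] = {}
    exon_rows: list[tuple[str, str, str, int, int]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != _GFF_COLS:
            raise FormatError(f"{path}:{lineno}: expected {_GFF_COLS} columns")
        seqid, _source, ftype, start, end, _score, strand, _phase, attrs = cols
        attributes = _gff_attributes(attrs)
        if ftype == "gene":
            gid = attributes.get("ID")
            if not gid:
                raise FormatError(f"{path}:{lineno}: gene without ID")
            if gid in genes:
                raise FormatError(f"{path}:{lineno}: duplicate gene {gid}")
            genes[gid] = {"chromosome": seqid, "strand": strand, "exons": []}
        elif ftype == coding_feature:
            parent = attributes.get("Parent") or attributes.get("ID")
            if not parent:
                raise FormatError(f"{path}:{lineno}: {coding_feature} without Parent")
            exon_rows.append((parent, seqid, strand, int(start), int(end)))
    for parent, seqid, strand, start, end in exon_rows:
        if parent not in genes:
            raise FormatError(f"{coding_feature} with unknown parent gene {parent!r}")
        genes[parent]["exons"].append((start, end))
    models = []
    for gid, info in genes.items():
        if not info["exons"]:
            raise FormatError(f"gene {gid}: no {coding_feature} features")
        exons = sorted(info["exons"])
        if info["strand"] == "-":
            exons = exons[::-1]
        models.append(GeneModel(gid, info["chromosome"], info["strand"], exons))
    return models


def write_gene_models(models, path: str | Path, coding_feature: str = "CDS") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            lo, hi = m.span
            fh.write("\t".join([m.chromosome, "pgfam", "gene", str(lo), str(hi),
                                ".", m.strand, ".", f"ID={m.gene_id}"]) + "\n")
            for s, e in sorted(m.exons):
                fh.write("\t".join([m.chromosome, "pgfam", coding_feature, str(s),
                                    str(e), ".", m.strand, ".",
                                    f"Parent={m.gene_id}"]) + "\n")


def read_newick_file(path: str | Path) -> Tree:
    return parse_newick(Path(path).read_text())


def write_newick_file(tree: Tree, path: str | Path) -> None:
    Path(path).write_text(write_newick(tree) + "\n")
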