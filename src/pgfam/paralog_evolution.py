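"""Paralog-pair analysis: alignment identity/coverage, tandem-duplicate
detection (80/80 rule), terminal sister pairs, and Nei-Gojobori (1986)
Ka/Ks with unweighted pathway averaging and Jukes-Cantor correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .formats_io import GeneModel
from .tree import Tree

UNDEFINED = "——"  # rendering for an undefined Ka/Ks ratio


class ParalogError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Pairwise global alignment
# ---------------------------------------------------------------------------

@dataclass
class PairAlignment:
    gene_a: str
    gene_b: str
    identity_pct: float
    coverage_pct: float
    score: float


@dataclass
class AlignScoring:
    """Scoring for global alignment.  ``matrix`` (a substitution-matrix name
    such as "BLOSUM62") overrides match/mismatch.  End gaps are free by
    default so that coverage reflects the aligned core.
    """

    matrix: str | None = "BLOSUM62"
    match: float = 2.0
    mismatch: float = -1.0
    open_gap: float = -10.0
    extend_gap: float = -0.5
    free_end_gaps: bool = True


def _build_aligner(scoring: AlignScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if scoring.matrix:
        aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    else:
        aligner.match_score = scoring.match
        aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.open_gap
    aligner.extend_gap_score = scoring.extend_gap
    if scoring.free_end_gaps:
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # older biopython
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    return aligner


def global_align_identity(seq_a: str, seq_b: str,
                          scoring: AlignScoring | None = None,
                          name_a: str = "a", name_b: str = "b") -> PairAlignment:
    """Globally align two sequences and report identity over the aligned core
    (terminal gaps excluded) and coverage of the longer sequence."""
    if not seq_a or not seq_b:
        raise ParalogError("empty sequence")
    scoring = scoring or AlignScoring()
    aligner = _build_aligner(scoring)
    alignment = aligner.align(seq_a, seq_b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    both = [i for i in range(len(row_a)) if row_a[i] != "-" and row_b[i] != "-"]
    if not both:
        return PairAlignment(name_a, name_b, 0.0, 0.0, alignment.score)
    first, last = both[0], both[-1]
    core_a = row_a[first:last + 1]
    core_b = row_b[first:last + 1]
    ncols = last - first + 1
    matches = sum(1 for x, y in zip(core_a, core_b) if x == y and x != "-")
    identity = 100.0 * matches / ncols
    longer, longer_len = (core_a, len(seq_a)) if len(seq_a) >= len(seq_b) else (core_b, len(seq_b))
    span = sum(1 for c in longer if c != "-")
    coverage = 100.0 * span / longer_len
    return PairAlignment(name_a, name_b, identity, coverage, alignment.score)


# ---------------------------------------------------------------------------
# Tandem duplicates
# ---------------------------------------------------------------------------

@dataclass
class TandemPair:
    gene_a: str
    gene_b: str
    identity_pct: float
    coverage_pct: float
    intervening_genes: int
    distance_bp: int


def detect_tandem_pairs(gene_models: list[GeneModel], sequences: dict[str, str],
                        max_separation: int = 1, max_distance_bp: int = 100_000,
                        min_identity: float = 80.0, min_coverage: float = 80.0,
                        scoring: AlignScoring | None = None) -> list[TandemPair]:
    """Pairs on one chromosome that are closely linked (<= ``max_separation``
    intervening family genes, or <= ``max_distance_bp`` apart) with identity
    and coverage both above 80%."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in gene_models:
        by_chrom.setdefault(m.chromosome, []).append(m)
    pairs: list[TandemPair] = []
    for chrom in sorted(by_chrom):
        models = sorted(by_chrom[chrom], key=lambda m: m.span)
        for i in range(len(models)):
            for j in range(i + 1, len(models)):
                a, b = models[i], models[j]
                intervening = j - i - 1
                gap = max(b.span[0] - a.span[1], 0)
                if intervening > max_separation and gap > max_distance_bp:
                    continue
                if a.gene_id not in sequences or b.gene_id not in sequences:
                    continue
                aln = global_align_identity(sequences[a.gene_id], sequences[b.gene_id],
                                            scoring, a.gene_id, b.gene_id)
                if aln.identity_pct > min_identity and aln.coverage_pct > min_coverage:
                    pairs.append(TandemPair(a.gene_id, b.gene_id, aln.identity_pct,
                                            aln.coverage_pct, intervening, gap))
    return pairs


def terminal_paralog_pairs(tree: Tree, identity_of, min_identity: float = 80.0
                           ) -> list[tuple[str, str]]:
    """Sister-tip pairs ("cherries") with identity above the threshold.

    ``identity_of`` is a callable (name_a, name_b) -> percent identity or a
    mapping keyed by frozenset pairs.
    """
    if not callable(identity_of):
        mapping = identity_of
        identity_of = lambda a, b: mapping[frozenset((a, b))]  # noqa: E731
    pairs = []
    for node in tree.root.preorder():
        if len(node.children) == 2 and all(c.is_leaf for c in node.children):
            a, b = sorted(c.name for c in node.children)
            if identity_of(a, b) > min_identity:
                pairs.append((a, b))
    return sorted(pairs)


# ---------------------------------------------------------------------------
# NG86 Ka/Ks
# ---------------------------------------------------------------------------

@dataclass
class KaKsResult:
    ka: float
    ks: float
    ratio: float | None        # None when Ks = 0 (rendered "——")
    saturated: bool = False    # p >= 3/4 in either class

    def ratio_str(self, ndigits: int = 4) -> str:
        if self.ratio is None or math.isnan(self.ka) or math.isnan(self.ks):
            return UNDEFINED
        return f"{round(self.ratio, ndigits):g}"


_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_AA = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    _CODON_AA[_stop] = "*"
_NUCS = "ACGT"


def _syn_fraction(codon: str) -> float:
    """Synonymous site count of one codon (0..3): per position, the fraction
    of single-nucleotide changes (stop-producing changes excluded) that
    preserve the amino acid."""
    aa = _CODON_AA[codon]
    total = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for nuc in _NUCS:
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1:]
            if _CODON_AA[alt] == "*":
                continue
            valid += 1
            if _CODON_AA[alt] == aa:
                syn += 1
        if valid:
            total += syn / valid
    return total


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) substitution counts between two codons,
    averaged over all minimal substitution pathways.  Pathways passing
    through a stop codon are excluded unless every pathway does."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in permutations(diff):
        current = codon_a
        sd = nd = 0
        valid = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if _CODON_AA[nxt] == "*":
                valid = False
            if _CODON_AA[nxt] == _CODON_AA[current]:
                sd += 1
            else:
                nd += 1
            current = nxt
        results.append((valid, sd, nd))
    usable = [(sd, nd) for valid, sd, nd in results if valid]
    if not usable:
        usable = [(sd, nd) for _, sd, nd in results]
    sd = sum(x for x, _ in usable) / len(usable)
    nd = sum(y for _, y in usable) / len(usable)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.nan
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_kaks(cds_a: str, cds_b: str) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks for a gap-free, in-frame, equal-length CDS
    pair.  ``ratio`` is None when Ks = 0; saturation (p >= 3/4) yields NaN
    distances with ``saturated`` set.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise ParalogError("sequences differ in length")
    if len(cds_a) % 3 != 0 or not cds_a:
        raise ParalogError("length not a positive multiple of 3")
    if "-" in cds_a or "-" in cds_b:
        raise ParalogError("gapped sequences not allowed; codon-align first")
    codons_a = [cds_a[i:i + 3] for i in range(0, len(cds_a), 3)]
    codons_b = [cds_b[i:i + 3] for i in range(0, len(cds_b), 3)]
    for codons in (codons_a, codons_b):
        for k, codon in enumerate(codons):
            if codon not in _CODON_AA:
                raise ParalogError(f"unknown codon {codon!r}")
            if _CODON_AA[codon] == "*" and k < len(codons) - 1:
                raise ParalogError("internal stop codon")
    # drop terminal stop codons if present
    if _CODON_AA[codons_a[-1]] == "*" or _CODON_AA[codons_b[-1]] == "*":
        codons_a, codons_b = codons_a[:-1], codons_b[:-1]
    if not codons_a:
        raise ParalogError("no codons left after stop removal")
    s_sites = sum(_syn_fraction(c) for c in codons_a) / 2.0 \
        + sum(_syn_fraction(c) for c in codons_b) / 2.0
    n_sites = 3.0 * len(codons_a) - s_sites
    sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        s, n = _pathway_counts(ca, cb)
        sd += s
        nd += n
    p_s = sd / s_sites if s_sites > 0 else 0.0
    p_n = nd / n_sites if n_sites > 0 else 0.0
    ks = _jukes_cantor(p_s)
    ka = _jukes_cantor(p_n)
    saturated = math.isnan(ks) or math.isnan(ka)
    if saturated or ks == 0.0:
        ratio = None
    else:
        ratio = ka / ks
    return KaKsResult(ka, ks, ratio, saturated)


def codon_align(cds_a: str, cds_b: str, scoring: AlignScoring | None = None
                ) -> tuple[str, str]:
    """Codon-align two CDS by threading the protein global alignment back
    onto the nucleotides; codon columns gapped in either protein are dropped,
    yielding a gap-free equal-length pair ready for :func:`ng86_kaks`."""
    from Bio.Seq import Seq
    for cds in (cds_a, cds_b):
        if len(cds) % 3 != 0:
            raise ParalogError("CDS length not divisible by 3")
    prot_a = str(Seq(cds_a).translate()).rstrip("*")
    prot_b = str(Seq(cds_b).translate()).rstrip("*")
    scoring = scoring or AlignScoring(free_end_gaps=False)
    aligner = _build_aligner(scoring)
    alignment = aligner.align(prot_a, prot_b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    out_a, out_b = [], []
    ia = ib = 0
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            out_a.append(cds_a[3 * ia:3 * ia + 3])
            out_b.append(cds_b[3 * ib:3 * ib + 3])
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
    return "".join(out_a), "".join(out_b)
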