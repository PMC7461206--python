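"""Two-species gene-family simulator with a complete ground-truth ledger.

A diploid species A and a descendant species B that underwent a whole-genome
triplication are simulated per ancestral lineage: species B receives three
subgenome copies (LF/MF1/MF2) that are lost independently with
subgenome-specific probabilities (biased fractionation), then tandem and
dispersed duplications are applied in both species.  Coding sequences evolve
by a propose/accept-reject codon process whose accepted
nonsynonymous:synonymous ratio tracks a target omega.  Expression tables and
promoters are constructed so that planted pair categories and motifs are
recoverable by the downstream analysis modules.

The paper-style system this emulates provides no generative model; every
distribution here is a documented stand-in chosen for testability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cis_elements import MotifDefinition, MotifHit, reverse_complement, scan_promoter
from .formats_io import GeneModel, SequenceRecord
from .pg_identify import DEFAULT_DOMAIN_MOTIFS
from .tree import Tree, TreeNode

SUBGENOMES = ("LF", "MF1", "MF2")
DEFAULT_TISSUES = ("root", "stem", "leaf", "inflorescence", "silique")
REFERENCE_GENE = "GAPDH"
REFERENCE_CT = 20.0

_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
from .paralog_evolution import _CODON_AA  # standard genetic code

_NONSTOP = [c for c in _CODONS if _CODON_AA[c] != "*"]
_AA_TO_CODONS: dict[str, list[str]] = {}
for _c in _NONSTOP:
    _AA_TO_CODONS.setdefault(_CODON_AA[_c], []).append(_c)

# protein positions (0-based codon index) where the conserved domains go
_MOTIF_POSITIONS = {"I": 9, "II": 29, "III": 49, "IV": 69}


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    n_ancestral: int = 20
    loss_prob_by_subgenome: tuple[float, float, float] = (0.5, 0.66, 0.71)
    tandem_rate: float = 0.08
    post_split_dup_rate_a: float = 0.05
    post_split_dup_rate_b: float = 0.05
    loss_prob_a: float = 0.0
    subs_per_site: float = 0.05
    omega: float = 0.2
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    category_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_codons: int = 90
    promoter_len: int = 2000
    motif_domains: tuple[str, ...] = ("I", "II", "III", "IV")
    seed: int = 0

    def __post_init__(self):
        probs = (*self.loss_prob_by_subgenome, self.tandem_rate,
                 self.post_split_dup_rate_a, self.post_split_dup_rate_b,
                 self.loss_prob_a)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise SimulationError("probabilities must be in [0, 1]")
        lf, mf1, mf2 = self.loss_prob_by_subgenome
        if not lf <= mf1 <= mf2:
            raise SimulationError("loss probabilities must satisfy LF <= MF1 <= MF2")
        if abs(sum(self.category_mix) - 1.0) > 1e-9:
            raise SimulationError("category_mix must sum to 1")
        if self.subs_per_site < 0:
            raise SimulationError("subs_per_site must be >= 0")
        if self.omega < 0:
            raise SimulationError("omega must be >= 0")
        if self.motif_domains and self.n_codons < 80:
            raise SimulationError("n_codons must be >= 80 to hold the four domains")


@dataclass
class LineageTruth:
    lineage_id: str
    genes_a: list[str] = field(default_factory=list)
    genes_b: list[str] = field(default_factory=list)
    subgenome_of: dict[str, str] = field(default_factory=dict)

    @property
    def n_a(self) -> int:
        return len(self.genes_a)

    @property
    def n_b(self) -> int:
        return len(self.genes_b)


@dataclass
class SimTruth:
    lineages: list[LineageTruth] = field(default_factory=list)
    subgenome_of: dict[str, str] = field(default_factory=dict)
    tandem_pairs: list[tuple[str, str]] = field(default_factory=list)
    planted_categories: dict[tuple[str, str], str] = field(default_factory=dict)
    planted_motifs: dict[str, list[MotifHit]] = field(default_factory=dict)
    substitutions: dict[str, int] = field(default_factory=dict)

    @property
    def n_active_lineages(self) -> int:
        return sum(1 for lin in self.lineages if lin.n_a + lin.n_b > 0)


@dataclass
class FamilyHistory:
    config: SimConfig
    trees: list[Tree]               # one rooted true gene tree per active lineage
    gene_models: list[GeneModel]    # species-B gene models (GFF-ready)
    truth: SimTruth

    def genes(self, species: str | None = None) -> list[str]:
        out = []
        for tree in self.trees:
            for name in tree.tip_names():
                if species is None or name.startswith(species + "_"):
                    out.append(name)
        return out


# ---------------------------------------------------------------------------
# History
# ---------------------------------------------------------------------------

def _tip(name: str, length: float) -> TreeNode:
    return TreeNode(name=name, length=length)


def _internal(length: float, children: list[TreeNode]) -> TreeNode:
    node = TreeNode(length=length, support=100)
    for c in children:
        node.add(c)
    return node


def _group_subtree(genes: list[str], attach_depth: float, s: float) -> TreeNode:
    """Subtree for one retained copy and its duplicates: tandem copy joins as
    a shallow cherry, a dispersed copy joins just above it."""
    if len(genes) == 1:
        return _tip(genes[0], s - attach_depth)
    if len(genes) == 2:
        cherry_depth = 0.9 * s if s > 0 else 0.0
        node = _internal(cherry_depth - attach_depth,
                         [_tip(genes[0], s - cherry_depth),
                          _tip(genes[1], s - cherry_depth)])
        return node
    # base + tandem + dispersed
    cherry_depth = 0.9 * s if s > 0 else 0.0
    join_depth = 0.8 * s if s > 0 else 0.0
    cherry = _internal(cherry_depth - join_depth,
                       [_tip(genes[0], s - cherry_depth),
                        _tip(genes[1], s - cherry_depth)])
    return _internal(join_depth - attach_depth,
                     [cherry, _tip(genes[2], s - join_depth)])


def simulate_family_history(config: SimConfig) -> FamilyHistory:
    if config.n_ancestral <= 0:
        raise SimulationError("n_ancestral must be positive")
    rng = np.random.default_rng([config.seed, 0])
    s = config.subs_per_site
    truth = SimTruth()
    trees: list[Tree] = []
    placement_units: list[list[str]] = []   # genes emitted adjacently (species B)
    dispersed_units: list[tuple[str, int]] = []  # (gene, source unit index)
    for i in range(config.n_ancestral):
        lid = f"L{i + 1:03d}"
        lin = LineageTruth(lid)
        # species A
        a_genes: list[str] = []
        if rng.random() >= config.loss_prob_a:
            a_genes.append(f"A_{lid}.1")
            if rng.random() < config.post_split_dup_rate_a:
                a_genes.append(f"A_{lid}.2")
        lin.genes_a = a_genes
        # species B: three subgenome copies, independent loss, then duplication
        b_groups: list[tuple[str, list[str], str | None]] = []  # (subgenome, adjacent genes, dispersed)
        for sg, p_loss in zip(SUBGENOMES, config.loss_prob_by_subgenome):
            if rng.random() < p_loss:
                continue
            base = f"B_{lid}.{sg}"
            adjacent = [base]
            if rng.random() < config.tandem_rate:
                tandem = f"B_{lid}.{sg}t"
                adjacent.append(tandem)
                truth.tandem_pairs.append((base, tandem))
            dispersed = None
            if rng.random() < config.post_split_dup_rate_b:
                dispersed = f"B_{lid}.{sg}d"
            b_groups.append((sg, adjacent, dispersed))
            for g in adjacent + ([dispersed] if dispersed else []):
                lin.genes_b.append(g)
                lin.subgenome_of[g] = sg
                truth.subgenome_of[g] = sg
        truth.lineages.append(lin)
        # build the true gene tree for this lineage
        sub_b: dict[str, TreeNode] = {}
        n_b_groups = len(b_groups)
        wgt1 = 0.15 * s
        wgt2 = 0.30 * s
        b_root: TreeNode | None = None
        if n_b_groups == 1:
            sg, adjacent, dispersed = b_groups[0]
            b_root = _group_subtree(adjacent + ([dispersed] if dispersed else []), 0.0, s)
        elif n_b_groups == 2:
            kids = [_group_subtree(adj + ([d] if d else []), wgt1, s)
                    for _, adj, d in b_groups]
            b_root = _internal(wgt1, kids)
        elif n_b_groups == 3:
            # LF splits off first, MF1/MF2 later
            lf_sub = _group_subtree(b_groups[0][1] + ([b_groups[0][2]] if b_groups[0][2] else []), wgt1, s)
            mf1_sub = _group_subtree(b_groups[1][1] + ([b_groups[1][2]] if b_groups[1][2] else []), wgt2, s)
            mf2_sub = _group_subtree(b_groups[2][1] + ([b_groups[2][2]] if b_groups[2][2] else []), wgt2, s)
            inner = _internal(wgt2 - wgt1, [mf1_sub, mf2_sub])
            b_root = _internal(wgt1, [lf_sub, inner])
        a_root: TreeNode | None = None
        if len(a_genes) == 1:
            a_root = _tip(a_genes[0], s)
        elif len(a_genes) == 2:
            half = 0.5 * s
            a_root = _internal(half, [_tip(a_genes[0], s - half),
                                      _tip(a_genes[1], s - half)])
        if a_root is not None and b_root is not None:
            root = TreeNode(support=100)
            root.add(a_root)
            root.add(b_root)
            trees.append(Tree(root))
        elif a_root is not None or b_root is not None:
            only = a_root if a_root is not None else b_root
            only.length = None
            trees.append(Tree(only))
        # else: extinct lineage, no tree
        for _, adjacent, dispersed in b_groups:
            placement_units.append(adjacent)
            if dispersed:
                dispersed_units.append((dispersed, len(placement_units) - 1))
    gene_models = _place_genes(placement_units, dispersed_units, config, rng)
    return FamilyHistory(config, trees, gene_models, truth)


def _random_exons(rng, start: int, total_cds: int, strand: str) -> list[tuple[int, int]]:
    n_exons = int(rng.integers(1, 6))
    cuts = sorted(rng.choice(np.arange(1, total_cds // 3), size=n_exons - 1,
                             replace=False) * 3) if n_exons > 1 else []
    lengths = np.diff([0, *cuts, total_cds]).tolist()
    exons = []
    pos = start
    for length in lengths:
        exons.append((pos, pos + length - 1))
        pos += length + int(rng.integers(100, 400))
    return exons if strand == "+" else exons[::-1]


def _place_genes(units: list[list[str]], dispersed: list[tuple[str, int]],
                 config: SimConfig, rng) -> list[GeneModel]:
    """Lay species-B genes onto chromosomes C01..C09; tandem copies are
    adjacent with a small (<10 kb) gap, dispersed duplicates always go to a
    different chromosome than their source copy."""
    chroms = [f"C{i:02d}" for i in range(1, 10)]
    cursor = {c: 10_000 for c in chroms}
    total_cds = 3 * config.n_codons
    models = []
    for u, unit in enumerate(units):
        chrom = chroms[u % len(chroms)]
        for k, gene in enumerate(unit):
            strand = "+" if rng.random() < 0.5 else "-"
            start = cursor[chrom]
            exons = _random_exons(rng, start, total_cds, strand)
            models.append(GeneModel(gene, chrom, strand, exons))
            span = max(e for _, e in exons) - start + 1
            gap = int(rng.integers(1_000, 8_000)) if k < len(unit) - 1 \
                else int(rng.integers(30_000, 60_000))
            cursor[chrom] = start + span + gap
    for gene, source_unit in dispersed:
        chrom = chroms[(source_unit + 4) % len(chroms)]
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursor[chrom] + 200_000
        exons = _random_exons(rng, start, total_cds, strand)
        models.append(GeneModel(gene, chrom, strand, exons))
        cursor[chrom] = start + (max(e for _, e in exons) - start + 1) + 40_000
    return models


def family_tree(history: FamilyHistory, join_length: float = 0.02) -> Tree:
    """Join the per-lineage true trees into one rooted family tree
    (caterpillar, a two-species lineage innermost so that every pure lineage
    stays a maximal single-species clade)."""
    if not history.trees:
        raise SimulationError("no surviving lineages")
    def is_mixed(t: Tree) -> bool:
        species = {n.split("_", 1)[0] for n in t.tip_names()}
        return len(species) == 2
    ordered = sorted(history.trees, key=lambda t: not is_mixed(t))
    if len(ordered) == 1:
        return ordered[0].copy()
    current = ordered[0].copy().root
    if current.length is None:
        current.length = join_length
    for t in ordered[1:]:
        nxt = t.copy().root
        if nxt.length is None:
            nxt.length = join_length
        parent = TreeNode(length=join_length, support=100)
        parent.add(current)
        parent.add(nxt)
        current = parent
    current.length = None
    current.support = None
    return Tree(current)


def true_paralog_pairs(history: FamilyHistory) -> list[tuple[str, str]]:
    """Same-species sister-tip pairs of the true gene trees."""
    pairs = []
    for tree in history.trees:
        for node in tree.root.preorder():
            if len(node.children) == 2 and all(c.is_leaf for c in node.children):
                a, b = sorted(c.name for c in node.children)
                if a.split("_", 1)[0] == b.split("_", 1)[0]:
                    pairs.append((a, b))
    return sorted(pairs)


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def _translate(codons: list[str]) -> str:
    return "".join(_CODON_AA[c] for c in codons)


def _encode_protein(rng, aa: str) -> list[str]:
    return [_AA_TO_CODONS[res][rng.integers(len(_AA_TO_CODONS[res]))] for res in aa]


def _evolve_codons(rng, codons: list[str], n_subs: int, omega: float,
                   frozen: set[int]) -> tuple[list[str], int]:
    """Accept/reject codon evolution: synonymous proposals accepted with
    probability 1, nonsynonymous with probability omega (scaled down jointly
    when omega > 1); proposals creating stops or touching frozen codons are
    rejected.  Returns the evolved codons and the realized substitution count.
    """
    seq = list(codons)
    p_syn = 1.0 if omega <= 1.0 else 1.0 / omega
    p_non = omega if omega <= 1.0 else 1.0
    accepted = 0
    attempts = 0
    limit = 500 * max(n_subs, 1) + 1000
    free = [i for i in range(len(seq)) if i not in frozen]
    if not free:
        return seq, 0
    while accepted < n_subs and attempts < limit:
        attempts += 1
        ci = free[rng.integers(len(free))]
        pos = int(rng.integers(3))
        codon = seq[ci]
        current = codon[pos]
        alt = "ACGT"[rng.integers(4)]
        if alt == current:
            continue
        new_codon = codon[:pos] + alt + codon[pos + 1:]
        if _CODON_AA[new_codon] == "*":
            continue
        synonymous = _CODON_AA[new_codon] == _CODON_AA[codon]
        p_accept = p_syn if synonymous else p_non
        if p_accept < 1.0 and rng.random() >= p_accept:
            continue
        seq[ci] = new_codon
        accepted += 1
    return seq, accepted


def _ancestral_codons(rng, config: SimConfig) -> tuple[list[str], set[int]]:
    codons = [_NONSTOP[rng.integers(len(_NONSTOP))] for _ in range(config.n_codons)]
    frozen: set[int] = set()
    for domain in config.motif_domains:
        motif = DEFAULT_DOMAIN_MOTIFS[domain]
        start = _MOTIF_POSITIONS[domain]
        encoded = _encode_protein(rng, motif)
        for k, codon in enumerate(encoded):
            codons[start + k] = codon
            frozen.add(start + k)
    return codons, frozen


def emit_sequences(history: FamilyHistory, config: SimConfig | None = None
                   ) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Evolve CDS along the true trees; returns (cds records, protein
    records) for every extant gene, in tree order."""
    config = config or history.config
    if config.omega < 0:
        raise SimulationError("omega must be >= 0")
    rng = np.random.default_rng([config.seed, 1])
    n_nt = 3 * config.n_codons
    cds_records: list[SequenceRecord] = []
    protein_records: list[SequenceRecord] = []
    for li, tree in enumerate(history.trees):
        ancestor, frozen = _ancestral_codons(rng, config)

        def recurse(node: TreeNode, codons: list[str], edge_id: str) -> None:
            if node.length:
                n_subs = int(rng.poisson(node.length * n_nt))
                codons, realized = _evolve_codons(rng, codons, n_subs,
                                                  config.omega, frozen)
                history.truth.substitutions[edge_id] = realized
            if node.is_leaf:
                cds = "".join(codons)
                cds_records.append(SequenceRecord(node.name, cds, "cds"))
                protein_records.append(
                    SequenceRecord(node.name, _translate(codons), "protein"))
                return
            for k, child in enumerate(node.children):
                recurse(child, codons, f"{edge_id}.{k}")

        recurse(tree.root, ancestor, f"T{li}")
    return cds_records, protein_records


def evolve_pair(n_codons: int, divergence: float, omega: float, seed: int,
                ) -> tuple[str, str]:
    """Evolve two sequences independently from a common ancestor, each along
    a branch of ``divergence``/2 substitutions per site; handy for Ka/Ks
    calibration."""
    rng = np.random.default_rng(seed)
    codons = [_NONSTOP[rng.integers(len(_NONSTOP))] for _ in range(n_codons)]
    out = []
    for _ in range(2):
        n_subs = int(rng.poisson(divergence / 2.0 * 3 * n_codons))
        evolved, _ = _evolve_codons(rng, codons, n_subs, omega, frozen=set())
        out.append("".join(evolved))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _ct_rows(gene: str, cts: dict[str, float | None], tissues) -> list[dict]:
    return [{"gene": gene, "sample": t,
             "ct": "ND" if cts.get(t) is None else cts[t]} for t in tissues]


def emit_expression(history: FamilyHistory, config: SimConfig | None = None
                    ) -> pd.DataFrame:
    """Long-format Ct table (gene, sample, ct) in which every true paralog
    pair realizes its planted category under the default thresholds of
    :func:`pgfam.expression.categorize_pair`.  The reference gene has a
    constant Ct; "ND" marks no amplification."""
    config = config or history.config
    tissues = list(config.tissues)
    if len(tissues) < 2:
        raise SimulationError("need at least two tissues")
    rng = np.random.default_rng([config.seed, 2])
    cal = tissues[0]
    other = tissues[1:]
    rows: list[dict] = []
    for t in tissues:
        rows.append({"gene": REFERENCE_GENE, "sample": t, "ct": REFERENCE_CT})
    pairs = true_paralog_pairs(history)
    paired_genes = {g for p in pairs for g in p}
    mix = np.asarray(config.category_mix, dtype=float)
    for a, b in pairs:
        category = ("I", "II", "III", "IV")[rng.choice(4, p=mix)]
        history.truth.planted_categories[(a, b)] = category
        silent: dict[str, float | None] = {t: None for t in tissues}
        if category == "I":
            if rng.random() < 0.5:
                ct_a = ct_b = dict(silent)
            else:
                t2 = other[rng.integers(len(other))]
                shared = dict(silent)
                shared[cal] = 24.0
                shared[t2] = 23.0
                ct_a, ct_b = dict(shared), dict(shared)
        elif category == "II":
            t2 = other[rng.integers(len(other))]
            ct_a, ct_b = dict(silent), dict(silent)
            ct_a[cal] = ct_b[cal] = 24.0
            ct_a[t2] = 22.0   # 4-fold above its calibrator level
            ct_b[t2] = 24.0
        elif category == "III":
            ct_a, ct_b = dict(silent), dict(silent)
            ct_a[cal] = ct_b[cal] = 24.0
            if len(other) >= 2:
                t2, t3 = rng.choice(len(other), size=2, replace=False)
                ct_a[other[t2]] = 23.0
                ct_b[other[t3]] = 23.0
            else:  # two tissues: overlap only in the calibrator
                ct_b[other[0]] = 23.0
        else:  # IV
            ct_a = dict(silent)
            ct_b = dict(silent)
            t2 = other[rng.integers(len(other))]
            ct_b[cal] = 24.0
            ct_b[t2] = 23.0
        rows.extend(_ct_rows(a, ct_a, tissues))
        rows.extend(_ct_rows(b, ct_b, tissues))
    # unpaired genes: random simple patterns
    for gene in history.genes():
        if gene in paired_genes:
            continue
        pattern = rng.integers(3)
        cts: dict[str, float | None] = {t: None for t in tissues}
        if pattern == 1:       # ubiquitous
            for t in tissues:
                cts[t] = 24.0 + float(rng.integers(0, 3))
        elif pattern == 2:     # single-tissue
            cts[other[rng.integers(len(other))]] = 23.0
        rows.extend(_ct_rows(gene, cts, tissues))
    return pd.DataFrame(rows, columns=["gene", "sample", "ct"])


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

def _realize_iupac(rng, consensus: str) -> str:
    from .cis_elements import IUPAC
    return "".join(opts[rng.integers(len(opts))] if len(opts := IUPAC[c]) > 1 else opts
                   for c in consensus.upper())


def emit_promoters(history: FamilyHistory, motifs: list[MotifDefinition],
                   config: SimConfig | None = None,
                   plants: dict[str, list[tuple[str, str]]] | None = None,
                   mean_plants: float = 2.0,
                   background_free_of: list[MotifDefinition] | None = None,
                   ) -> list[SequenceRecord]:
    """Random promoters with named motifs inserted at recorded positions and
    strands (ledgered in ``history.truth.planted_motifs``).

    ``plants`` maps gene -> [(motif name, strand)] for explicit planting;
    otherwise each promoter receives Poisson(``mean_plants``) random motifs.
    ``background_free_of`` rejection-samples backgrounds until they contain
    none of the given motifs on either strand (use short promoters or long
    motifs, or this will not converge).
    """
    config = config or history.config
    by_name = {m.name: m for m in motifs}
    longest = max((len(m.consensus) for m in motifs), default=0)
    if longest > config.promoter_len:
        raise SimulationError("motif longer than promoter")
    rng = np.random.default_rng([config.seed, 3])
    records = []
    for gene in history.genes():
        background = None
        for _ in range(2000):
            candidate = "".join("ACGT"[i] for i in rng.integers(0, 4, config.promoter_len))
            if not background_free_of or not scan_promoter(candidate, background_free_of):
                background = candidate
                break
        if background is None:
            raise SimulationError("could not sample a motif-free background")
        seq = list(background)
        if plants is not None:
            wanted = plants.get(gene, [])
        else:
            k = int(rng.poisson(mean_plants))
            names = sorted(by_name)
            wanted = [(names[rng.integers(len(names))],
                       "+" if rng.random() < 0.5 else "-") for _ in range(k)]
        occupied: list[tuple[int, int]] = []
        planted_here: list[MotifHit] = []
        for name, strand in wanted:
            motif = by_name[name]
            realized = _realize_iupac(rng, motif.consensus)
            insert = realized if strand == "+" else reverse_complement(realized)
            mlen = len(insert)
            for _ in range(100):
                pos = int(rng.integers(0, config.promoter_len - mlen + 1))
                if all(pos + mlen <= lo or pos >= hi for lo, hi in occupied):
                    seq[pos:pos + mlen] = insert
                    occupied.append((pos, pos + mlen))
                    planted_here.append(MotifHit(name, pos + 1, strand))
                    break
        history.truth.planted_motifs[gene] = planted_here
        records.append(SequenceRecord(gene, "".join(seq), "promoter"))
    return records
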