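import numpy as np
import pandas as pd
import pytest

from pgfam.cis_elements import MotifDefinition, scan_promoter
from pgfam.expression import categorize_pair, relative_expression
from pgfam.paralog_evolution import ng86_kaks
from pgfam.pg_identify import classify_pg, scan_domains
from pgfam.synthetic_data import (REFERENCE_GENE, SimConfig, SimulationError,
                                  emit_expression, emit_promoters,
                                  emit_sequences, evolve_pair, family_tree,
                                  simulate_family_history, true_paralog_pairs)


def _cfg(**kw):
    kw.setdefault("n_ancestral", 8)
    kw.setdefault("seed", 5)
    return SimConfig(**kw)


# ---------------------------------------------------------------------------
# History
# ---------------------------------------------------------------------------

def test_no_loss_gives_three_copies_per_lineage():
    cfg = _cfg(loss_prob_by_subgenome=(0.0, 0.0, 0.0), tandem_rate=0.0,
               post_split_dup_rate_a=0.0, post_split_dup_rate_b=0.0)
    history = simulate_family_history(cfg)
    assert len(history.genes("B")) == 3 * cfg.n_ancestral


def test_zero_ancestral_rejected():
    with pytest.raises(SimulationError):
        simulate_family_history(_cfg(n_ancestral=0))


def test_same_seed_identical_outputs():
    h1 = simulate_family_history(_cfg())
    h2 = simulate_family_history(_cfg())
    assert [str(t) for t in h1.trees] == [str(t) for t in h2.trees]
    assert [(m.gene_id, m.chromosome, m.exons) for m in h1.gene_models] == \
           [(m.gene_id, m.chromosome, m.exons) for m in h2.gene_models]
    c1, p1 = emit_sequences(h1)
    c2, p2 = emit_sequences(h2)
    assert [(r.id, r.seq) for r in c1] == [(r.id, r.seq) for r in c2]
    e1, e2 = emit_expression(h1), emit_expression(h2)
    assert e1.equals(e2)


def test_retention_follows_binomial_expectation():
    # mean retained per subgenome over replicates within 3 SE of n(1 - p)
    losses = (0.5, 0.66, 0.71)
    n = 68
    reps = 200
    totals = np.zeros(3)
    for seed in range(reps):
        cfg = SimConfig(n_ancestral=n, loss_prob_by_subgenome=losses,
                        tandem_rate=0.0, post_split_dup_rate_a=0.0,
                        post_split_dup_rate_b=0.0, seed=seed)
        history = simulate_family_history(cfg)
        counts = {"LF": 0, "MF1": 0, "MF2": 0}
        for sg in history.truth.subgenome_of.values():
            counts[sg] += 1
        totals += [counts["LF"], counts["MF1"], counts["MF2"]]
    means = totals / reps
    for mean, p in zip(means, losses):
        expected = n * (1 - p)
        se = np.sqrt(n * p * (1 - p)) / np.sqrt(reps)
        assert abs(mean - expected) < 3 * se


def test_every_gene_traces_to_one_lineage():
    history = simulate_family_history(_cfg())
    seen = {}
    for lin in history.truth.lineages:
        for g in lin.genes_a + lin.genes_b:
            assert g not in seen
            seen[g] = lin.lineage_id
    assert set(seen) == set(history.genes())


def test_gain_loss_arithmetic_reconciles():
    history = simulate_family_history(_cfg())
    for lin in history.truth.lineages:
        for n in (lin.n_a, lin.n_b):
            gains = max(n - 1, 0)
            losses = 1 if n == 0 else 0
            assert n == 1 - losses + gains


def test_tandem_pairs_adjacent_in_gff():
    history = simulate_family_history(_cfg(tandem_rate=0.8, seed=2))
    assert history.truth.tandem_pairs
    order = {}
    by_chrom = {}
    for m in sorted(history.gene_models, key=lambda m: (m.chromosome, m.span)):
        by_chrom.setdefault(m.chromosome, []).append(m)
    for chrom, models in by_chrom.items():
        for idx, m in enumerate(models):
            order[m.gene_id] = (chrom, idx)
    for a, b in history.truth.tandem_pairs:
        ca, ia = order[a]
        cb, ib = order[b]
        assert ca == cb
        assert abs(ia - ib) == 1
        # gap below 10 kb
        ma = next(m for m in history.gene_models if m.gene_id == a)
        mb = next(m for m in history.gene_models if m.gene_id == b)
        gap = max(mb.span[0] - ma.span[1], ma.span[0] - mb.span[1])
        assert gap < 10_000


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def test_zero_divergence_identical_descendants():
    history = simulate_family_history(_cfg(subs_per_site=0.0))
    cds, _ = emit_sequences(history)
    seqs = {}
    for rec in cds:
        lid = rec.id.split("_")[1].split(".")[0]
        seqs.setdefault(lid, set()).add(rec.seq)
    assert all(len(s) == 1 for s in seqs.values())


def test_planted_domains_recovered_by_scanner():
    history = simulate_family_history(_cfg())
    _, proteins = emit_sequences(history)
    for rec in proteins:
        cls = classify_pg(scan_domains(rec.seq))
        assert cls.composition == {"I", "II", "III", "IV"}


def test_omega_zero_means_zero_ka():
    a, b = evolve_pair(100, 0.2, omega=0.0, seed=1)
    result = ng86_kaks(a, b)
    assert result.ka == 0.0


def test_negative_omega_rejected():
    with pytest.raises(SimulationError):
        _cfg(omega=-0.5)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def test_planted_categories_recovered(fresh_history):
    ct = emit_expression(fresh_history)
    matrix = relative_expression(ct, REFERENCE_GENE, "root")
    for (a, b), planted in fresh_history.truth.planted_categories.items():
        cat = categorize_pair(matrix.row(a), matrix.row(b))
        assert cat.category == planted, (a, b, planted, cat)


def test_category_mix_all_one_category():
    cfg = _cfg(category_mix=(1.0, 0.0, 0.0, 0.0), tandem_rate=0.5)
    history = simulate_family_history(cfg)
    ct = emit_expression(history)
    matrix = relative_expression(ct, REFERENCE_GENE, "root")
    assert history.truth.planted_categories
    for (a, b) in history.truth.planted_categories:
        assert categorize_pair(matrix.row(a), matrix.row(b)).category == "I"


def test_category_iv_one_member_all_nd(fresh_history):
    ct = emit_expression(fresh_history)
    by_gene = {g: dict(zip(sub["sample"], sub["ct"]))
               for g, sub in ct.groupby("gene")}
    for (a, b), planted in fresh_history.truth.planted_categories.items():
        if planted == "IV":
            all_nd = [all(v == "ND" for v in by_gene[g].values()) for g in (a, b)]
            assert sum(all_nd) == 1


def test_too_few_tissues_rejected(fresh_history):
    with pytest.raises(SimulationError):
        emit_expression(fresh_history, _cfg(tissues=("root",)))


def test_reference_gene_constant(fresh_history):
    ct = emit_expression(fresh_history)
    ref = ct[ct["gene"] == REFERENCE_GENE]["ct"].unique()
    assert len(ref) == 1


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

CGTCA = MotifDefinition("CGTCA-motif", "hormone", "CGTCA")


def test_planted_motif_found(fresh_history):
    genes = fresh_history.genes()
    plants = {genes[0]: [("CGTCA-motif", "+")]}
    records = emit_promoters(fresh_history, [CGTCA], plants=plants)
    rec = next(r for r in records if r.id == genes[0])
    hits = scan_promoter(rec.seq, [CGTCA])
    planted = fresh_history.truth.planted_motifs[genes[0]][0]
    assert any(h.position == planted.position and h.strand == "+" for h in hits)


def test_minus_strand_plant_found_only_by_rc(fresh_history):
    genes = fresh_history.genes()
    plants = {genes[0]: [("CGTCA-motif", "-")]}
    records = emit_promoters(fresh_history, [CGTCA], plants=plants)
    rec = next(r for r in records if r.id == genes[0])
    planted = fresh_history.truth.planted_motifs[genes[0]][0]
    hits = scan_promoter(rec.seq, [CGTCA])
    assert any(h.position == planted.position and h.strand == "-" for h in hits)


def test_zero_plants_with_clean_background(fresh_history):
    cfg = _cfg(promoter_len=120)
    records = emit_promoters(fresh_history, [CGTCA], cfg, plants={},
                             background_free_of=[CGTCA])
    for rec in records:
        assert scan_promoter(rec.seq, [CGTCA]) == []


def test_motif_longer_than_promoter_rejected(fresh_history):
    long_motif = MotifDefinition("long", "x", "A" * 50)
    with pytest.raises(SimulationError):
        emit_promoters(fresh_history, [long_motif], _cfg(promoter_len=40),
                       plants={})


def test_all_planted_motifs_recoverable(fresh_history):
    from pgfam.cis_elements import load_motif_dictionary
    motifs = load_motif_dictionary()
    records = emit_promoters(fresh_history, motifs)
    by_id = {r.id: r for r in records}
    for gene, planted in fresh_history.truth.planted_motifs.items():
        hits = scan_promoter(by_id[gene].seq, motifs)
        for p in planted:
            assert any(h.name == p.name and h.position == p.position
                       and h.strand == p.strand for h in hits), (gene, p)


# ---------------------------------------------------------------------------
# Family tree helper
# ---------------------------------------------------------------------------

def test_family_tree_contains_all_genes(small_history):
    tree = family_tree(small_history)
    assert sorted(tree.tip_names()) == sorted(small_history.genes())
    assert tree.is_rooted


def test_true_paralog_pairs_same_species(small_history):
    for a, b in true_paralog_pairs(small_history):
        assert a.split("_")[0] == b.split("_")[0]
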