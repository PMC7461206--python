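import math

import numpy as np
import pytest

from pgfam.formats_io import SequenceRecord
from pgfam.phylogeny import (DistanceMatrix, PhylogenyError, assign_clades,
                             bootstrap_supports, midpoint_root, nj_tree,
                             poisson_distance_matrix)
from pgfam.tree import parse_newick, write_newick


def _dm(labels, d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(labels, d, np.ones_like(d, dtype=int))


# ---------------------------------------------------------------------------
# Poisson distances
# ---------------------------------------------------------------------------

def test_identical_sequences_zero_distance():
    dm = poisson_distance_matrix([SequenceRecord("a", "MKLV"),
                                  SequenceRecord("b", "MKLV")])
    assert dm.d[0, 1] == 0.0


def test_half_mismatches_closed_form():
    # p = 5/10 -> d = -ln(0.5)
    dm = poisson_distance_matrix([SequenceRecord("a", "AAAAAAAAAA"),
                                  SequenceRecord("b", "AAAAACCCCC")])
    assert dm.d[0, 1] == pytest.approx(-math.log(0.5))


def test_pairwise_deletion_excludes_gap_columns():
    dm = poisson_distance_matrix([SequenceRecord("a", "AA-A"),
                                  SequenceRecord("b", "AAAA")])
    assert dm.compared_sites[0, 1] == 3
    assert dm.d[0, 1] == 0.0


def test_saturated_pair_is_infinite():
    dm = poisson_distance_matrix([SequenceRecord("a", "AAAA"),
                                  SequenceRecord("b", "CCCC")])
    assert math.isinf(dm.d[0, 1])
    with pytest.raises(PhylogenyError):
        nj_tree(dm)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def test_two_taxa_edge_split():
    t = nj_tree(_dm(["A", "B"], [[0, 0.8], [0.8, 0]]))
    assert sum(tip.length for tip in t.tips()) == pytest.approx(0.8)


def test_three_taxa_closed_form():
    t = nj_tree(_dm(["A", "B", "C"], [[0, 0.3, 0.5],
                                      [0.3, 0, 0.6],
                                      [0.5, 0.6, 0]]))
    lengths = {tip.name: tip.length for tip in t.tips()}
    assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
    assert lengths["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
    assert lengths["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)


def test_additive_six_taxon_recovery():
    true = parse_newick("(((A:1,B:2):1,C:3):1,(D:1,E:2):2,F:4);")
    dists = true.tip_distances()
    names = sorted(true.tip_names())
    n = len(names)
    mat = np.zeros((n, n))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i != j:
                mat[i, j] = dists[tuple(sorted((a, b)))]
    recovered = nj_tree(_dm(names, mat))
    assert recovered.splits() == true.splits()
    rd = recovered.tip_distances()
    for key, value in dists.items():
        assert rd[key] == pytest.approx(value)


def test_nj_deterministic_under_ties():
    d = [[0, 2, 2, 2], [2, 0, 2, 2], [2, 2, 0, 2], [2, 2, 2, 0]]
    t1 = nj_tree(_dm(list("ABCD"), d))
    t2 = nj_tree(_dm(list("ABCD"), d))
    assert write_newick(t1) == write_newick(t2)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

ALN = [SequenceRecord("A", "AAAAAAAAGG"), SequenceRecord("B", "AAAAAAAAGC"),
       SequenceRecord("C", "CCCCAAAAGG"), SequenceRecord("D", "CCCCAAAAGC")]


def test_unanimous_signal_full_support():
    # every variable column supports AB|CD; constants pad against saturation
    aln = [SequenceRecord("A", "AAAAAAAATTTTTTTT"),
           SequenceRecord("B", "AAAAAAAATTTTTTTT"),
           SequenceRecord("C", "CCCCCCCCTTTTTTTT"),
           SequenceRecord("D", "CCCCCCCCTTTTTTTT")]
    t = bootstrap_supports(aln, 100, seed=0)
    supports = [n.support for n in t.root.preorder()
                if n.support is not None]
    assert supports and all(s == 100 for s in supports)


def test_bootstrap_deterministic_under_seed():
    t1 = bootstrap_supports(ALN, 50, seed=42)
    t2 = bootstrap_supports(ALN, 50, seed=42)
    assert write_newick(t1) == write_newick(t2)


def test_conflicting_signal_near_fifty():
    # 100 columns support AB|CD, 100 support AC|BD, 100 constant; many
    # columns keep resampled ties (broken deterministically) rare
    aln = [SequenceRecord("A", "A" * 100 + "G" * 100 + "T" * 100),
           SequenceRecord("B", "A" * 100 + "C" * 100 + "T" * 100),
           SequenceRecord("C", "C" * 100 + "G" * 100 + "T" * 100),
           SequenceRecord("D", "C" * 100 + "C" * 100 + "T" * 100)]
    t = bootstrap_supports(aln, 1000, seed=3)
    supports = [n.support for n in t.root.preorder() if n.support is not None]
    assert len(supports) == 1
    assert abs(supports[0] - 50) <= 5


def test_zero_reps_rejected():
    with pytest.raises(PhylogenyError):
        bootstrap_supports(ALN, 0, seed=1)


# ---------------------------------------------------------------------------
# Midpoint rooting
# ---------------------------------------------------------------------------

def test_midpoint_two_tips_equidistant():
    t = midpoint_root(parse_newick("(A:1.5,B:0.5);"))
    lengths = {tip.name: tip.length for tip in t.tips()}
    assert lengths["A"] == pytest.approx(1.0)
    assert lengths["B"] == pytest.approx(1.0)


def test_midpoint_on_chain():
    # tip path 1 + 2 + 3 = 6; midpoint 3.0 sits inside C's edge
    t = midpoint_root(parse_newick("(A:1,(B:2,C:3):0.5);"))
    dists = t.root.children
    lengths = sorted((c.length for c in dists))
    tip_d = t.tip_distances()
    assert tip_d[("B", "C")] == pytest.approx(5.0)
    # root equidistant from the two farthest tips
    depths = {}
    for tip in t.tips():
        d = 0.0
        node = tip
        while node.parent is not None:
            d += node.length or 0.0
            node = node.parent
        depths[tip.name] = d
    assert depths["B"] == pytest.approx(2.5)
    assert depths["C"] == pytest.approx(2.5)


def test_midpoint_preserves_tip_distance_multiset():
    t = parse_newick("((A:1,B:4):0.5,(C:2,D:1):0.25,E:6);")
    before = t.tip_distances()
    after = midpoint_root(t).tip_distances()
    for key, value in before.items():
        assert after[key] == pytest.approx(value)


def test_midpoint_preserves_supports_on_bipartitions():
    t = parse_newick("((A:1,B:4)88:0.5,(C:2,D:1)66:0.25,E:6);")
    rooted = midpoint_root(t)
    support_of_side = {}
    for node in rooted.root.preorder():
        if node.support is not None and not node.is_leaf:
            support_of_side[frozenset(x.name for x in node.tips())] = node.support
    assert support_of_side[frozenset({"C", "D"})] == 66
    assert support_of_side[frozenset({"A", "B"})] == 88


def test_zero_length_tree_rejected():
    with pytest.raises(PhylogenyError):
        midpoint_root(parse_newick("(A:0,B:0);"))


# ---------------------------------------------------------------------------
# Clade assignment
# ---------------------------------------------------------------------------

def test_tip_inherits_anchor_clade():
    t = parse_newick("((g1:1,anchC:1)90:1,(g2:1,anchD:1)95:1);")
    asn = assign_clades(t, {"anchC": "C", "anchD": "D"})
    assert asn.of("g1") == "C"
    assert asn.of("g2") == "D"


def test_mixed_clan_unassigned():
    # g1's smallest supported anchored clan holds anchors of two clades
    t = parse_newick("(((g1:1,anchC:1)40:1,anchD:1)90:1,(x:1,anchE:1)95:1);")
    asn = assign_clades(t, {"anchC": "C", "anchD": "D", "anchE": "E"})
    assert asn.of("g1") is None
    assert "g1" in asn.unassigned


def test_all_anchored_identity():
    t = parse_newick("((a:1,b:1)90:1,(c:1,d:1)90:1);")
    anchor_map = {"a": "A", "b": "A", "c": "B", "d": "B"}
    asn = assign_clades(t, anchor_map)
    assert asn.clades == anchor_map


def test_missing_anchor_rejected():
    t = parse_newick("(a:1,b:1);")
    with pytest.raises(PhylogenyError):
        assign_clades(t, {"zz": "C"})


def test_low_support_clan_skipped():
    # the 40-support cherry is not trusted; g1 climbs to the 90 clan -> C
    t = parse_newick("(((g1:1,other:1)40:1,anchC:1)90:1,(x:1,anchD:1)95:1);")
    asn = assign_clades(t, {"anchC": "C", "anchD": "D"})
    assert asn.of("g1") == "C"
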