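"""Family phylogeny: Poisson-corrected distances, neighbor joining,
bootstrap supports, midpoint rooting and anchor-based clade assignment.

Distances use pairwise deletion: alignment columns where either sequence of
a pair carries a gap/ambiguity character are excluded for that pair only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .formats_io import SequenceRecord
from .tree import Tree, TreeNode, reroot_on_edge

DEFAULT_AMBIGUOUS = frozenset("-X?")


class PhylogenyError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    compared_sites: np.ndarray

    def __post_init__(self):
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise PhylogenyError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise PhylogenyError("matrix not symmetric")

    @property
    def has_undefined(self) -> bool:
        return bool(np.isinf(self.d).any() or np.isnan(self.d).any())


def poisson_distance_matrix(alignment: list[SequenceRecord],
                            ambiguous: frozenset = DEFAULT_AMBIGUOUS) -> DistanceMatrix:
    """Poisson-corrected protein distance d = -ln(1 - p) with pairwise deletion.

    Pairs with no comparable sites or p >= 1 get an infinite entry, which
    :func:`nj_tree` refuses.
    """
    if len(alignment) < 2:
        raise PhylogenyError("need at least two sequences")
    lengths = {len(r.seq) for r in alignment}
    if len(lengths) != 1:
        raise PhylogenyError("alignment sequences differ in length")
    labels = [r.id for r in alignment]
    seqs = [r.seq.upper() for r in alignment]
    arr = np.array([list(s) for s in seqs])
    ok = ~np.isin(arr, sorted(ambiguous))
    n = len(labels)
    d = np.zeros((n, n))
    compared = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            compared[i, j] = compared[j, i] = m
            if m == 0:
                d[i, j] = d[j, i] = math.inf
                continue
            p = float((arr[i][both] != arr[j][both]).sum()) / m
            d[i, j] = d[j, i] = math.inf if p >= 1.0 else -math.log(1.0 - p)
    return DistanceMatrix(labels, d, compared)


# ---------------------------------------------------------------------------
# Neighbor joining (Saitou & Nei agglomeration)
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> Tree:
    """Unrooted NJ tree; negative branch-length estimates are clamped to zero
    with the deficit moved to the sister edge.  Ties in the Q criterion break
    on the lowest (row, column) index pair, so the result is deterministic.
    """
    if dm.has_undefined:
        raise PhylogenyError("distance matrix contains undefined entries")
    n = len(dm.labels)
    if n < 2:
        raise PhylogenyError("need at least two taxa")
    nodes = [TreeNode(name=label) for label in dm.labels]
    if n == 2:
        root = TreeNode()
        half = dm.d[0, 1] / 2.0
        for node in nodes:
            node.length = half
            root.add(node)
        return Tree(root)
    d = dm.d.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if best is None or q[a, b] < q[best] - 1e-12:
                    best = (a, b)
        a, b = best
        dij = sub[a, b]
        va = dij / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2))
        vb = dij - va
        if va < 0:
            vb, va = dij, 0.0
        elif vb < 0:
            va, vb = dij, 0.0
        i, j = active[a], active[b]
        parent = TreeNode()
        nodes[i].length = va
        nodes[j].length = vb
        parent.add(nodes[i])
        parent.add(nodes[j])
        # distances from the new node to the rest
        new_row = np.zeros(d.shape[0] + 1)
        for c in range(m):
            if c in (a, b):
                continue
            k = active[c]
            new_row[k] = max((sub[a, c] + sub[b, c] - dij) / 2.0, 0.0)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]
    # final three-way join
    root = TreeNode()
    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    vi = max((dij + dik - djk) / 2.0, 0.0)
    vj = max((dij + djk - dik) / 2.0, 0.0)
    vk = max((dik + djk - dij) / 2.0, 0.0)
    for idx, v in ((i, vi), (j, vj), (k, vk)):
        nodes[idx].length = v
        root.add(nodes[idx])
    return Tree(root)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_supports(alignment: list[SequenceRecord], n_reps: int = 1000,
                       seed: int | None = None,
                       ambiguous: frozenset = DEFAULT_AMBIGUOUS) -> Tree:
    """NJ tree of the full alignment with internal-node supports set to the
    percentage of column-resampled replicates containing each bipartition.
    """
    if n_reps < 1:
        raise PhylogenyError("n_reps must be >= 1")
    full = nj_tree(poisson_distance_matrix(alignment, ambiguous))
    length = len(alignment[0].seq)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    successful = 0
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        resampled = [SequenceRecord(r.id, "".join(r.seq[c] for c in cols), r.kind)
                     for r in alignment]
        try:
            rep_tree = nj_tree(poisson_distance_matrix(resampled, ambiguous))
        except PhylogenyError:
            continue  # saturated replicate: no information
        successful += 1
        for split in rep_tree.splits():
            counts[split] = counts.get(split, 0) + 1
    if successful == 0:
        raise PhylogenyError("all bootstrap replicates failed")
    all_tips = frozenset(full.tip_names())
    for node in full.root.preorder():
        if node is full.root or node.is_leaf:
            continue
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(all_tips) - len(side) < 2:
            continue
        from .tree import _canonical_split
        split = _canonical_split(side, all_tips)
        node.support = int(round(100.0 * counts.get(split, 0) / successful))
    return full


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------

def midpoint_root(tree: Tree) -> Tree:
    """Root at the midpoint of the longest tip-to-tip path."""
    work = tree.copy()
    dists = work.tip_distances()
    if not dists:
        raise PhylogenyError("tree has fewer than two tips")
    (u_name, v_name), diameter = max(dists.items(), key=lambda kv: (kv[1], kv[0]))
    if diameter <= 0:
        raise PhylogenyError("zero-length tree cannot be midpoint rooted")
    tips = {t.name: t for t in work.tips()}
    u, v = tips[u_name], tips[v_name]
    # path u -> LCA -> v as (edge child node, length, child_at_start_of_walk)
    anc_u = []
    node = u
    while node is not None:
        anc_u.append(node)
        node = node.parent
    anc_v_set = set()
    node = v
    while node is not None:
        anc_v_set.add(id(node))
        node = node.parent
    lca = next(a for a in anc_u if id(a) in anc_v_set)
    path: list[tuple[TreeNode, float, bool]] = []
    node = u
    while node is not lca:
        path.append((node, node.length or 0.0, True))
        node = node.parent
    down = []
    node = v
    while node is not lca:
        down.append((node, node.length or 0.0, False))
        node = node.parent
    path.extend(reversed(down))
    half = diameter / 2.0
    cum = 0.0
    for node, seg, child_at_start in path:
        if cum + seg >= half - 1e-12:
            dist_from_child = (half - cum) if child_at_start else (cum + seg - half)
            dist_from_child = min(max(dist_from_child, 0.0), seg)
            return reroot_on_edge(work, node, dist_from_child)
        cum += seg
    raise PhylogenyError("midpoint not found (inconsistent branch lengths)")


# ---------------------------------------------------------------------------
# Clade assignment
# ---------------------------------------------------------------------------

@dataclass
class CladeAssignment:
    clades: dict[str, str | None]

    def of(self, gene_id: str) -> str | None:
        return self.clades[gene_id]

    @property
    def unassigned(self) -> list[str]:
        return sorted(g for g, c in self.clades.items() if c is None)


def assign_clades(tree: Tree, anchor_map: dict[str, str],
                  support_threshold: int = 50) -> CladeAssignment:
    """Propagate anchor clades to unanchored tips.

    Each unanchored tip takes the clade of the smallest well-supported
    (support >= threshold, or support absent) ancestor clan that contains at
    least one anchor; a clan holding anchors of several clades marks the tip
    unassigned.
    """
    work = tree if tree.is_rooted else midpoint_root(tree)
    tip_names = set(work.tip_names())
    missing = set(anchor_map) - tip_names
    if missing:
        raise PhylogenyError(f"anchors absent from tree: {sorted(missing)}")
    result: dict[str, str | None] = {}
    tips = {t.name: t for t in work.tips()}
    for name, tip in tips.items():
        if name in anchor_map:
            result[name] = anchor_map[name]
            continue
        assigned: str | None = None
        node = tip.parent
        while node is not None:
            well_supported = node.support is None or node.support >= support_threshold
            if well_supported:
                clades = {anchor_map[t.name] for t in node.tips()
                          if t.name in anchor_map}
                if len(clades) == 1:
                    assigned = clades.pop()
                    break
                if len(clades) > 1:
                    break  # conflict: smallest supported anchored clan is mixed
            node = node.parent
        result[name] = assigned
    return CladeAssignment(result)
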