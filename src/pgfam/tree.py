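"""Phylogenetic tree structure with Newick parsing and writing.

Trees carry branch lengths (substitutions/site) and optional integer
bootstrap supports (0-100) on internal nodes.  Tip species is encoded as a
label prefix ("A_", "B_", "At_", "Bo_", ...) split on a configurable
separator.
"""

from __future__ import annotations

from typing import Iterator


class NewickError(ValueError):
    """Raised for malformed Newick text or invalid tree values."""


class TreeNode:
    """A node; the edge *above* the node carries ``length`` and ``support``."""

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: str | None = None, length: float | None = None,
                 support: int | None = None):
        self.name = name
        self.length = length
        self.support = support
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["TreeNode"]:
        out: list[TreeNode] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> list["TreeNode"]:
        return [n for n in self.preorder() if n.is_leaf]

    def copy(self) -> "TreeNode":
        clone = TreeNode(self.name, self.length, self.support)
        for child in self.children:
            clone.add(child.copy())
        return clone

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<TreeNode {self.name or '(internal)'}>"


class Tree:
    """A rooted or unrooted (root trifurcation) tree."""

    def __init__(self, root: TreeNode):
        self.root = root
        names = [t.name for t in root.tips()]
        if len(names) != len(set(names)):
            raise NewickError("duplicate tip labels")

    def tips(self) -> list[TreeNode]:
        return self.root.tips()

    def tip_names(self) -> list[str]:
        return [t.name for t in self.tips()]

    def copy(self) -> "Tree":
        return Tree(self.root.copy())

    @property
    def is_rooted(self) -> bool:
        return len(self.root.children) == 2

    def species_of(self, tip_name: str, sep: str = "_") -> str:
        if sep not in tip_name:
            raise ValueError(f"tip {tip_name!r} has no species prefix (sep={sep!r})")
        return tip_name.split(sep, 1)[0]

    # -- metric helpers ---------------------------------------------------

    def tip_distances(self) -> dict[tuple[str, str], float]:
        """All pairwise tip-to-tip path lengths (unordered pairs, sorted keys)."""
        dists: dict[tuple[str, str], float] = {}
        # distance from every node to tips below it, merged at internal nodes
        below: dict[TreeNode, dict[str, float]] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                below[node] = {node.name: 0.0}
                continue
            merged: dict[str, float] = {}
            kids = [below[c] for c in node.children]
            lens = [c.length or 0.0 for c in node.children]
            for i in range(len(kids)):
                for j in range(i + 1, len(kids)):
                    for na, da in kids[i].items():
                        for nb, db in kids[j].items():
                            key = (na, nb) if na < nb else (nb, na)
                            dists[key] = da + lens[i] + db + lens[j]
            for k, d, ln in zip(range(len(kids)), kids, lens):
                for name, dist in d.items():
                    merged[name] = dist + ln
            below[node] = merged
        return dists

    # -- bipartitions -----------------------------------------------------

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalised to its smaller side
        (ties broken lexicographically)."""
        all_tips = frozenset(self.tip_names())
        out: set[frozenset[str]] = set()
        for node in self.root.preorder():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(t.name for t in node.tips())
            if len(side) >= 2 and len(all_tips) - len(side) >= 2:
                out.add(_canonical_split(side, all_tips))
        return out

    def __str__(self) -> str:
        return write_newick(self)


def _canonical_split(side: frozenset[str], all_tips: frozenset[str]) -> frozenset[str]:
    other = all_tips - side
    if (len(side), tuple(sorted(side))) <= (len(other), tuple(sorted(other))):
        return side
    return other


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> Tree:
    """Parse a Newick string; numeric internal labels become supports."""
    text = text.strip()
    if not text:
        raise NewickError("empty Newick string")
    if not text.endswith(";"):
        raise NewickError("Newick must end with ';'")
    body = text[:-1]
    pos = 0

    def parse_clade() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(body) and body[pos] == "(":
            pos += 1
            while True:
                node.add(parse_clade())
                if pos >= len(body):
                    raise NewickError("unbalanced parentheses")
                if body[pos] == ",":
                    pos += 1
                    continue
                if body[pos] == ")":
                    pos += 1
                    break
                raise NewickError(f"unexpected character {body[pos]!r} at {pos}")
        # label
        start = pos
        while pos < len(body) and body[pos] not in ",():;":
            pos += 1
        label = body[start:pos].strip()
        if label:
            if node.is_leaf:
                node.name = label
            else:
                try:
                    node.support = int(round(float(label)))
                except ValueError:
                    node.name = label
                else:
                    if not 0 <= node.support <= 100:
                        raise NewickError(f"support {label} outside 0-100")
        # branch length
        if pos < len(body) and body[pos] == ":":
            pos += 1
            start = pos
            while pos < len(body) and body[pos] not in ",():;":
                pos += 1
            try:
                node.length = float(body[start:pos])
            except ValueError as exc:
                raise NewickError(f"bad branch length {body[start:pos]!r}") from exc
            if node.length < 0:
                raise NewickError(f"negative branch length {node.length}")
        return node

    root = parse_clade()
    if pos != len(body):
        raise NewickError(f"trailing characters after position {pos}: {body[pos:]!r}")
    if root.is_leaf and root.name is None:
        raise NewickError("empty tree")
    return Tree(root)


def write_newick(tree: Tree) -> str:
    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            s = node.name or ""
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.support is not None:
                s += str(int(node.support))
            elif node.name:
                s += node.name
        if node.length is not None:
            s += f":{_fmt_len(node.length)}"
        return s

    return fmt(tree.root) + ";"


def _fmt_len(x: float) -> str:
    s = f"{x:.6f}".rstrip("0").rstrip(".")
    return s or "0"


# ---------------------------------------------------------------------------
# Rerooting
# ---------------------------------------------------------------------------

def reroot_on_edge(tree: Tree, child: TreeNode, dist_from_child: float) -> Tree:
    """Root the tree on the edge above ``child``, ``dist_from_child`` away
    from it.  ``child`` must belong to ``tree`` and have a parent.  Supports
    stay attached to the same bipartitions.  Operates on (and consumes) the
    given tree's nodes; pass a copy if the original must survive.
    """
    if child.parent is None:
        raise ValueError("cannot reroot on the root's own edge")
    edge_len = child.length if child.length is not None else 0.0
    if not 0.0 <= dist_from_child <= edge_len + 1e-12:
        raise ValueError("dist_from_child outside the edge")
    edge_sup = child.support
    parent = child.parent
    parent.children.remove(child)
    child.parent = None
    new_root = TreeNode()
    child.length = dist_from_child
    new_root.add(child)
    _invert_up(parent)
    parent.length = edge_len - dist_from_child
    parent.support = edge_sup
    new_root.add(parent)
    _suppress_unifurcations(new_root)
    return Tree(new_root)


def _invert_up(node: TreeNode) -> TreeNode:
    """Re-hang all former ancestors of ``node`` beneath it."""
    p = node.parent
    if p is None:
        return node
    up_len, up_sup = node.length, node.support
    node.parent = None
    p.children.remove(node)
    _invert_up(p)
    p.length = up_len
    p.support = up_sup
    node.add(p)
    node.length = None
    node.support = None
    return node


def _suppress_unifurcations(root: TreeNode) -> None:
    for node in list(root.preorder()):
        for child in list(node.children):
            while len(child.children) == 1:
                grand = child.children[0]
                grand.length = (grand.length or 0.0) + (child.length or 0.0)
                if grand.support is None:
                    grand.support = child.support
                idx = node.children.index(child)
                node.children[idx] = grand
                grand.parent = node
                child = grand
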