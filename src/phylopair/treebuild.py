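"""Neighbor-joining tree construction, Newick IO and patristic distances.

Trees are stored with a rooted data structure but interpreted as unrooted:
the product of neighbor joining on >= 3 taxa is a root of degree 3 (the last
three-way join), and all topology comparisons go through unrooted
bipartitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "TreeError",
    "NewickError",
    "neighbor_joining",
    "patristic_matrix",
    "parse_newick",
    "write_newick",
]


class TreeError(ValueError):
    pass


class NewickError(TreeError):
    """Newick parse failure; carries the 0-based offset of the failure."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative matrix with zero diagonal over ordered taxa."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        n = len(self.ids)
        if m.shape != (n, n):
            raise TreeError(f"matrix shape {m.shape} does not match {n} taxa")
        if len(set(self.ids)) != n:
            raise TreeError("taxon ids must be unique")
        if not np.all(np.isfinite(m)):
            raise TreeError("distance matrix must be finite")
        if np.any(m < 0):
            raise TreeError("distance matrix must be nonnegative")
        if not np.allclose(m, m.T, atol=1e-9):
            raise TreeError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-9):
            raise TreeError("distance matrix diagonal must be zero")

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])


class TreeNode:
    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float | None = None):
        self.name = name
        self.length = length  # length of the edge to the parent
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def traverse(self):
        yield self
        for c in self.children:
            yield from c.traverse()


@dataclass
class PhyloTree:
    """Tree with branch lengths; leaf labels unique.  Unrooted semantics."""

    root: TreeNode
    _leafmap: dict[str, TreeNode] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        names = [l.name for l in self.root.leaves()]
        if any(n is None or n == "" for n in names):
            raise TreeError("all leaves must be labeled")
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise TreeError(f"duplicate leaf labels: {dup}")
        self._leafmap = {l.name: l for l in self.root.leaves()}

    @property
    def leaf_names(self) -> list[str]:
        return [l.name for l in self.root.leaves()]

    def leaf(self, name: str) -> TreeNode:
        try:
            return self._leafmap[name]
        except KeyError as exc:
            raise TreeError(f"no leaf named {name!r}") from exc

    def copy(self) -> "PhyloTree":
        return parse_newick(write_newick(self))

    def scale_branches(self, factor: float) -> "PhyloTree":
        t = self.copy()
        for node in t.root.traverse():
            if node.length is not None:
                node.length *= factor
        return t

    def bipartitions(self, restrict_to: set[str] | None = None) -> set[frozenset[str]]:
        """Non-trivial unrooted bipartitions, each encoded canonically as the
        side not containing the reference (lexicographically smallest) leaf.

        With *restrict_to*, bipartitions are projected onto that leaf subset
        first (equivalent to pruning the tree to the subset).
        """
        all_leaves = set(self.leaf_names)
        keep = all_leaves if restrict_to is None else (all_leaves & set(restrict_to))
        if not keep:
            return set()
        ref = min(keep)
        out: set[frozenset[str]] = set()
        for node in self.root.traverse():
            if node is self.root or node.is_leaf():
                continue
            side = {l.name for l in node.leaves()} & keep
            if ref in side:
                side = keep - side
            if 2 <= len(side) <= len(keep) - 2:
                out.add(frozenset(side))
        return out

    def newick(self) -> str:
        return write_newick(self)


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Classical agglomerative neighbor joining.

    At each step the pair minimizing the Q-criterion is joined; branch
    lengths come from the standard two-point formulas, with negative
    estimates clamped to zero and the deficit moved to the sibling branch.
    Ties in Q are broken by the lexicographically smallest (label, label)
    pair, where an internal node carries the smallest leaf label below it.
    """
    n = len(D.ids)
    if n < 2:
        raise TreeError("neighbor joining requires at least 2 taxa")
    if n == 2:
        root = TreeNode()
        a = TreeNode(D.ids[0], float(D.matrix[0, 1]) / 2)
        b = TreeNode(D.ids[1], float(D.matrix[0, 1]) / 2)
        root.add(a)
        root.add(b)
        return PhyloTree(root)

    nodes: list[TreeNode] = [TreeNode(name) for name in D.ids]
    labels: list[str] = list(D.ids)  # sort key: min leaf label under node
    d = np.array(D.matrix, dtype=float)

    def clamp(la: float, lb: float) -> tuple[float, float]:
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        return la, max(lb, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] <= qmin + 1e-12:
                    key = tuple(sorted((labels[i], labels[j])))
                    if best is None or key < best[0]:
                        best = (key, i, j)
        _, i, j = best
        la = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lb = d[i, j] - la
        la, lb = clamp(la, lb)
        new = TreeNode()
        ci, cj = nodes[i], nodes[j]
        ci.length, cj.length = la, lb
        new.add(ci)
        new.add(cj)

        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = dnew[keep]
        d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        d = d2
        nodes = [nodes[k] for k in keep] + [new]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]

    # final three-way join (three-point formulas)
    root = TreeNode()
    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    for node, ln in sorted(zip((a, b, c), (la, lb, lc)), key=lambda p: labels[nodes.index(p[0])]):
        node.length = max(float(ln), 0.0)
        root.add(node)
    return PhyloTree(root)


def patristic_matrix(tree: PhyloTree, ids: list[str] | None = None) -> DistanceMatrix:
    """Path-length (patristic) distances between all leaf pairs."""
    if ids is None:
        ids = sorted(tree.leaf_names)
    # distance from root to every node
    depth: dict[int, float] = {id(tree.root): 0.0}
    parent: dict[int, TreeNode] = {}
    for node in tree.root.traverse():
        for c in node.children:
            if c.length is None:
                raise TreeError("patristic distances require branch lengths on all edges")
            depth[id(c)] = depth[id(node)] + float(c.length)
            parent[id(c)] = node

    def path_to_root(node: TreeNode) -> list[TreeNode]:
        out = [node]
        while id(node) in parent:
            node = parent[id(node)]
            out.append(node)
        return out

    leaves = {name: tree.leaf(name) for name in ids}
    n = len(ids)
    mat = np.zeros((n, n))
    anc_cache = {name: path_to_root(leaves[name]) for name in ids}
    for i in range(n):
        anc_i = {id(x) for x in anc_cache[ids[i]]}
        for j in range(i + 1, n):
            lca = next(x for x in anc_cache[ids[j]] if id(x) in anc_i)
            dij = depth[id(leaves[ids[i]])] + depth[id(leaves[ids[j]])] - 2 * depth[id(lca)]
            mat[i, j] = mat[j, i] = dij
    return DistanceMatrix(ids, mat)


# ---------------------------------------------------------------------------
# Newick

_SPECIALS = set("(),:;")


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string (names, optional branch lengths, nesting)."""
    s = text.strip()
    if not s:
        raise NewickError("empty Newick string", 0)
    pos = 0

    def error(msg: str) -> NewickError:
        return NewickError(msg, pos)

    def parse_clade() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.add(parse_clade())
                if pos >= len(s):
                    raise error("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise error(f"unexpected character {s[pos]!r}")
        # optional label
        start = pos
        while pos < len(s) and s[pos] not in _SPECIALS:
            pos += 1
        label = s[start:pos].strip()
        if label:
            node.name = label
        # optional branch length
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in _SPECIALS:
                pos += 1
            try:
                node.length = float(s[start:pos])
            except ValueError:
                raise error(f"invalid branch length {s[start:pos]!r}")
        return node

    root = parse_clade()
    if pos >= len(s) or s[pos] != ";":
        raise error("expected ';' at end of tree")
    if root.is_leaf() and root.name is None:
        raise error("tree has no content")
    return PhyloTree(root)


def write_newick(tree: PhyloTree) -> str:
    def fmt(node: TreeNode) -> str:
        if node.is_leaf():
            core = node.name or ""
        else:
            core = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                core += node.name
        if node.length is not None:
            core += f":{node.length:.10g}"
        return core

    return fmt(tree.root) + ";"
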