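"""Lightweight rooted/unrooted phylogenetic trees.

A tree is stored rooted; unrooted semantics (splits, Robinson-Foulds,
nearest-neighbour interchange) treat the root as an anonymous internal
vertex.  Branch lengths live on the edge above each node.  This module is
deliberately small: it supports exactly what the neighbour-joining,
hierarchical-clustering and Bayesian machinery need, and round-trips
through Newick so external tools can consume every tree we write.
"""

from __future__ import annotations

import numpy as np


class Node:
    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float | None = None):
        self.name = name
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, {self.length!r}, {len(self.children)} children)"


class Tree:
    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------ IO
    @classmethod
    def from_newick(cls, s: str) -> "Tree":
        s = s.strip()
        if s.endswith(";"):
            s = s[:-1]
        pos = 0

        def parse_node() -> Node:
            nonlocal pos
            node = Node()
            if s[pos] == "(":
                pos += 1
                while True:
                    node.add(parse_node())
                    if s[pos] == ",":
                        pos += 1
                        continue
                    if s[pos] == ")":
                        pos += 1
                        break
            # label (possibly with :length)
            start = pos
            while pos < len(s) and s[pos] not in ",();":
                pos += 1
            label = s[start:pos]
            if label:
                name, _, length = label.partition(":")
                node.name = name or None
                if length:
                    node.length = float(length)
            return node

        root = parse_node()
        if pos != len(s):
            raise ValueError(f"trailing characters in newick string: {s[pos:]!r}")
        return cls(root)

    def to_newick(self, lengths: bool = True, fmt: str = "%.6g") -> str:
        def render(node: Node) -> str:
            if node.is_leaf:
                out = node.name or ""
            else:
                out = "(" + ",".join(render(c) for c in node.children) + ")"
                if node.name:
                    out += node.name
            if lengths and node.length is not None:
                out += ":" + (fmt % node.length)
            return out

        return render(self.root) + ";"

    # ------------------------------------------------------------ traversal
    def postorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        out.reverse()
        return out

    def preorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def edges(self) -> list[Node]:
        """Every node below the root; each carries the branch above it."""
        return [n for n in self.postorder() if n is not self.root]

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            c = Node(node.name, node.length)
            for child in node.children:
                c.add(clone(child))
            return c

        return Tree(clone(self.root))

    def total_length(self) -> float:
        return float(sum(n.length or 0.0 for n in self.edges()))

    # ------------------------------------------------------------- unrooted
    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalised to the side that does
        not contain the lexicographically smallest leaf."""
        names = set(self.leaf_names())
        ref = min(names)
        out: set[frozenset[str]] = set()
        below: dict[int, set[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = {node.name}
            else:
                acc: set[str] = set()
                for c in node.children:
                    acc |= below[id(c)]
                below[id(node)] = acc
            if node is self.root:
                continue
            side = below[id(node)]
            if 1 < len(side) < len(names) - 1:
                out.add(frozenset(side if ref not in side else names - side))
        return out

    def rf_distance(self, other: "Tree") -> int:
        if set(self.leaf_names()) != set(other.leaf_names()):
            raise ValueError("trees have different leaf sets")
        a, b = self.splits(), other.splits()
        return len(a ^ b)

    def has_clade(self, taxa: frozenset[str]) -> bool:
        """True if `taxa` forms one side of a bipartition (unrooted clade)."""
        names = set(self.leaf_names())
        taxa = frozenset(taxa)
        if not taxa <= names:
            raise ValueError("clade contains unknown taxa")
        if len(taxa) <= 1 or len(taxa) >= len(names) - 1:
            return True
        ref = min(names)
        canon = taxa if ref not in taxa else frozenset(names - taxa)
        return canon in self.splits()

    # ---------------------------------------------------------- path metric
    def distance_matrix(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf path-length matrix (sums of branch lengths)."""
        leaves = self.leaves()
        names = [n.name for n in leaves]
        idx = {id(n): i for i, n in enumerate(leaves)}
        m = len(leaves)
        dist = np.zeros((m, m))
        below: dict[int, list[tuple[int, float]]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = [(idx[id(node)], 0.0)]
                continue
            groups = []
            for c in node.children:
                bl = c.length or 0.0
                groups.append([(i, d + bl) for i, d in below[id(c)]])
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for i, di in groups[gi]:
                        for j, dj in groups[gj]:
                            dist[i, j] = dist[j, i] = di + dj
            below[id(node)] = [p for g in groups for p in g]
        return names, dist


# ---------------------------------------------------------------------------
# random constrained topologies


def random_tree(
    names: list[str],
    rng: np.random.Generator,
    constraints: list[frozenset[str]] | None = None,
    branch_length: float | None = None,
) -> Tree:
    """Random topology over `names` by sequential addition, with each
    constrained clade (nested or disjoint taxon subsets) kept monophyletic.

    Constraints are honoured by building each maximal clade as a unit and
    recursing, so every draw satisfies all of them by construction.
    """
    constraints = [frozenset(c) for c in (constraints or [])]
    for a in constraints:
        for b in constraints:
            if a is not b and a & b and not (a <= b or b <= a):
                raise ValueError("constraints must be nested or disjoint")

    def build(taxa: list[str], active: list[frozenset[str]]) -> Node:
        maximal = [c for c in active if len(c) < len(taxa)]
        maximal = [c for c in maximal if not any(c < d and len(d) < len(taxa) for d in maximal)]
        units: list[Node] = []
        used: set[str] = set()
        for clade in maximal:
            inner = [d for d in active if d < clade]
            units.append(build(sorted(clade), inner))
            used |= clade
        for t in taxa:
            if t not in used:
                units.append(Node(t))
        if len(units) == 1:
            return units[0]
        # random sequential attachment; only edges created at this level are
        # candidates, so previously built constraint clades stay intact
        order = list(rng.permutation(len(units)))
        root = Node()
        root.add(units[order[0]])
        root.add(units[order[1]])
        level_edges = [units[order[0]], units[order[1]]]
        for k in order[2:]:
            target = level_edges[int(rng.integers(len(level_edges)))]
            parent = target.parent
            mid = Node()
            parent.children[parent.children.index(target)] = mid
            mid.parent = parent
            mid.add(target)
            mid.add(units[k])
            level_edges.extend([mid, units[k]])
        return root

    root = build(sorted(names), constraints)
    tree = Tree(root)
    if branch_length is not None:
        for n in tree.edges():
            n.length = float(branch_length)
    return tree


# ---------------------------------------------------------------------------
# unrooting and nearest-neighbour interchange


def unroot(tree: Tree) -> Tree:
    """Collapse a degree-2 root into a trifurcation (in place).

    The two root-child branches are merged onto the surviving child, giving
    the standard unrooted representation with 2n-3 identifiable branches.
    """
    root = tree.root
    if len(root.children) != 2:
        return tree
    a, b = root.children
    if b.is_leaf:
        a, b = b, a
    if b.is_leaf:
        raise ValueError("cannot unroot a two-leaf tree")
    a.length = (a.length or 0.0) + (b.length or 0.0)
    root.children = [a] + b.children
    for c in b.children:
        c.parent = root
    b.children = []
    return tree


def internal_edges(tree: Tree) -> list[Node]:
    """Child nodes of internal edges in the unrooted sense: internal,
    non-root nodes.  With a trifurcating root this is exactly the n-3
    internal branches of the unrooted tree."""
    return [n for n in tree.postorder() if n is not tree.root and not n.is_leaf]


def nni(tree: Tree, edge_child: Node, sib_index: int, child_index: int) -> None:
    """In-place NNI across the edge (parent(edge_child), edge_child): swap
    the `sib_index`-th sibling subtree of `edge_child` with its
    `child_index`-th child subtree.

    Choosing the edge, sibling and child uniformly at random yields a
    symmetric proposal on unrooted topologies (sibling/child counts per edge
    are invariant under the move), as required by Metropolis-Hastings.
    """
    parent = edge_child.parent
    if parent is None or edge_child.is_leaf:
        raise ValueError("NNI requires an internal, non-root edge child")
    siblings = [c for c in parent.children if c is not edge_child]
    sib = siblings[sib_index % len(siblings)]
    child = edge_child.children[child_index % len(edge_child.children)]
    pi = parent.children.index(sib)
    ci = edge_child.children.index(child)
    parent.children[pi] = child
    child.parent = parent
    edge_child.children[ci] = sib
    sib.parent = edge_child
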