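"""Lightweight phylogenetic tree structure for binary-character parsimony.

Trees are stored as an adjacency map over integer node ids; tip ``i``
corresponds to ``taxa[i]``.  Unrooted trees have internal nodes of degree
three; a rooted tree additionally carries one degree-2 root.  The class
supports the operations the parsimony machinery needs: split extraction,
newick serialization, topology enumeration for exhaustive search, and
random tree generation.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator

import numpy as np


class TreeError(ValueError):
    """Raised for structurally invalid trees or invalid tree operations."""


class PhyloTree:
    """Unrooted (or a-posteriori rooted) tree over a fixed taxon set.

    Attributes
    ----------
    taxa : list[str]
        Tip labels; tip node ``i`` is ``taxa[i]``.
    adj : dict[int, set[int]]
        Adjacency map.  Node ids >= ``len(taxa)`` are internal.
    rooted : bool
        True once a degree-2 root has been inserted.
    root : int | None
        The root node id when rooted.
    support : dict[frozenset[str], float]
        Optional per-split bootstrap support (percent, 0-100).
    total_length : int | None
        Parsimony steps of the tree on the matrix it was inferred from.
    """

    def __init__(self, taxa: Iterable[str]):
        self.taxa: list[str] = list(taxa)
        if len(set(self.taxa)) != len(self.taxa):
            raise TreeError("duplicate taxon labels")
        self.adj: dict[int, set[int]] = {}
        self.rooted: bool = False
        self.root: int | None = None
        self.support: dict[frozenset[str], float] = {}
        self.total_length: int | None = None
        self._next_id = len(self.taxa)

    # -- construction ----------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.taxa)

    def new_node(self) -> int:
        nid = self._next_id
        self._next_id += 1
        self.adj[nid] = set()
        return nid

    def add_edge(self, u: int, v: int) -> None:
        self.adj.setdefault(u, set()).add(v)
        self.adj.setdefault(v, set()).add(u)

    def remove_edge(self, u: int, v: int) -> None:
        self.adj[u].discard(v)
        self.adj[v].discard(u)

    def copy(self) -> "PhyloTree":
        t = PhyloTree(self.taxa)
        t.adj = {k: set(v) for k, v in self.adj.items()}
        t.rooted = self.rooted
        t.root = self.root
        t.support = dict(self.support)
        t.total_length = self.total_length
        t._next_id = self._next_id
        return t

    @classmethod
    def star(cls, taxa: Iterable[str]) -> "PhyloTree":
        """Star tree: all tips joined at a single internal node."""
        t = cls(taxa)
        hub = t.new_node()
        for i in range(t.n_tips):
            t.add_edge(i, hub)
        return t

    @classmethod
    def from_newick(cls, newick: str, taxa: Iterable[str] | None = None) -> "PhyloTree":
        """Parse a newick string (topology only; lengths/labels ignored).

        If ``taxa`` is given, tip ids follow that order; otherwise tips are
        numbered by appearance.  A top-level bifurcation is kept as a
        degree-2 root; a trifurcation yields an unrooted tree.
        """
        s = newick.strip().rstrip(";")
        pos = 0

        def parse() -> tuple:
            nonlocal pos
            if s[pos] == "(":
                pos += 1
                children = [parse()]
                while s[pos] == ",":
                    pos += 1
                    children.append(parse())
                if s[pos] != ")":
                    raise TreeError(f"unbalanced newick at position {pos}")
                pos += 1
                # skip internal label / branch length
                while pos < len(s) and s[pos] not in ",()":
                    pos += 1
                return tuple(children)
            j = pos
            while j < len(s) and s[j] not in ",():":
                j += 1
            name = s[pos:j]
            pos = j
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            return (name.strip(),)

        structure = parse()

        names: list[str] = []

        def collect(node) -> None:
            if len(node) == 1 and isinstance(node[0], str):
                names.append(node[0])
            else:
                for c in node:
                    collect(c)

        collect(structure)
        order = list(taxa) if taxa is not None else names
        t = cls(order)
        index = {name: i for i, name in enumerate(order)}

        def build(node) -> int:
            if len(node) == 1 and isinstance(node[0], str):
                return index[node[0]]
            nid = t.new_node()
            for c in node:
                t.add_edge(nid, build(c))
            return nid

        top = build(structure)
        if len(t.adj.get(top, ())) == 2:
            t.rooted = True
            t.root = top
        return t

    # -- structure queries -----------------------------------------------

    def nodes(self) -> list[int]:
        return sorted(self.adj)

    def edges(self) -> list[tuple[int, int]]:
        """Undirected edges as sorted (u, v) pairs, deterministic order."""
        return sorted(
            (min(u, v), max(u, v)) for u in self.adj for v in self.adj[u] if u < v
        )

    def degree(self, node: int) -> int:
        return len(self.adj[node])

    def validate(self) -> None:
        """Check connectivity, acyclicity and degree constraints."""
        nodes = self.nodes()
        n_edges = sum(len(v) for v in self.adj.values()) // 2
        if n_edges != len(nodes) - 1:
            raise TreeError("tree is not acyclic/connected (edge count)")
        seen = {nodes[0]}
        stack = [nodes[0]]
        while stack:
            u = stack.pop()
            for v in self.adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        if len(seen) != len(nodes):
            raise TreeError("tree is disconnected")
        for u in nodes:
            d = self.degree(u)
            if u < self.n_tips:
                if d != 1:
                    raise TreeError(f"tip {u} has degree {d}")
            elif self.rooted and u == self.root:
                if d != 2:
                    raise TreeError("root must have degree 2")
            elif d != 3:
                raise TreeError(f"internal node {u} has degree {d}")

    def postorder(self, root: int | None = None) -> list[tuple[int, int]]:
        """(node, parent) pairs, children before parents; root parent = -1."""
        if root is None:
            root = self.root if self.rooted else self.n_tips
            if root not in self.adj:
                root = max(self.adj)
        order: list[tuple[int, int]] = []
        stack = [(root, -1)]
        n_nodes = len(self.adj)
        while stack:
            node, parent = stack.pop()
            order.append((node, parent))
            if len(order) > n_nodes:
                raise TreeError("cycle detected during traversal")
            for child in self.adj[node]:
                if child != parent:
                    stack.append((child, node))
        order.reverse()
        return order

    def splits(self) -> set[frozenset[str]]:
        """Nontrivial splits, each as the tip-label set not containing taxa[0].

        Only internal edges contribute; the side excluding the first taxon
        canonicalizes each bipartition.  A rooted tree yields the splits of
        its underlying unrooted topology.
        """
        result: set[frozenset[str]] = set()
        for side in self._edge_sides():
            if 1 < len(side) < self.n_tips - 1:
                if self.taxa[0] in side:
                    side = set(range(self.n_tips)) - {self.taxa.index(x) for x in side}
                    side = {self.taxa[i] for i in side}
                result.add(frozenset(side))
        return result

    def _edge_sides(self) -> Iterator[set[str]]:
        for u, v in self.edges():
            yield self.tips_below(v, u)

    def tips_below(self, node: int, parent: int) -> set[str]:
        """Tip labels in the component of ``node`` when edge to parent is cut."""
        seen = {parent, node}
        stack = [node]
        tips: set[str] = set()
        while stack:
            u = stack.pop()
            if u < self.n_tips:
                tips.add(self.taxa[u])
            for w in self.adj[u]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return tips

    def topology_key(self) -> frozenset[frozenset[str]]:
        """Canonical identifier of the unrooted topology (its split set)."""
        return frozenset(self.splits())

    # -- serialization ---------------------------------------------------

    def newick(self, with_support: bool = False) -> str:
        """Newick string; bootstrap supports become internal node labels."""
        if self.rooted:
            start = self.root
        else:
            start = self.n_tips if self.n_tips in self.adj else max(self.adj)

        def fmt(node: int, parent: int) -> str:
            if node < self.n_tips:
                return _quote_newick(self.taxa[node])
            parts = [fmt(c, node) for c in sorted(self.adj[node]) if c != parent]
            label = ""
            if with_support and parent != -1:
                side = self.tips_below(node, parent)
                key = frozenset(side)
                if self.taxa[0] in side:
                    key = frozenset(set(self.taxa) - side)
                if key in self.support:
                    label = f"{self.support[key]:g}"
            return "(" + ",".join(parts) + ")" + label

        return fmt(start, -1) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree {self.n_tips} tips rooted={self.rooted}>"


def _quote_newick(name: str) -> str:
    if any(c in name for c in " (),:;'[]"):
        return "'" + name.replace("'", "''") + "'"
    return name


# -- tree generation ----------------------------------------------------


def _attach_tip(tree: PhyloTree, tip: int, edge: tuple[int, int]) -> int:
    """Subdivide ``edge`` with a new node and hang ``tip`` from it."""
    u, v = edge
    tree.remove_edge(u, v)
    w = tree.new_node()
    tree.add_edge(u, w)
    tree.add_edge(w, v)
    tree.add_edge(w, tip)
    return w


def random_tree(taxa: Iterable[str], rng: np.random.Generator) -> PhyloTree:
    """Uniform-ish random unrooted binary tree by random sequential addition."""
    taxa = list(taxa)
    if len(taxa) < 3:
        raise TreeError("need >= 3 taxa for an unrooted tree")
    t = PhyloTree(taxa)
    hub = t.new_node()
    for i in range(3):
        t.add_edge(i, hub)
    for tip in range(3, len(taxa)):
        edges = t.edges()
        edge = edges[int(rng.integers(len(edges)))]
        _attach_tip(t, tip, edge)
    return t


def enumerate_topologies(taxa: Iterable[str]) -> Iterator[PhyloTree]:
    """All distinct unrooted binary topologies ((2n-5)!! trees).

    Generated by sequential addition of taxa in order, branching over every
    attachment edge.  Practical for n <= 8 (10,395 trees).
    """
    taxa = list(taxa)
    if len(taxa) < 3:
        raise TreeError("need >= 3 taxa")
    base = PhyloTree(taxa)
    hub = base.new_node()
    for i in range(3):
        base.add_edge(i, hub)

    def expand(tree: PhyloTree, next_tip: int) -> Iterator[PhyloTree]:
        if next_tip == len(taxa):
            yield tree
            return
        for edge in tree.edges():
            t2 = tree.copy()
            _attach_tip(t2, next_tip, edge)
            yield from expand(t2, next_tip + 1)

    yield from expand(base, 3)


def n_unrooted_topologies(n: int) -> int:
    """(2n-5)!! — the number of distinct unrooted binary trees on n tips."""
    if n < 3:
        return 1
    out = 1
    for k in range(3, n + 1):
        out *= 2 * k - 5
    return out
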