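"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from trucphylo.matrix import PresenceAbsenceMatrix
from trucphylo.trees import PhyloTree


def sankoff_steps(tree: PhyloTree, states: dict[int, int]) -> int:
    """Unit-cost Sankoff dynamic program: independent parsimony oracle.

    ``states`` maps tip ids to 0/1.  The DP is rooted at an arbitrary
    node; the minimum total substitution cost is rooting-invariant.
    """
    root = next(n for n in tree.adj if tree.degree(n) > 1)
    INF = 10**9

    def cost(node: int, parent: int) -> tuple[int, int]:
        if node < tree.n_tips:
            s = states[node]
            return (0, INF) if s == 0 else (INF, 0)
        c0 = c1 = 0
        for child in tree.adj[node]:
            if child == parent:
                continue
            k0, k1 = cost(child, node)
            c0 += min(k0, k1 + 1)
            c1 += min(k0 + 1, k1)
        return c0, c1

    return min(cost(root, -1))


def random_matrix(
    rng: np.random.Generator, n_taxa: int, n_features: int
) -> PresenceAbsenceMatrix:
    """Random binary matrix with cyclic group labels (testing only)."""
    from trucphylo.matrix import GROUPS

    data = rng.integers(0, 2, size=(n_taxa, n_features)).astype(np.uint8)
    taxa = [f"t{i}" for i in range(n_taxa)]
    groups = [GROUPS[i % 4] for i in range(n_taxa)]
    features = [f"f{j}" for j in range(n_features)]
    return PresenceAbsenceMatrix(taxa, groups, features, data)


@pytest.fixture
def quartet_tree() -> PhyloTree:
    """((A,B),(C,D)) as an unrooted quartet."""
    t = PhyloTree.from_newick("((A,B),(C,D));")
    # drop the degree-2 root so the tree is genuinely unrooted
    if t.rooted:
        r = t.root
        u, v = t.adj[r]
        t.remove_edge(r, u)
        t.remove_edge(r, v)
        del t.adj[r]
        t.add_edge(u, v)
        t.rooted = False
        t.root = None
    return t


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
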