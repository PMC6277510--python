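"""Binary-character maximum parsimony: Fitch counting, heuristic search,
bootstrap, a-posteriori (Lundberg) rooting and per-character fit indices.

The machinery mirrors a classical PAUP-style workflow for presence/absence
characters: an unrooted most-parsimonious tree is sought by stepwise random
addition plus branch rearrangement (NNI or SPR), split reliability is
assessed by character bootstrap, the tree is rooted a posteriori by the
branch whose hypothetical-ancestor attachment minimizes the increase in
total length, and each character is scored with the standard fit indices
(CI, RI, RC, HI) plus a Goloboff-style concave fit.

Fitch passes are vectorized over characters with small-integer state
bitmasks, which keeps heuristic search and bootstrap practical at the
matrix sizes the pipeline works at (tens of taxa, hundreds of characters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .matrix import PresenceAbsenceMatrix
from .trees import PhyloTree, TreeError, _attach_tip

ANCESTOR_LABEL = "__hypothetical_ancestor__"


# -- Fitch counting ------------------------------------------------------


def _state_masks(data: np.ndarray) -> np.ndarray:
    """Map binary states to bitmasks: 0 -> 0b01, 1 -> 0b10."""
    return (np.asarray(data, dtype=np.uint8) + 1).astype(np.uint8)


def _fitch_pass(
    tree: PhyloTree, masks: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """Per-character Fitch step counts (optionally weighted) on ``tree``.

    ``masks`` has one row per tip id present in the tree; the pass is
    rooted at the lowest tip present, which leaves the count invariant
    (Fitch length does not depend on the rooting used for the traversal).
    """
    root = min(n for n in tree.adj if n < tree.n_tips)
    order = tree.postorder(root=root)
    n_chars = masks.shape[1]
    if weights is None:
        steps = np.zeros(n_chars, dtype=np.int64)
    else:
        steps = np.zeros(n_chars, dtype=np.float64)
    states: dict[int, np.ndarray] = {}
    for node, parent in order:
        if node < tree.n_tips:
            states[node] = masks[node]
            if node == root:
                # root tip combines with its single subtree
                child = next(c for c in tree.adj[node] if c != parent)
                inter = masks[node] & states[child]
                disjoint = inter == 0
                steps += weights * disjoint if weights is not None else disjoint
            continue
        children = [c for c in tree.adj[node] if c != parent]
        cur = states[children[0]]
        for c in children[1:]:
            other = states[c]
            inter = cur & other
            disjoint = inter == 0
            steps += weights * disjoint if weights is not None else disjoint
            cur = np.where(disjoint, cur | other, inter)
        states[node] = cur
        for c in children:
            del states[c]
    return steps


def fitch_steps(tree: PhyloTree, character: Sequence[int]) -> int:
    """Minimum number of state changes for one binary character.

    Parameters
    ----------
    tree
        Tree whose tips cover all taxa; tip ``i`` takes ``character[i]``.
    character
        Binary states ordered as ``tree.taxa``.
    """
    col = np.asarray(character)
    if col.shape != (tree.n_tips,):
        raise TreeError(
            f"character has {col.shape[0] if col.ndim else 0} states "
            f"for {tree.n_tips} taxa"
        )
    if not np.isin(col, (0, 1)).all():
        raise TreeError("character states must be 0/1 with no missing data")
    masks = _state_masks(col.reshape(-1, 1))
    return int(_fitch_pass(tree, masks)[0])


def per_character_steps(tree: PhyloTree, m: PresenceAbsenceMatrix) -> np.ndarray:
    """Fitch steps for every character of the matrix, in feature order."""
    if m.taxa != tree.taxa:
        raise TreeError("matrix taxa and tree taxa differ (order matters)")
    return _fitch_pass(tree, _state_masks(m.data))


def tree_length(tree: PhyloTree, m: PresenceAbsenceMatrix) -> int:
    """Total parsimony length: sum of Fitch steps over all characters."""
    if m.n_features == 0:
        return 0
    return int(per_character_steps(tree, m).sum())


# -- heuristic search ----------------------------------------------------


@dataclass
class SearchConfig:
    """Settings for the heuristic maximum-parsimony search.

    ``n_random_starts`` stepwise random-addition trees are each refined by
    hill-climbing over ``rearrangement`` neighborhoods (``"NNI"`` or
    ``"SPR"``) until no neighbor is shorter.  A fixed ``seed`` makes the
    whole search deterministic.
    """

    n_random_starts: int = 5
    rearrangement: str = "SPR"
    seed: int | None = None
    max_sweeps: int = 100
    max_best_trees: int = 64
    # sideways (equal-length) moves allowed per start once no neighbor
    # improves: walks the plateaus that trap pure hill-climbing on small
    # rugged matrices
    max_plateau_moves: int = 20


@dataclass
class SearchResult:
    best_length: int | float
    best_trees: list[PhyloTree]

    @property
    def tree(self) -> PhyloTree:
        return self.best_trees[0]


def _stepwise_addition(
    masks: np.ndarray,
    taxa: list[str],
    order: Sequence[int],
    weights: np.ndarray | None,
) -> PhyloTree:
    tree = PhyloTree(taxa)
    hub = tree.new_node()
    for i in order[:3]:
        tree.add_edge(int(i), hub)
    for tip in order[3:]:
        best_edge, best_len = None, None
        for edge in tree.edges():
            w = _attach_tip(tree, int(tip), edge)
            length = _fitch_pass(tree, masks, weights).sum()
            if best_len is None or length < best_len:
                best_len, best_edge = length, edge
            _detach_tip(tree, int(tip), w, edge)
        _attach_tip(tree, int(tip), best_edge)
    return tree


def _detach_tip(tree: PhyloTree, tip: int, w: int, edge: tuple[int, int]) -> None:
    u, v = edge
    tree.remove_edge(w, tip)
    tree.remove_edge(u, w)
    tree.remove_edge(w, v)
    del tree.adj[w]
    tree.add_edge(u, v)
    tree._next_id = w  # reuse the id; w was the most recently created node


def _nni_neighbors(tree: PhyloTree):
    """Yield the 2(n-3) NNI rearrangements, deterministically ordered."""
    for u, v in tree.edges():
        if u < tree.n_tips or v < tree.n_tips:
            continue
        a, b = sorted(x for x in tree.adj[u] if x != v)
        c, d = sorted(x for x in tree.adj[v] if x != u)
        for swap_u, swap_v in ((a, c), (a, d)):
            t2 = tree.copy()
            t2.remove_edge(u, swap_u)
            t2.remove_edge(v, swap_v)
            t2.add_edge(u, swap_v)
            t2.add_edge(v, swap_u)
            yield t2


def _spr_neighbors(tree: PhyloTree):
    """Yield subtree-prune-regraft rearrangements, deterministically ordered.

    Every directed edge (parent, child) defines a pruned subtree rooted at
    ``child``; it is regrafted onto every edge of the remaining tree.
    """
    for u, v in tree.edges():
        for parent, child in ((u, v), (v, u)):
            if tree.degree(parent) != 3:
                continue  # pruning here would leave a tip dangling oddly
            n1, n2 = sorted(x for x in tree.adj[parent] if x != child)
            base = tree.copy()
            base.remove_edge(parent, child)
            base.remove_edge(parent, n1)
            base.remove_edge(parent, n2)
            del base.adj[parent]
            base.add_edge(n1, n2)
            # component containing n1 is the regraft target
            target_nodes = set()
            stack = [n1]
            while stack:
                x = stack.pop()
                if x in target_nodes:
                    continue
                target_nodes.add(x)
                stack.extend(base.adj[x])
            if child in target_nodes:
                continue
            for x, y in base.edges():
                if x not in target_nodes:
                    continue
                if {x, y} == {n1, n2}:
                    continue  # regrafting on the closing edge recreates `tree`
                t2 = base.copy()
                t2.remove_edge(x, y)
                w = parent
                t2.adj[w] = set()
                t2.add_edge(x, w)
                t2.add_edge(w, y)
                t2.add_edge(w, child)
                yield t2


def mp_search(
    m: PresenceAbsenceMatrix,
    config: SearchConfig | None = None,
    weights: np.ndarray | None = None,
) -> SearchResult:
    """Heuristic search for most-parsimonious unrooted trees.

    Returns all distinct best-length topologies encountered (up to
    ``config.max_best_trees``), each carrying ``total_length``.

    Raises
    ------
    TreeError
        If the matrix has fewer than four taxa (no unrooted topology
        choice exists).
    """
    if m.n_taxa < 4:
        raise TreeError("maximum parsimony search requires >= 4 taxa")
    config = config or SearchConfig()
    if config.rearrangement not in ("NNI", "SPR"):
        raise TreeError(f"unknown rearrangement {config.rearrangement!r}")
    rng = np.random.default_rng(config.seed)
    masks = _state_masks(m.data)
    neighbor_fn = _spr_neighbors if config.rearrangement == "SPR" else _nni_neighbors

    best_len: float | None = None
    best: dict[frozenset, PhyloTree] = {}
    for _ in range(config.n_random_starts):
        order = rng.permutation(m.n_taxa)
        tree = _stepwise_addition(masks, m.taxa, order, weights)
        cur_len = _fitch_pass(tree, masks, weights).sum()
        plateau_budget = config.max_plateau_moves
        visited = {tree.topology_key()}
        for _sweep in range(config.max_sweeps):
            improved = False
            sideways = None
            for t2 in neighbor_fn(tree):
                length = _fitch_pass(t2, masks, weights).sum()
                if length < cur_len:
                    tree, cur_len, improved = t2, length, True
                    visited = {tree.topology_key()}
                elif length == cur_len and not improved and sideways is None:
                    key = t2.topology_key()
                    if key not in visited:
                        sideways = (t2, key)
                if (
                    best_len is not None
                    and length == best_len
                    and len(best) < config.max_best_trees
                ):
                    best.setdefault(t2.topology_key(), t2)
            if improved:
                continue
            if sideways is not None and plateau_budget > 0:
                tree = sideways[0]
                visited.add(sideways[1])
                plateau_budget -= 1
                continue
            break
        if best_len is None or cur_len < best_len:
            best_len = cur_len
            best = {tree.topology_key(): tree}
        elif cur_len == best_len and len(best) < config.max_best_trees:
            best.setdefault(tree.topology_key(), tree)
    # drop stale equal-length entries collected before the final best_len
    out = []
    for key in sorted(best, key=lambda k: sorted(map(sorted, k))):
        t = best[key]
        length = _fitch_pass(t, masks, weights).sum()
        if length == best_len:
            t.total_length = int(length) if weights is None else float(length)
            out.append(t)
    return SearchResult(
        best_length=int(best_len) if weights is None else float(best_len),
        best_trees=out,
    )


def exhaustive_search(
    m: PresenceAbsenceMatrix, weights: np.ndarray | None = None
) -> SearchResult:
    """Exact search over all unrooted topologies (practical for <= 8 taxa)."""
    from .trees import enumerate_topologies

    masks = _state_masks(m.data)
    best_len = None
    best: list[PhyloTree] = []
    for tree in enumerate_topologies(m.taxa):
        length = _fitch_pass(tree, masks, weights).sum()
        if best_len is None or length < best_len:
            best_len, best = length, [tree]
        elif length == best_len:
            best.append(tree)
    for t in best:
        t.total_length = int(best_len) if weights is None else float(best_len)
    return SearchResult(
        best_length=int(best_len) if weights is None else float(best_len),
        best_trees=best,
    )


# -- Lundberg rooting ----------------------------------------------------


def lundberg_root(
    tree: PhyloTree,
    m: PresenceAbsenceMatrix,
    ancestor_states: Sequence[int] | None = None,
) -> PhyloTree:
    """Root an unrooted tree a posteriori by hypothetical-ancestor attachment.

    A hypothetical ancestor with the given character states (default:
    all-absent, treating domain absence as the ancestral condition) is
    attached to every branch in turn; the root is placed on the branch that
    minimizes the resulting total parsimony length.  Ties are broken by the
    deterministic branch enumeration order of :meth:`PhyloTree.edges` and
    flagged on the returned tree (``root_tie``).

    The returned tree carries ``lundberg_length`` (length including the
    ancestor at the chosen branch) alongside ``total_length`` (unrooted
    length without the ancestor).
    """
    if tree.rooted:
        raise TreeError("tree is already rooted")
    ancestor = (
        np.zeros(m.n_features, dtype=np.uint8)
        if ancestor_states is None
        else np.asarray(ancestor_states, dtype=np.uint8)
    )
    if ancestor.shape != (m.n_features,):
        raise TreeError(
            f"ancestor vector length {ancestor.shape[0] if ancestor.ndim else 0} "
            f"!= {m.n_features} characters"
        )
    anc_tip = len(tree.taxa)
    ext_taxa = tree.taxa + [ANCESTOR_LABEL]
    ext_masks = _state_masks(np.vstack([m.data, ancestor]))
    n = tree.n_tips
    shift = lambda x: x if x < n else x + 1  # noqa: E731
    best_edge, best_len, tie = None, None, False
    for edge in tree.edges():
        t2 = _with_extra_tip_taxon(tree, ext_taxa)
        w = _attach_tip(t2, anc_tip, (shift(edge[0]), shift(edge[1])))
        length = int(_fitch_pass(t2, ext_masks).sum())
        if best_len is None or length < best_len:
            best_edge, best_len, tie = edge, length, False
        elif length == best_len:
            tie = True
    rooted = tree.copy()
    u, v = best_edge
    rooted.remove_edge(u, v)
    root = rooted.new_node()
    rooted.add_edge(u, root)
    rooted.add_edge(root, v)
    rooted.rooted = True
    rooted.root = root
    rooted.total_length = tree_length(tree, m)
    rooted.lundberg_length = best_len  # type: ignore[attr-defined]
    rooted.root_tie = tie  # type: ignore[attr-defined]
    rooted.root_edge = best_edge  # type: ignore[attr-defined]
    return rooted


def _with_extra_tip_taxon(tree: PhyloTree, ext_taxa: list[str]) -> PhyloTree:
    """Copy of ``tree`` re-indexed so one extra tip id is available.

    Internal node ids are shifted by one so the new tip slot (old
    ``n_tips``) is free.
    """
    n = tree.n_tips
    shift = lambda x: x if x < n else x + 1  # noqa: E731
    t = PhyloTree(ext_taxa)
    t.adj = {
        shift(u): {shift(v) for v in nb} for u, nb in tree.adj.items()
    }
    t._next_id = tree._next_id + 1
    return t


# -- bootstrap -----------------------------------------------------------


def bootstrap_support(
    m: PresenceAbsenceMatrix,
    reps: int = 1000,
    seed: int | None = None,
    search_config: SearchConfig | None = None,
    reference: PhyloTree | None = None,
) -> tuple[PhyloTree, dict[frozenset[str], float]]:
    """Character-bootstrap split supports attached to a reference MP tree.

    Characters are resampled with replacement ``reps`` times (implemented
    as multinomial character weights); each replicate is analyzed with the
    same heuristic search, and the support of each split of the reference
    tree is the percentage of replicate best trees containing it.

    Returns the reference tree (supports filled in) and the support map.
    """
    if reps < 1:
        raise TreeError("bootstrap needs reps >= 1")
    rng = np.random.default_rng(seed)
    search_config = search_config or SearchConfig(n_random_starts=1)
    if reference is None:
        ref_cfg = SearchConfig(
            n_random_starts=max(search_config.n_random_starts, 3),
            rearrangement=search_config.rearrangement,
            seed=int(rng.integers(2**31 - 1)),
        )
        reference = mp_search(m, ref_cfg).tree
    ref_splits = reference.splits()
    hits = {s: 0 for s in ref_splits}
    for _ in range(reps):
        weights = rng.multinomial(m.n_features, np.full(m.n_features, 1.0 / m.n_features)).astype(float)
        rep_cfg = SearchConfig(
            n_random_starts=search_config.n_random_starts,
            rearrangement=search_config.rearrangement,
            seed=int(rng.integers(2**31 - 1)),
            max_best_trees=1,
        )
        rep_tree = mp_search(m, rep_cfg, weights=weights).tree
        rep_splits = rep_tree.splits()
        for s in ref_splits:
            if s in rep_splits:
                hits[s] += 1
    support = {s: 100.0 * h / reps for s, h in hits.items()}
    reference.support = support
    return reference, support


# -- per-character fit indices -------------------------------------------


@dataclass
class CharacterFitRecord:
    """Parsimony fit of one binary character on one tree.

    ``m``/``s``/``g`` are the minimum, observed and maximum step counts
    (min over all trees, on the evaluated tree, max over all trees).  The
    derived indices are the standard consistency (CI = m/s), retention
    (RI = (g-s)/(g-m)), rescaled consistency (RC = CI*RI) and homoplasy
    (HI = 1-CI) indices, plus the concave Goloboff fit
    G = k/(k + s - m).  RI and RC are NaN when g == m (index undefined,
    e.g. for parsimony-uninformative characters).
    """

    feature: str
    m: int
    s: int
    g: int
    ci: float
    ri: float
    rc: float
    hi: float
    g_fit: float
    nd: float = field(default=float("nan"))


def character_fit(
    tree: PhyloTree, m: PresenceAbsenceMatrix, k: float = 2.0
) -> list[CharacterFitRecord]:
    """Fit indices for every character of ``m`` on ``tree``.

    For a binary character with ``a`` presences and ``b`` absences the
    closed forms are: min steps = 1 if both states occur else 0, and max
    steps over all trees = min(a, b) (every minority-state tip changed
    independently).  Observed steps come from a Fitch pass.
    """
    steps = per_character_steps(tree, m)
    ones = m.data.sum(axis=0).astype(int)
    zeros = m.n_taxa - ones
    records = []
    for j, feat in enumerate(m.features):
        a, b = int(ones[j]), int(zeros[j])
        m_min = 1 if (a >= 1 and b >= 1) else 0
        g_max = min(a, b)
        s = int(steps[j])
        ci = m_min / s if s > 0 else 1.0
        hi = 1.0 - ci
        if g_max > m_min:
            ri = (g_max - s) / (g_max - m_min)
            rc = ci * ri
        else:
            ri = float("nan")
            rc = float("nan")
        g_fit = k / (k + (s - m_min))
        nd = float("nan")
        if m.ages is not None and feat in m.ages:
            nd = m.ages[feat]
        records.append(
            CharacterFitRecord(feat, m_min, s, g_max, ci, ri, rc, hi, g_fit, nd)
        )
    return records


def fit_vs_age_table(
    records: Iterable[CharacterFitRecord],
    plot_prefix: str | Path | None = None,
) -> pd.DataFrame:
    """Character-fit table sorted by age, optionally with scatter plots.

    One row per character with columns ``feature, nd, m, s, g, CI, RI, RC,
    HI, G``.  When ``plot_prefix`` is given, one scatter (index vs nd) per
    index is written as ``<prefix>_<index>.png``.
    """
    rows = [
        {
            "feature": r.feature, "nd": r.nd, "m": r.m, "s": r.s, "g": r.g,
            "CI": r.ci, "RI": r.ri, "RC": r.rc, "HI": r.hi, "G": r.g_fit,
        }
        for r in records
    ]
    df = pd.DataFrame(rows).sort_values("nd", kind="stable").reset_index(drop=True)
    if plot_prefix is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for index in ("CI", "RI", "RC", "HI", "G"):
            fig, ax = plt.subplots(figsize=(4, 3))
            ax.scatter(df["nd"], df[index], s=12, alpha=0.7)
            ax.set_xlabel("character age (nd)")
            ax.set_ylabel(index)
            ax.set_ylim(-0.05, 1.05)
            fig.tight_layout()
            fig.savefig(f"{plot_prefix}_{index}.png", dpi=100)
            plt.close(fig)
    return df


# -- consensus -----------------------------------------------------------


def strict_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """Strict consensus: keep only splits present in every input tree."""
    if not trees:
        raise TreeError("no trees given")
    taxa = trees[0].taxa
    common = set.intersection(*(set(t.splits()) for t in trees))
    cons = PhyloTree.star(taxa)
    hub = cons.n_tips
    # refine the star by grouping each common split under a new node,
    # largest splits first so nesting resolves correctly
    holder = {i: hub for i in range(cons.n_tips)}
    for split in sorted(common, key=len, reverse=True):
        tips = sorted(taxa.index(x) for x in split)
        parents = {holder[i] for i in tips}
        if len(parents) != 1:
            continue  # incompatible ordering cannot arise from tree splits
        parent = parents.pop()
        node = cons.new_node()
        cons.add_edge(parent, node)
        for i in tips:
            cons.remove_edge(parent, i)
            cons.add_edge(node, i)
            holder[i] = node
    return cons
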