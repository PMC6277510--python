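"""Maximum parsimony: Fitch counting, search, rooting, bootstrap, fit indices."""

import numpy as np
import pytest

from trucphylo.matrix import GROUPS, PresenceAbsenceMatrix
from trucphylo.parsimony import (
    SearchConfig,
    bootstrap_support,
    character_fit,
    exhaustive_search,
    fit_vs_age_table,
    fitch_steps,
    lundberg_root,
    mp_search,
    per_character_steps,
    strict_consensus,
    tree_length,
)
from trucphylo.trees import PhyloTree, TreeError, random_tree

from conftest import random_matrix, sankoff_steps


def _pam(rows, taxa):
    rows = np.asarray(rows, dtype=np.uint8)
    groups = [GROUPS[i % 4] for i in range(len(taxa))]
    features = [f"f{j}" for j in range(rows.shape[1])]
    return PresenceAbsenceMatrix(list(taxa), groups, features, rows)


class TestFitch:
    @pytest.mark.parametrize(
        "states,expected",
        [
            ([1, 1, 0, 0], 1),  # single synapomorphy on ((A,B),(C,D))
            ([1, 0, 1, 0], 2),  # maximal conflict
            ([0, 0, 0, 0], 0),  # constant
            ([1, 1, 1, 1], 0),
            ([1, 0, 0, 0], 1),  # autapomorphy
        ],
    )
    def test_quartet_step_counts(self, quartet_tree, states, expected):
        assert fitch_steps(quartet_tree, states) == expected

    def test_missing_state_rejected(self, quartet_tree):
        with pytest.raises(TreeError):
            fitch_steps(quartet_tree, [1, 0, 1])

    def test_agrees_with_sankoff_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(4, 9))
            tree = random_tree([f"t{i}" for i in range(n)], rng)
            states = rng.integers(0, 2, size=n)
            expected = sankoff_steps(tree, dict(enumerate(states)))
            assert fitch_steps(tree, states) == expected

    def test_invariant_under_taxon_permutation(self):
        rng = np.random.default_rng(7)
        taxa = [f"t{i}" for i in range(8)]
        tree = random_tree(taxa, rng)
        m = random_matrix(rng, 8, 30)
        m.taxa = taxa
        base = tree_length(tree, m)
        perm = rng.permutation(8)
        m2 = PresenceAbsenceMatrix(
            [m.taxa[i] for i in perm],
            [m.groups[i] for i in perm],
            m.features,
            m.data[perm],
        )
        tree2 = PhyloTree.from_newick(tree.newick(), taxa=m2.taxa)
        assert tree_length(tree2, m2) == base


class TestTreeLength:
    def test_additive_over_characters(self, quartet_tree):
        m = _pam([[1, 1], [1, 0], [0, 1], [0, 0]], quartet_tree.taxa)
        expected = sum(
            fitch_steps(quartet_tree, m.data[:, j]) for j in range(2)
        )
        assert tree_length(quartet_tree, m) == expected == 3

    def test_empty_character_set(self, quartet_tree):
        m = _pam(np.zeros((4, 0)), quartet_tree.taxa)
        assert tree_length(quartet_tree, m) == 0


class TestSearch:
    def test_fewer_than_four_taxa_rejected(self):
        m = _pam([[1], [0], [1]], ["a", "b", "c"])
        with pytest.raises(TreeError):
            mp_search(m)

    def test_recovers_truth_without_homoplasy(self):
        # characters are exactly the clades of a known 8-taxon tree
        truth = PhyloTree.from_newick(
            "((( a,b),(c,d)),((e,f),(g,h)));".replace(" ", "")
        )
        clades = [
            {"a", "b"}, {"c", "d"}, {"e", "f"}, {"g", "h"},
            {"a", "b", "c", "d"}, {"e", "f", "g", "h"},
        ]
        taxa = sorted(truth.taxa)
        rows = np.array(
            [[1 if t in c else 0 for c in clades] for t in taxa]
        )
        m = _pam(rows, taxa)
        res = mp_search(m, SearchConfig(n_random_starts=3, seed=0))
        assert res.best_length == len(clades)
        truth2 = PhyloTree.from_newick(truth.newick(), taxa=taxa)
        assert res.tree.topology_key() == truth2.topology_key()

    def test_matches_exhaustive_on_six_taxa(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            m = random_matrix(rng, 6, 15)
            heur = mp_search(m, SearchConfig(n_random_starts=3, seed=2))
            exact = exhaustive_search(m)
            assert heur.best_length == exact.best_length

    def test_duplicate_taxa_become_sisters(self):
        rows = np.array(
            [[1, 1, 0], [1, 1, 0], [0, 1, 1], [0, 0, 1], [1, 0, 0]]
        )
        rows = np.vstack([rows, rows[4]])  # t5 identical to t4
        m = _pam(rows, [f"t{i}" for i in range(6)])
        # a zero-length split cannot increase tree length, so the sister
        # arrangement is among the equally most-parsimonious trees
        exact = exhaustive_search(m)
        assert any(
            frozenset({"t4", "t5"}) in t.splits() for t in exact.best_trees
        )
        heur = mp_search(m, SearchConfig(n_random_starts=3, seed=3))
        assert heur.best_length == exact.best_length

    def test_deterministic_for_fixed_seed(self, rng):
        m = random_matrix(rng, 8, 25)
        cfg = SearchConfig(n_random_starts=2, seed=9)
        a = mp_search(m, cfg)
        b = mp_search(m, cfg)
        assert a.best_length == b.best_length
        assert [t.topology_key() for t in a.best_trees] == [
            t.topology_key() for t in b.best_trees
        ]


class TestLundbergRooting:
    def test_root_placed_next_to_all_absent_taxon(self):
        # A=(0,0) B=(1,0) C=(1,1) D=(1,1): ancestor 00 attaches best near A
        taxa = ["A", "B", "C", "D"]
        m = _pam([[0, 0], [1, 0], [1, 1], [1, 1]], taxa)
        res = mp_search(m, SearchConfig(n_random_starts=3, seed=0))
        tree = res.tree
        # oracle: evaluate ancestor attachment on every branch via Sankoff
        best = None
        for u, v in tree.edges():
            ext = PhyloTree(taxa + ["anc"])
            shift = {x: (x if x < 4 else x + 1) for x in tree.adj}
            for a in tree.adj:
                for b in tree.adj[a]:
                    ext.add_edge(shift[a], shift[b])
            ext._next_id = max(ext.adj) + 1
            w = ext.new_node()
            ext.remove_edge(shift[u], shift[v])
            ext.add_edge(shift[u], w)
            ext.add_edge(w, shift[v])
            ext.add_edge(w, 4)
            length = sum(
                sankoff_steps(
                    ext, {**{i: int(m.data[i, j]) for i in range(4)}, 4: 0}
                )
                for j in range(2)
            )
            if best is None or length < best[0]:
                best = (length, (u, v))
        rooted = lundberg_root(tree, m)
        assert rooted.lundberg_length == best[0]
        # the chosen branch is incident to tip A (node 0)
        assert 0 in rooted.root_edge
        assert rooted.rooted and rooted.degree(rooted.root) == 2

    def test_all_zero_matrix_ties_are_flagged(self, quartet_tree):
        m = _pam(np.zeros((4, 3)), quartet_tree.taxa)
        rooted = lundberg_root(quartet_tree, m)
        assert rooted.root_tie
        assert rooted.root_edge == quartet_tree.edges()[0]

    def test_ancestor_length_mismatch_rejected(self, quartet_tree):
        m = _pam([[1], [1], [0], [0]], quartet_tree.taxa)
        with pytest.raises(TreeError):
            lundberg_root(quartet_tree, m, ancestor_states=[0, 0])


class TestBootstrap:
    def test_single_rep_supports_are_zero_or_hundred(self, rng):
        m = random_matrix(rng, 6, 20)
        ref = mp_search(m, SearchConfig(n_random_starts=2, seed=1)).tree
        _, support = bootstrap_support(m, reps=1, seed=4, reference=ref)
        assert set(support.values()) <= {0.0, 100.0}

    def test_clean_signal_gives_full_support(self):
        # homoplasy-free clade characters, enough copies per split that no
        # replicate is likely to resample a split's characters away entirely
        taxa = [f"t{i}" for i in range(8)]
        clades = [
            {"t0", "t1"}, {"t2", "t3"}, {"t4", "t5"}, {"t6", "t7"},
            {"t0", "t1", "t2", "t3"},
        ]
        rows = np.array(
            [[1 if t in c else 0 for c in clades for _ in range(8)]
             for t in taxa]
        )
        m = _pam(rows, taxa)
        ref = mp_search(m, SearchConfig(n_random_starts=3, seed=0)).tree
        _, support = bootstrap_support(m, reps=50, seed=5, reference=ref)
        assert all(v == 100.0 for v in support.values())


class TestCharacterFit:
    def test_perfect_informative_character(self, quartet_tree):
        m = _pam([[1], [1], [0], [0]], quartet_tree.taxa)
        (rec,) = character_fit(quartet_tree, m)
        assert (rec.m, rec.s, rec.g) == (1, 1, 2)
        assert rec.ci == 1.0 and rec.ri == 1.0 and rec.hi == 0.0

    def test_homoplastic_character_indices(self, quartet_tree):
        m = _pam([[1], [0], [1], [0]], quartet_tree.taxa)
        (rec,) = character_fit(quartet_tree, m, k=2.0)
        assert (rec.m, rec.s, rec.g) == (1, 2, 2)
        assert rec.ci == 0.5 and rec.ri == 0.0 and rec.rc == 0.0
        assert rec.hi == 0.5
        assert rec.g_fit == pytest.approx(2.0 / 3.0)

    def test_identities_hold_on_random_data(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            n = int(rng.integers(5, 10))
            taxa = [f"t{i}" for i in range(n)]
            tree = random_tree(taxa, rng)
            m = random_matrix(rng, n, 25)
            m.taxa = taxa
            for rec in character_fit(tree, m):
                assert rec.m <= rec.s <= rec.g
                assert rec.hi == pytest.approx(1.0 - rec.ci)
                if not np.isnan(rec.ri):
                    assert rec.rc == pytest.approx(rec.ci * rec.ri)
                    assert 0.0 <= rec.ri <= 1.0
                assert 0.0 <= rec.ci <= 1.0

    def test_max_steps_closed_form_is_attained(self):
        # g = min(a, b) must bound the Fitch count on every topology
        rng = np.random.default_rng(30)
        from trucphylo.trees import enumerate_topologies

        taxa = [f"t{i}" for i in range(6)]
        states = np.array([1, 1, 1, 0, 0, 1])
        g = min(states.sum(), len(states) - states.sum())
        observed = {
            fitch_steps(t, states) for t in enumerate_topologies(taxa)
        }
        assert max(observed) == g
        assert min(observed) == 1


class TestFitVsAge:
    def test_table_sorted_with_one_row_per_character(self, quartet_tree):
        m = _pam([[1, 1], [1, 0], [0, 1], [0, 0]], quartet_tree.taxa)
        m.ages = {"f0": 0.9, "f1": 0.1}
        df = fit_vs_age_table(character_fit(quartet_tree, m))
        assert len(df) == 2
        assert list(df["nd"]) == sorted(df["nd"])

    def test_planted_age_homoplasy_trend(self):
        # young characters get convergent gains: HI should rise with nd
        from scipy.stats import spearmanr

        rng = np.random.default_rng(8)
        taxa = [f"t{i}" for i in range(8)]
        tree = random_tree(taxa, rng)
        n_old, n_young = 30, 30
        old = np.zeros((8, n_old), dtype=np.uint8)
        for j in range(n_old):  # clean clade characters
            side = tree.tips_below(*tree.edges()[j % len(tree.edges())][::-1])
            for i, t in enumerate(taxa):
                old[i, j] = t in side
        young = rng.integers(0, 2, size=(8, n_young)).astype(np.uint8)
        data = np.hstack([old, young])
        features = [f"f{j}" for j in range(n_old + n_young)]
        ages = {
            f: (0.1 if j < n_old else 0.9) for j, f in enumerate(features)
        }
        m = PresenceAbsenceMatrix(
            taxa, [GROUPS[i % 4] for i in range(8)], features, data, ages
        )
        df = fit_vs_age_table(character_fit(tree, m))
        informative = df[(df["g"] > df["m"]) & (df["m"] > 0)]
        rho, _ = spearmanr(informative["nd"], informative["HI"])
        assert rho > 0


class TestConsensus:
    def test_strict_consensus_keeps_only_shared_splits(self):
        a = PhyloTree.from_newick("((A,B),(C,(D,E)));")
        b = PhyloTree.from_newick("((A,C),(B,(D,E)));", taxa=a.taxa)
        cons = strict_consensus([a, b])
        assert cons.splits() == a.splits() & b.splits()
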