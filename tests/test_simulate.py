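"""Synthetic-data generators: determinism, planted truth, noise limits."""

import numpy as np
import pytest

from trucphylo.matrix import GROUPS
from trucphylo.parsimony import character_fit, per_character_steps, tree_length
from trucphylo.rhizome import ORFAN
from trucphylo.simulate import (
    ConfigError,
    FamilySpec,
    SimConfig,
    config_from_dict,
    config_to_dict,
    gen_four_group_matrix,
    gen_genomes,
    gen_hit_table,
)


class TestConfigValidation:
    def test_invalid_rate_rejected(self):
        with pytest.raises(ConfigError, match="gain_rate"):
            SimConfig(gain_rate=1.5)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(n_taxa_per_group=1)

    def test_donor_props_must_sum_below_one(self):
        with pytest.raises(ConfigError):
            SimConfig(donor_props={"virus": 0.8, "bacteria": 0.4})

    def test_unknown_genome_in_family_span_rejected(self):
        with pytest.raises(ConfigError, match="nonexistent"):
            SimConfig(family_spec=[FamilySpec("f", ("nonexistent",))])

    def test_round_trips_through_dict(self):
        cfg = SimConfig(seed=3, n_characters=50)
        again = config_from_dict(config_to_dict(cfg))
        assert config_to_dict(again) == config_to_dict(cfg)


class TestCharacterMatrix:
    def test_fixed_seed_is_bit_identical(self):
        a, ta, aa = gen_four_group_matrix(SimConfig(seed=7))
        b, tb, ab = gen_four_group_matrix(SimConfig(seed=7))
        assert np.array_equal(a.data, b.data)
        assert aa == ab
        assert ta.topology_key() == tb.topology_key()

    def test_shape_and_groups(self):
        cfg = SimConfig(seed=0, n_taxa_per_group=3, n_characters=25)
        m, tree, ages = gen_four_group_matrix(cfg)
        assert m.data.shape == (12, 25)
        assert [g for g in GROUPS for _ in range(3)] == m.groups
        assert set(ages) == set(m.features)
        assert all(0.0 <= v <= 1.0 for v in ages.values())

    def test_truth_tree_has_four_group_clades(self):
        cfg = SimConfig(seed=1, n_taxa_per_group=4, n_characters=10)
        m, tree, _ = gen_four_group_matrix(cfg)
        splits = tree.splits()
        for g in GROUPS:
            members = frozenset(
                t for t, lab in zip(m.taxa, m.groups) if lab == g
            )
            if m.taxa[0] in members:
                members = frozenset(set(m.taxa) - members)
            assert members in splits

    def test_no_change_limit_all_present_zero_steps(self):
        cfg = SimConfig(
            seed=2, gain_rate=0.0, loss_rate=0.0, character_origin="root",
            n_taxa_per_group=3, n_characters=15, age_noise=0.0,
        )
        m, tree, ages = gen_four_group_matrix(cfg)
        assert m.data.all()
        assert tree_length(tree, m) == 0
        assert all(v == 0.0 for v in ages.values())

    def test_single_gain_characters_fit_truth_perfectly(self):
        cfg = SimConfig(
            seed=3, gain_rate=0.0, loss_rate=0.0,
            n_taxa_per_group=4, n_characters=60, age_noise=0.0,
        )
        m, tree, _ = gen_four_group_matrix(cfg)
        steps = per_character_steps(tree, m)
        ones = m.data.sum(axis=0)
        for j in range(m.n_features):
            if 0 < ones[j] < m.n_taxa:
                assert steps[j] == 1  # a single gain on the truth tree
        for rec in character_fit(tree, m):
            if rec.m == 1:
                assert rec.s == 1 and rec.ci == 1.0

    def test_ages_equal_scaled_origin_depth_without_jitter(self):
        from trucphylo.simulate import four_group_truth_tree

        cfg = SimConfig(
            seed=4, gain_rate=0.0, loss_rate=0.0, age_noise=0.0,
            n_taxa_per_group=4, n_characters=80,
        )
        m, tree, ages = gen_four_group_matrix(cfg)
        ref, sim_root, parent, _ = four_group_truth_tree(4)
        depths = {sim_root: 0}
        for node, par in reversed(ref.postorder(root=sim_root)):
            if par != -1:
                depths[node] = depths[par] + 1
        max_depth = max(depths.values())
        clade_tips = {
            node: (
                {ref.taxa[node]} if node < ref.n_tips
                else ref.tips_below(node, parent[node])
            ) if node != sim_root else set(ref.taxa)
            for node in depths
        }
        # without noise the presence pattern IS the origin clade, so the
        # age must equal that node's depth scaled to [0, 1]
        for j, f in enumerate(m.features):
            pattern = {t for t, x in zip(m.taxa, m.data[:, j]) if x}
            matching = [
                depths[n] for n, tips in clade_tips.items() if tips == pattern
            ]
            assert matching, f"pattern of {f} is not a truth clade"
            assert ages[f] == pytest.approx(min(matching) / max_depth)


class TestGenomes:
    def test_deterministic_and_truth_complete(self):
        a, ta = gen_genomes(SimConfig(seed=5))
        b, tb = gen_genomes(SimConfig(seed=5))
        assert [(g.gene, g.sequence) for g in a] == [
            (g.gene, g.sequence) for g in b
        ]
        assert ta == tb
        assert {g.gene for g in a} == set(ta)

    def test_empty_family_spec_rejected(self):
        with pytest.raises(ConfigError):
            gen_genomes(SimConfig(family_spec=[]))

    def test_zero_shared_families_means_empty_core(self):
        from trucphylo.pangenome import (
            all_vs_all_homology,
            build_families,
            partition_pangenome,
        )

        spec = [
            FamilySpec(f"u{i}", (genome,))
            for i, genome in enumerate(SimConfig().genome_names)
        ]
        genes, _ = gen_genomes(SimConfig(seed=6, family_spec=spec))
        by_genome: dict[str, list] = {}
        for g in genes:
            by_genome.setdefault(g.genome, []).append(g)
        fams = build_families(all_vs_all_homology(by_genome), by_genome)
        assert partition_pangenome(fams).core_families == 0

    def test_single_core_family_with_one_gene_each(self):
        from trucphylo.pangenome import (
            all_vs_all_homology,
            build_families,
            partition_pangenome,
        )

        cfg = SimConfig(
            seed=7,
            family_spec=[FamilySpec("core", SimConfig().genome_names)],
        )
        genes, _ = gen_genomes(cfg)
        by_genome: dict[str, list] = {}
        for g in genes:
            by_genome.setdefault(g.genome, []).append(g)
        fams = build_families(all_vs_all_homology(by_genome), by_genome)
        part = partition_pangenome(fams)
        assert part.core_families == 1


class TestHitTables:
    def test_pure_virus_props_give_hundred_percent(self):
        from trucphylo.rhizome import aggregate_rhizome, classify_best_hits
        from trucphylo.simulate import SELF_TAXONOMY

        cfg = SimConfig(seed=8, donor_props={"virus": 1.0})
        genes, _ = gen_genomes(cfg)
        hits, _ = gen_hit_table(cfg, genes)
        summary = aggregate_rhizome(
            classify_best_hits(hits, SELF_TAXONOMY)
        )
        assert summary.percentages["virus"] == 100.0
        assert summary.counts[ORFAN] == 0

    def test_orfans_have_no_passing_hits(self):
        cfg = SimConfig(seed=9, donor_props={"virus": 0.4})
        genes, _ = gen_genomes(cfg)
        hits, truth = gen_hit_table(cfg, genes)
        for gid, donor in truth.items():
            if donor == ORFAN:
                assert hits[gid] == []
            else:
                top = max(hits[gid], key=lambda h: h.score)
                assert top.taxonomy[0].lower().startswith(donor[:4])

    def test_self_family_decoys_are_neutralized_by_exclusion(self):
        from trucphylo.rhizome import classify_best_hits
        from trucphylo.simulate import SELF_TAXONOMY

        cfg = SimConfig(seed=10, plant_self_family_decoys=True)
        genes, _ = gen_genomes(cfg)
        hits, truth = gen_hit_table(cfg, genes)
        excl = classify_best_hits(hits, SELF_TAXONOMY, "family")
        for a in excl:
            assert a.donor == truth[a.unit]
        none = classify_best_hits(hits, SELF_TAXONOMY, "none")
        decoyed = [a for a in none if truth[a.unit] != ORFAN]
        assert all(a.donor == "virus" for a in decoyed)

    def test_below_threshold_orfan_mode_emits_weak_hits(self):
        cfg = SimConfig(
            seed=11, donor_props={"virus": 0.2}, orfan_mode="below_threshold"
        )
        genes, _ = gen_genomes(cfg)
        hits, truth = gen_hit_table(cfg, genes)
        weak = [
            h for gid, donor in truth.items() if donor == ORFAN
            for h in hits[gid]
        ]
        assert weak and all(h.evalue > 1e-3 for h in weak)
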