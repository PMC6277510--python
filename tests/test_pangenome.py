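"""Homology search, gene-family construction and pangenome partitioning."""

import io

import numpy as np
import pytest

from trucphylo.pangenome import (
    GeneFamily,
    GeneRecord,
    HomologyHit,
    PangenomeError,
    PangenomePartition,
    Thresholds,
    align_pair,
    all_vs_all_homology,
    build_families,
    partition_pangenome,
    read_fasta,
    read_hits_tsv,
    round_percentage,
    write_fasta,
    write_hits_tsv,
)
from trucphylo.simulate import SimConfig, gen_genomes


def _random_protein(rng, n):
    from trucphylo.pangenome import AMINO_ACIDS

    return "".join(AMINO_ACIDS[i] for i in rng.integers(20, size=n))


class TestAlignment:
    def test_identical_sequences_align_perfectly(self, rng):
        seq = _random_protein(rng, 200)
        a = GeneRecord("g1", "a", seq)
        b = GeneRecord("g2", "b", seq)
        hit = align_pair(a, b)
        assert hit.identity == pytest.approx(100.0)
        assert hit.query_coverage == pytest.approx(1.0)
        assert hit.evalue < 1e-50

    def test_unrelated_random_pairs_never_pass_evalue(self, rng):
        thresholds = Thresholds()
        for _ in range(100):
            a = GeneRecord("g1", "a", _random_protein(rng, 100))
            b = GeneRecord("g2", "b", _random_protein(rng, 100))
            hit = align_pair(a, b)
            assert hit is None or hit.evalue > thresholds.evalue

    def test_planted_diverged_family_passes_thresholds(self):
        # deeply diverged family (~45% expected sitewise identity, i.e.
        # around 40% after local-alignment gapping) must still pass the
        # permissive clustering thresholds
        from trucphylo.simulate import FamilySpec

        cfg = SimConfig(
            seed=9,
            mutation_prob=0.55,
            family_spec=[FamilySpec("core1", SimConfig().genome_names,
                                    genes_per_genome=1, length=300)],
        )
        genes, truth = gen_genomes(cfg)
        fam_genes = [g for g in genes if truth[g.gene]["family"] == "core1"]
        assert len(fam_genes) == 4
        for i, a in enumerate(fam_genes):
            for b in fam_genes[i + 1:]:
                hit = align_pair(a, b)
                assert hit is not None and Thresholds().passes(hit)

    def test_empty_genome_rejected(self):
        with pytest.raises(PangenomeError, match="empty"):
            all_vs_all_homology({"a": [], "b": [GeneRecord("b", "x", "MKV")]})


def _hit(q, s, identity=50.0, cov=0.9, score=100.0, evalue=1e-10):
    return HomologyHit(q, s, identity, cov, cov, score, evalue)


class TestFamilies:
    def _genomes(self, ids):
        return {
            g: [GeneRecord(g, gid, "MKVL") for gid in gids]
            for g, gids in ids.items()
        }

    def test_chain_closes_transitively(self):
        genomes = self._genomes({"G1": ["a"], "G2": ["b"], "G3": ["c"]})
        hits = [
            _hit("a", "b"), _hit("b", "a"),
            _hit("b", "c"), _hit("c", "b"),
        ]
        fams = build_families(hits, genomes)
        assert len(fams) == 1
        assert {g.gene for g in fams[0].members} == {"a", "b", "c"}

    def test_non_reciprocal_hits_make_no_edge(self):
        genomes = self._genomes({"G1": ["a"], "G2": ["b"]})
        fams = build_families([_hit("a", "b")], genomes)
        assert len(fams) == 2

    def test_no_edges_gives_all_singletons(self):
        genomes = self._genomes({"G1": ["a", "b"], "G2": ["c"]})
        fams = build_families([], genomes)
        assert len(fams) == 3
        assert all(len(f.members) == 1 for f in fams)

    def test_unknown_gene_rejected(self):
        genomes = self._genomes({"G1": ["a"], "G2": ["b"]})
        with pytest.raises(PangenomeError, match="ghost"):
            build_families([_hit("a", "ghost")], genomes)

    def test_planted_families_recovered_exactly(self):
        cfg = SimConfig(seed=5)
        genes, truth = gen_genomes(cfg)
        by_genome: dict[str, list] = {}
        for g in genes:
            by_genome.setdefault(g.genome, []).append(g)
        hits = all_vs_all_homology(by_genome)
        fams = build_families(hits, by_genome)
        recovered = {
            frozenset(g.gene for g in f.members) for f in fams
        }
        expected_groups: dict[str, set] = {}
        for gid, row in truth.items():
            expected_groups.setdefault(row["family"], set()).add(gid)
        assert recovered == {frozenset(v) for v in expected_groups.values()}


class TestPartition:
    def _toy_families(self):
        mk = lambda fam, genomes: GeneFamily(  # noqa: E731
            fam, [GeneRecord(g, f"{fam}@{g}", "MKV") for g in genomes]
        )
        return [
            mk("a", ["G1", "G2", "G3", "G4"]),
            mk("b", ["G1"]),
            mk("c", ["G3"]),
        ]

    def test_toy_counts(self):
        part = partition_pangenome(self._toy_families())
        assert part.core_families == 1
        assert part.pangenome_families == 3
        assert part.per_genome["G1"]["n_unique"] == 1
        assert part.per_genome["G1"]["n_core"] == 1
        assert part.per_genome["G2"]["n_unique"] == 0

    def test_disjoint_genomes_have_empty_core(self):
        fams = [
            GeneFamily("u1", [GeneRecord("G1", "x", "MKV")]),
            GeneFamily("u2", [GeneRecord("G2", "y", "MKV")]),
        ]
        part = partition_pangenome(fams)
        assert part.core_families == 0

    def test_per_genome_counts_sum_to_genome_size(self):
        cfg = SimConfig(seed=5)
        genes, _ = gen_genomes(cfg)
        by_genome: dict[str, list] = {}
        for g in genes:
            by_genome.setdefault(g.genome, []).append(g)
        hits = all_vs_all_homology(by_genome)
        fams = build_families(hits, by_genome)
        part = partition_pangenome(fams)
        for genome, rec in part.per_genome.items():
            assert (
                rec["n_core"]
                + rec["n_span3"]
                + rec["n_span2"]
                + rec["n_unique"]
                == rec["total"]
                == len(by_genome[genome])
            )

    def test_published_four_microbe_percentages(self):
        # repertoire sizes and shared-gene counts of the four-intracellular-
        # microbe comparison (bacterium / archaeon / microsporidian / giant
        # virus); the percentage report must reproduce the printed values
        totals = {"R_bellii": 1430, "M_luminyensis": 2533,
                  "E_intestinalis": 1910, "Tupanvirus": 1269}
        core = {g: 33 for g in totals}
        span3 = {"R_bellii": 23, "M_luminyensis": 68,
                 "E_intestinalis": 13, "Tupanvirus": 68}
        shared = {"R_bellii": 261, "M_luminyensis": 362,
                  "E_intestinalis": 298, "Tupanvirus": 132}
        part = PangenomePartition.from_counts(totals, core, span3, shared)
        pg = part.per_genome
        assert pg["Tupanvirus"]["pct_core"] == 2.6
        assert pg["M_luminyensis"]["pct_core"] == 1.3
        core_pcts = [pg[g]["pct_core"] for g in totals]
        assert min(core_pcts) == 1.3 and max(core_pcts) == 2.6
        assert pg["R_bellii"]["pct_span3"] == 1.6
        assert pg["E_intestinalis"]["pct_span3"] == 0.7
        assert pg["Tupanvirus"]["pct_span3"] == 5.4
        assert pg["R_bellii"]["pct_shared_any"] == 18.3
        assert pg["M_luminyensis"]["pct_shared_any"] == 14.3
        assert pg["E_intestinalis"]["pct_shared_any"] == 15.6
        assert pg["Tupanvirus"]["pct_shared_any"] == 10.4

    def test_rounding_is_half_away_from_zero(self):
        assert round_percentage(1, 8) == 12.5
        assert round_percentage(5, 4000) == 0.1  # 0.125 -> 0.1
        assert round_percentage(1, 1600) == 0.1  # 0.0625 -> 0.1
        assert round_percentage(3, 4000) == 0.1  # 0.075 rounds up


class TestIO:
    def test_fasta_round_trip(self, tmp_path, rng):
        genes = [
            GeneRecord("G1", "g1", _random_protein(rng, 30)),
            GeneRecord("G2", "g2", _random_protein(rng, 25)),
        ]
        path = tmp_path / "genes.faa"
        write_fasta(genes, path)
        back = read_fasta(path)
        assert [(g.genome, g.gene, g.sequence) for g in back] == [
            (g.genome, g.gene, g.sequence) for g in genes
        ]

    def test_hits_tsv_round_trip(self):
        hits = [
            HomologyHit("q1", "s1", 55.5, 0.8, 0.7, 120.0, 1e-20,
                        ("Viruses", "Fam", "Gen")),
            HomologyHit("q2", "s2", 30.0, 0.5, 0.4, 40.0, 1e-4),
        ]
        buf = io.StringIO()
        write_hits_tsv(hits, buf)
        back = read_hits_tsv(io.StringIO(buf.getvalue()))
        assert [h.query for h in back] == ["q1", "q2"]
        assert back[0].taxonomy == ("Viruses", "Fam", "Gen")
        assert back[0].query_coverage == pytest.approx(0.8)
        assert back[1].evalue == pytest.approx(1e-4)
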