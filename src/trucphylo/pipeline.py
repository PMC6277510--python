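"""End-to-end orchestration of the synthetic evidence chain.

``run_pipeline`` sequences every stage — simulation, matrix construction
and filtering, maximum-parsimony tree with bootstrap and a-posteriori
rooting, character-fit indices vs age, age-weighted ordination, phyletic
clustering, four-genome pangenome and rhizome classification — into one
run directory with a provenance log.  Each stage is also callable on its
own through the functions it delegates to (see the CLI subcommands).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .matrix import (
    PresenceAbsenceMatrix,
    filter_parsimony_informative,
    read_assignments,
    select_universal,
    sharing_pattern_counts,
    write_ages_tsv,
    write_nexus,
    write_tsv,
)
from .ordination import evo_pcoa, group_separation, write_coordinates_tsv
from .pangenome import (
    Thresholds,
    all_vs_all_homology,
    build_families,
    partition_pangenome,
    write_fasta,
)
from .parsimony import (
    SearchConfig,
    bootstrap_support,
    character_fit,
    fit_vs_age_table,
    lundberg_root,
    mp_search,
)
from .phyletic import cluster_phyletic, four_branch_check
from .rhizome import aggregate_rhizome, classify_best_hits, write_circos_table
from .simulate import (
    SELF_TAXONOMY,
    SimConfig,
    config_to_dict,
    gen_four_group_matrix,
    gen_genomes,
    gen_hit_table,
    write_assignments_tsv,
    write_truth_donors_tsv,
    write_truth_families_tsv,
)

logger = logging.getLogger("trucphylo")


class PipelineStageError(RuntimeError):
    """A stage failed; the message names the stage.  Partial outputs of
    earlier stages remain in the run directory."""


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    ``sim`` controls the synthetic inputs; the remaining fields control
    the analysis stages.  The configuration is serialized (with its hash)
    alongside the outputs, so a run is reproducible from its directory.
    """

    outdir: str | Path = "trucphylo_run"
    sim: SimConfig = field(default_factory=SimConfig)
    bootstrap_reps: int = 100
    n_random_starts: int = 3
    rearrangement: str = "SPR"
    # replicate searches use stepwise addition + NNI: the standard fast
    # bootstrap compromise; the reference tree still gets the full search
    bootstrap_rearrangement: str = "NNI"
    goloboff_k: float = 2.0
    linkage: str = "average"
    pcoa_axes: int = 3
    exclusion_rank: str = "family"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = {
            "outdir": str(self.outdir),
            "sim": config_to_dict(self.sim),
            "bootstrap_reps": self.bootstrap_reps,
            "n_random_starts": self.n_random_starts,
            "rearrangement": self.rearrangement,
            "bootstrap_rearrangement": self.bootstrap_rearrangement,
            "goloboff_k": self.goloboff_k,
            "linkage": self.linkage,
            "pcoa_axes": self.pcoa_axes,
            "exclusion_rank": self.exclusion_rank,
            "log_level": self.log_level,
        }
        return d

    def config_hash(self) -> str:
        """Hash of the scientific parameters (paths excluded)."""
        d = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; returns a summary dict (also written as JSON).

    Raises
    ------
    PipelineStageError
        Naming the first failing stage; earlier outputs are retained.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    chash = cfg.config_hash()
    (out / "run_config.json").write_text(
        json.dumps({"config_hash": chash, **cfg.to_dict()}, indent=2),
        encoding="utf-8",
    )
    log_path = out / "run_log.jsonl"
    summary: dict = {"config_hash": chash, "version": __version__}

    def log_stage(stage: str, started: float, **info) -> None:
        rec = {
            "stage": stage,
            "seconds": round(time.perf_counter() - started, 3),
            "seed": cfg.sim.seed,
            "version": __version__,
            **info,
        }
        with open(log_path, "at", encoding="utf-8") as fh:
            fh.write(json.dumps(rec) + "\n")
        logger.info("stage %s done in %.2fs", stage, rec["seconds"])

    def stage(name):
        def deco(fn):
            def wrapped(*a, **kw):
                t0 = time.perf_counter()
                try:
                    result = fn(*a, **kw)
                except Exception as exc:  # noqa: BLE001
                    raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc
                log_stage(name, t0)
                return result

            return wrapped

        return deco

    # -- simulate ---------------------------------------------------------
    @stage("simulate")
    def _simulate():
        matrix, truth_tree, ages = gen_four_group_matrix(cfg.sim)
        write_assignments_tsv(matrix, out / "assignments.tsv", cfg.sim)
        write_ages_tsv(ages, out / "ages.tsv", header=[f"config {chash}"])
        (out / "truth_tree.nwk").write_text(truth_tree.newick() + "\n")
        return matrix, truth_tree

    matrix, truth_tree = _simulate()
    group_map = dict(zip(matrix.taxa, matrix.groups))

    # -- matrix -----------------------------------------------------------
    @stage("matrix")
    def _matrix():
        m = read_assignments(out / "assignments.tsv", group_map)
        m.ages = dict(matrix.ages)
        universal = select_universal(m)
        # trees/ordination/clustering use all informative characters; the
        # universality filter is an ingestion step for heterogeneous real
        # annotations and feeds the sharing-pattern report here
        informative = filter_parsimony_informative(m)
        write_tsv(universal, out / "matrix_universal.tsv")
        write_nexus(informative, out / "matrix_informative.nex")
        venn = sharing_pattern_counts(m)
        (out / "sharing_patterns.json").write_text(json.dumps(venn, indent=2))
        return m, informative

    full_matrix, informative = _matrix()

    # -- mptree -----------------------------------------------------------
    @stage("mptree")
    def _mptree():
        search = SearchConfig(
            n_random_starts=cfg.n_random_starts,
            rearrangement=cfg.rearrangement,
            seed=cfg.sim.seed,
        )
        result = mp_search(informative, search)
        ref, support = bootstrap_support(
            informative,
            reps=cfg.bootstrap_reps,
            seed=cfg.sim.seed,
            search_config=SearchConfig(
                n_random_starts=1, rearrangement=cfg.bootstrap_rearrangement
            ),
            reference=result.tree,
        )
        rooted = lundberg_root(result.tree, informative)
        (out / "mp_tree.nwk").write_text(ref.newick(with_support=True) + "\n")
        (out / "mp_tree_rooted.nwk").write_text(rooted.newick() + "\n")
        summary["mp_best_length"] = result.best_length
        summary["mp_n_best_trees"] = len(result.best_trees)
        summary["min_group_support"] = _group_supports(ref, group_map)
        return result.tree

    mp_tree = _mptree()

    # -- charfit ----------------------------------------------------------
    @stage("charfit")
    def _charfit():
        records = character_fit(mp_tree, informative, k=cfg.goloboff_k)
        table = fit_vs_age_table(records, plot_prefix=out / "fit_vs_age")
        table.to_csv(out / "fit_vs_age.tsv", sep="\t", index=False)
        return records

    _charfit()

    # -- evopcoa ----------------------------------------------------------
    @stage("evopcoa")
    def _evopcoa():
        result = evo_pcoa(full_matrix, k=cfg.pcoa_axes)
        write_coordinates_tsv(result, out / "evo_pcoa.tsv")
        scores = group_separation(result)
        (out / "group_separation.json").write_text(json.dumps(scores, indent=2))
        summary["group_separation"] = scores
        return result

    _evopcoa()

    # -- cluster ----------------------------------------------------------
    @stage("cluster")
    def _cluster():
        dendro = cluster_phyletic(full_matrix, linkage=cfg.linkage)
        (out / "dendrogram.nwk").write_text(dendro.newick() + "\n")
        report = four_branch_check(dendro, group_map)
        (out / "four_branch.json").write_text(
            json.dumps(
                {
                    "purity": report.purity,
                    "cluster_majority": report.cluster_majority,
                    "cluster_sizes": report.cluster_sizes,
                },
                indent=2,
            )
        )
        summary["cluster_purity"] = report.purity
        return report

    _cluster()

    # -- pangenome --------------------------------------------------------
    @stage("pangenome")
    def _pangenome():
        genes, truth = gen_genomes(cfg.sim)
        write_fasta(genes, out / "genomes.faa")
        write_truth_families_tsv(truth, out / "truth_families.tsv", cfg.sim)
        by_genome: dict[str, list] = {}
        for g in genes:
            by_genome.setdefault(g.genome, []).append(g)
        hits = all_vs_all_homology(by_genome, Thresholds())
        families = build_families(hits, by_genome)
        partition = partition_pangenome(families)
        (out / "pangenome.json").write_text(
            json.dumps(
                {
                    "pangenome_families": partition.pangenome_families,
                    "core_families": partition.core_families,
                    "per_genome": partition.per_genome,
                },
                indent=2,
            )
        )
        summary["core_families"] = partition.core_families
        return genes

    genes = _pangenome()

    # -- rhizome ----------------------------------------------------------
    @stage("rhizome")
    def _rhizome():
        hits, truth = gen_hit_table(cfg.sim, genes)
        write_truth_donors_tsv(truth, out / "truth_donors.tsv", cfg.sim)
        assignments = classify_best_hits(
            hits, SELF_TAXONOMY, exclusion_rank=cfg.exclusion_rank
        )
        by_genome: dict[str, list] = {}
        gene_genome = {g.gene: g.genome for g in genes}
        for a in assignments:
            by_genome.setdefault(gene_genome[a.unit], []).append(a)
        summaries = [
            aggregate_rhizome(a_list, genome=genome)
            for genome, a_list in sorted(by_genome.items())
        ]
        write_circos_table(summaries, out / "rhizome_circos.tsv")
        (out / "rhizome.json").write_text(
            json.dumps(
                {
                    s.genome: {"counts": s.counts, "percentages": s.percentages}
                    for s in summaries
                },
                indent=2,
            )
        )
        return summaries

    _rhizome()

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary


def _group_supports(tree, group_map: dict[str, str]) -> dict[str, float]:
    """Bootstrap support of each group's clade split, NaN if not in tree."""
    out: dict[str, float] = {}
    for group in sorted(set(group_map.values())):
        members = frozenset(t for t, g in group_map.items() if g == group)
        key = members
        if tree.taxa[0] in members:
            key = frozenset(set(tree.taxa) - members)
        out[group] = tree.support.get(key, float("nan"))
    return out
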