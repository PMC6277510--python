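"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the inputs of the full evidence chain:

* a binary character matrix evolved on a known four-group tree (balanced
  clades for archaea, bacteria, eukaryota and megavirales joined by a
  single backbone), with per-character gain origins that define both the
  planted presence pattern and a relative age ``nd`` correlated with the
  origin depth;
* four small genomes with planted gene families at controlled sharing
  levels (core / three-genome / two-genome / unique) and controlled
  within-family sequence divergence;
* best-hit tables with controlled donor-class proportions and optional
  same-family decoy hits, for the rhizome classifier.

All generators are deterministic for a fixed seed, and every planted truth
(tree, family spans, donor labels) is returned alongside the data so
downstream recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import __version__
from .matrix import GROUPS, PresenceAbsenceMatrix
from .pangenome import AMINO_ACIDS, GeneRecord, HomologyHit
from .rhizome import DONOR_CLASSES, ORFAN
from .trees import PhyloTree


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


#: Default four genome names (one per microbial group).
DEFAULT_GENOMES = ("bacterium", "archaeon", "eukaryote", "giantvirus")

#: Representative subject taxonomy path per donor class (superkingdom ->
#: genus); purely synthetic lineages.
DONOR_TAXONOMIES: dict[str, tuple[str, ...]] = {
    "virus": ("Viruses", "Synthvirales", "Synthviridae", "Synthvirus"),
    "eukaryota": ("Eukaryota", "Synthophyta", "Synthaceae", "Synthella"),
    "bacteria": ("Bacteria", "Synthobacterales", "Synthobacteraceae", "Synthobacter"),
    "archaea": ("Archaea", "Synthoarchaeales", "Synthoarchaeaceae", "Synthoarchaeum"),
}

#: Taxonomy of the simulated query organism (used for decoy self-hits).
SELF_TAXONOMY = ("Viruses", "Synthvirales", "Mimiviridae", "Selfvirus")


@dataclass
class FamilySpec:
    """One planted gene family: id, genome span, genes per genome, length."""

    family_id: str
    genomes: tuple[str, ...]
    genes_per_genome: int = 1
    length: int = 120


def default_family_spec() -> list[FamilySpec]:
    """Desk-scale default sharing structure over the four genomes.

    Two core families (all four genomes), two three-genome families, three
    two-genome families and three unique families per genome — enough to
    exercise every partition class while keeping all-vs-all alignment fast.
    """
    g = DEFAULT_GENOMES
    spec: list[FamilySpec] = [
        FamilySpec("core1", g),
        FamilySpec("core2", g),
        FamilySpec("tri1", (g[0], g[1], g[3])),
        FamilySpec("tri2", (g[1], g[2], g[3])),
        FamilySpec("duo1", (g[0], g[3])),
        FamilySpec("duo2", (g[1], g[2])),
        FamilySpec("duo3", (g[2], g[3])),
    ]
    for genome in g:
        for k in range(3):
            spec.append(FamilySpec(f"uniq_{genome}_{k + 1}", (genome,)))
    return spec


@dataclass
class SimConfig:
    """All knobs of the synthetic-data generators.

    Defaults are the desk-scale study conditions the pipeline is validated
    under: 8 taxa per group, 200 binary characters with 2% per-branch flip
    noise, mild age jitter, the default family sharing structure, and a
    giant-virus-like donor mix (51% virus / 11% eukaryote / 8% bacterium /
    0.2% archaeon, remainder ORFan).
    """

    n_taxa_per_group: int = 8
    n_characters: int = 200
    gain_rate: float = 0.02
    loss_rate: float = 0.02
    age_noise: float = 0.05
    character_origin: str = "structured"  # or "uniform" / "root"
    family_spec: list[FamilySpec] = field(default_factory=default_family_spec)
    genome_names: tuple[str, ...] = DEFAULT_GENOMES
    mutation_prob: float = 0.30
    donor_props: dict[str, float] = field(
        default_factory=lambda: {
            "virus": 0.51,
            "eukaryota": 0.11,
            "bacteria": 0.08,
            "archaea": 0.002,
        }
    )
    orfan_mode: str = "no_hits"  # or "below_threshold"
    plant_self_family_decoys: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rate in (
            ("gain_rate", self.gain_rate),
            ("loss_rate", self.loss_rate),
        ):
            if not (0.0 <= rate <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {rate}")
        if self.n_taxa_per_group < 2:
            raise ConfigError("need >= 2 taxa per group")
        if self.n_characters < 1:
            raise ConfigError("need >= 1 character")
        if self.age_noise < 0:
            raise ConfigError("age_noise must be >= 0")
        if self.character_origin not in ("structured", "uniform", "root"):
            raise ConfigError(
                "character_origin must be 'structured', 'uniform' or 'root'"
            )
        if self.orfan_mode not in ("no_hits", "below_threshold"):
            raise ConfigError("orfan_mode must be 'no_hits' or 'below_threshold'")
        bad = set(self.donor_props) - set(DONOR_CLASSES)
        if bad:
            raise ConfigError(f"unknown donor classes: {sorted(bad)}")
        if any(p < 0 for p in self.donor_props.values()):
            raise ConfigError("donor proportions must be >= 0")
        if sum(self.donor_props.values()) > 1.0 + 1e-12:
            raise ConfigError("donor proportions must sum to <= 1")
        for fam in self.family_spec:
            unknown = set(fam.genomes) - set(self.genome_names)
            if unknown:
                raise ConfigError(
                    f"family {fam.family_id}: unknown genomes {sorted(unknown)}"
                )

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per generator."""
        return np.random.default_rng([self.seed, stream])


# -- four-group character matrix ------------------------------------------


def _balanced_subtree(tree: PhyloTree, tips: list[int]) -> int:
    """Build a balanced binary subtree over ``tips``; returns its root node."""
    if len(tips) == 1:
        return tips[0]
    mid = len(tips) // 2
    left = _balanced_subtree(tree, tips[:mid])
    right = _balanced_subtree(tree, tips[mid:])
    node = tree.new_node()
    tree.add_edge(node, left)
    tree.add_edge(node, right)
    return node


def four_group_truth_tree(
    n_per_group: int,
) -> tuple[PhyloTree, int, dict[int, int], list[int]]:
    """Unrooted truth tree with the four groups as balanced clades.

    Returns the tree, the backbone node used as simulation root, the
    parent map of the rooted traversal (root's parent is -1), and the four
    group stem nodes (the root of each group's clade).
    """
    taxa = [
        f"{g[:3]}_{i + 1:02d}" for g in GROUPS for i in range(n_per_group)
    ]
    tree = PhyloTree(taxa)
    roots = []
    for gi in range(4):
        tips = list(range(gi * n_per_group, (gi + 1) * n_per_group))
        roots.append(_balanced_subtree(tree, tips))
    hub_ab = tree.new_node()
    tree.add_edge(hub_ab, roots[0])
    tree.add_edge(hub_ab, roots[1])
    hub_ev = tree.new_node()
    tree.add_edge(hub_ev, roots[2])
    tree.add_edge(hub_ev, roots[3])
    tree.add_edge(hub_ab, hub_ev)
    parent: dict[int, int] = {hub_ab: -1}
    for node, par in reversed(tree.postorder(root=hub_ab)):
        if par != -1:
            parent[node] = par
    return tree, hub_ab, parent, roots


def gen_four_group_matrix(
    cfg: SimConfig,
) -> tuple[PresenceAbsenceMatrix, PhyloTree, dict[str, float]]:
    """Evolve binary characters on the four-group truth tree.

    Each character originates as a gain at one node of the rooted truth
    tree: tips below the origin start present, all others absent.
    Per-branch flip noise then converts 0->1 with ``gain_rate`` and 1->0
    with ``loss_rate`` along every edge below the root.  The character age
    is the origin's depth scaled to [0, 1] (0 = root, i.e. most ancient)
    plus Gaussian jitter of sd ``age_noise``, clipped to [0, 1].

    Origin sampling modes (``character_origin``):

    * ``"structured"`` (default): a mixture emulating real phyletic
      profiles, in which group-diagnostic features are common — 45% of
      characters originate at one of the four group stems, 15% at the
      deep backbone (ancient, near-universal characters), and the rest
      uniformly across all remaining nodes (sub-clade characters and
      autapomorphies).  This guarantees the recoverable four-clade signal
      the generator exists to plant.
    * ``"uniform"``: uniform over all nodes of the rooted tree.
    * ``"root"``: every character originates at the root (all-present
      before noise).

    Returns the matrix (ages attached), the unrooted truth tree, and the
    age map.
    """
    rng = cfg.rng(1)
    tree, sim_root, parent, stems = four_group_truth_tree(cfg.n_taxa_per_group)
    n_tips = tree.n_tips
    # children lists and top-down order for the rooted traversal
    topdown = [n for n, _ in reversed(tree.postorder(root=sim_root))]
    depths = {sim_root: 0}
    for node in topdown[1:]:
        depths[node] = depths[parent[node]] + 1
    max_depth = max(depths.values())
    nodes = sorted(depths)
    deep = sorted({sim_root} | {parent[s] for s in stems})

    def sample_origin() -> int:
        if cfg.character_origin == "root":
            return sim_root
        if cfg.character_origin == "uniform":
            return nodes[int(rng.integers(len(nodes)))]
        u = rng.random()
        if u < 0.45:
            return stems[int(rng.integers(4))]
        if u < 0.60:
            return deep[int(rng.integers(len(deep)))]
        rest = [n for n in nodes if n not in set(stems) | set(deep)]
        return rest[int(rng.integers(len(rest)))]

    data = np.zeros((n_tips, cfg.n_characters), dtype=np.uint8)
    ages: dict[str, float] = {}
    features = [f"FSF{j + 1:04d}" for j in range(cfg.n_characters)]
    for j in range(cfg.n_characters):
        origin = sample_origin()
        state: dict[int, int] = {}
        for node in topdown:
            if node == origin:
                state[node] = 1
            elif node == sim_root:
                state[node] = 0
            else:
                s = state[parent[node]]
                if s == 0 and rng.random() < cfg.gain_rate:
                    s = 1
                elif s == 1 and rng.random() < cfg.loss_rate:
                    s = 0
                state[node] = s
        data[:, j] = [state[i] for i in range(n_tips)]
        nd = depths[origin] / max_depth
        if cfg.age_noise > 0:
            nd += rng.normal(0.0, cfg.age_noise)
        ages[features[j]] = float(np.clip(nd, 0.0, 1.0))
    groups = [g for g in GROUPS for _ in range(cfg.n_taxa_per_group)]
    matrix = PresenceAbsenceMatrix(tree.taxa, groups, features, data, dict(ages))
    return matrix, tree, ages


# -- four genomes with planted families ------------------------------------


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(
        AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=length)
    )


def _mutate(rng: np.random.Generator, seq: str, p: float) -> str:
    out = []
    for aa in seq:
        if rng.random() < p:
            choices = AMINO_ACIDS.replace(aa, "")
            out.append(choices[int(rng.integers(len(choices)))])
        else:
            out.append(aa)
    return "".join(out)


def gen_genomes(
    cfg: SimConfig,
) -> tuple[list[GeneRecord], dict[str, dict[str, str]]]:
    """Generate the planted gene families as FASTA-writable gene records.

    Every family gets a random ancestral protein; each member gene is the
    ancestor with independent per-site substitutions at
    ``cfg.mutation_prob``, keeping within-family identity well above the
    clustering threshold.  The truth table maps every gene id to its
    family and genome.

    Raises
    ------
    ConfigError
        If the family specification is empty.
    """
    if not cfg.family_spec:
        raise ConfigError("family_spec must not be empty")
    rng = cfg.rng(2)
    genes: list[GeneRecord] = []
    truth: dict[str, dict[str, str]] = {}
    for fam in cfg.family_spec:
        ancestor = _random_protein(rng, fam.length)
        for genome in fam.genomes:
            for k in range(fam.genes_per_genome):
                gid = f"{genome}|{fam.family_id}|{k + 1}"
                seq = _mutate(rng, ancestor, cfg.mutation_prob)
                genes.append(GeneRecord(genome, gid, seq))
                truth[gid] = {"family": fam.family_id, "genome": genome}
    return genes, truth


# -- hit tables with planted donors ----------------------------------------


def gen_hit_table(
    cfg: SimConfig, genes: Sequence[GeneRecord]
) -> tuple[dict[str, list[HomologyHit]], dict[str, str]]:
    """Planted best-hit tables for the rhizome classifier.

    Each gene draws a donor class from ``cfg.donor_props`` (remaining mass
    = ORFan).  Non-ORFan genes get a top-scoring hit whose subject carries
    the planted donor taxonomy plus a lower-scoring hit from another class;
    ORFans get no hit (``orfan_mode="no_hits"``) or only a hit failing the
    e-value threshold (``"below_threshold"``).  With
    ``plant_self_family_decoys`` every non-ORFan gene additionally gets a
    highest-scoring hit from the query's own family
    (:data:`SELF_TAXONOMY`), which family/genus exclusion must discard.

    Returns hits per gene id and the truth donor table.
    """
    rng = cfg.rng(3)
    classes = list(cfg.donor_props) + [ORFAN]
    probs = list(cfg.donor_props.values())
    probs.append(max(0.0, 1.0 - sum(probs)))
    probs = np.array(probs) / np.sum(probs)
    hits: dict[str, list[HomologyHit]] = {}
    truth: dict[str, str] = {}
    other = {c: [d for d in DONOR_CLASSES if d != c] for c in DONOR_CLASSES}
    for i, gene in enumerate(genes):
        donor = classes[int(rng.choice(len(classes), p=probs))]
        truth[gene.gene] = donor
        gene_hits: list[HomologyHit] = []
        if donor == ORFAN:
            if cfg.orfan_mode == "below_threshold":
                gene_hits.append(
                    HomologyHit(
                        gene.gene, f"weak_subj_{i}", 25.0, 0.4, 0.4,
                        score=18.0, evalue=5.0,
                        taxonomy=DONOR_TAXONOMIES["bacteria"],
                    )
                )
        else:
            top_score = 120.0 + float(rng.random()) * 40.0
            gene_hits.append(
                HomologyHit(
                    gene.gene, f"{donor}_subj_{i}",
                    identity=55.0 + float(rng.random()) * 25.0,
                    query_coverage=0.9, subject_coverage=0.9,
                    score=top_score, evalue=1e-30,
                    taxonomy=DONOR_TAXONOMIES[donor],
                )
            )
            runner = other[donor][int(rng.integers(len(other[donor])))]
            gene_hits.append(
                HomologyHit(
                    gene.gene, f"{runner}_subj_{i}",
                    identity=35.0 + float(rng.random()) * 10.0,
                    query_coverage=0.7, subject_coverage=0.7,
                    score=top_score - 30.0 - float(rng.random()) * 20.0,
                    evalue=1e-10,
                    taxonomy=DONOR_TAXONOMIES[runner],
                )
            )
            if cfg.plant_self_family_decoys:
                gene_hits.append(
                    HomologyHit(
                        gene.gene, f"self_subj_{i}",
                        identity=95.0, query_coverage=1.0, subject_coverage=1.0,
                        score=top_score + 100.0, evalue=1e-80,
                        taxonomy=SELF_TAXONOMY,
                    )
                )
        hits[gene.gene] = gene_hits
    return hits, truth


def gen_chimeric_gene(
    cfg: SimConfig,
    length: int = 400,
    junction: int = 200,
    donor_n: str = "eukaryota",
    donor_c: str = "virus",
    window: int = 40,
    step: int = 20,
    min_len: int = 20,
) -> tuple[GeneRecord, dict[str, list[HomologyHit]], int]:
    """A planted chimeric gene: N-side fragments hit one donor pool,
    C-side fragments the other.

    A fragment is assigned to the donor whose side covers the majority of
    it (midpoint rule).  Returns the gene, per-fragment hit lists and the
    junction position.
    """
    from .rhizome import fragment_protein

    rng = cfg.rng(4)
    gene = GeneRecord("chimera_host", "chimeric_gene", _random_protein(rng, length))
    hits: dict[str, list[HomologyHit]] = {}
    for frag in fragment_protein(gene.sequence, gene.gene, window, step, min_len):
        midpoint = (frag.start + frag.end) / 2
        donor = donor_n if midpoint < junction else donor_c
        hits[frag.fragment_id] = [
            HomologyHit(
                frag.fragment_id, f"{donor}_frag_subj_{frag.start}",
                identity=60.0, query_coverage=1.0, subject_coverage=0.9,
                score=80.0, evalue=1e-20, taxonomy=DONOR_TAXONOMIES[donor],
            )
        ]
    return gene, hits, junction


# -- writers ---------------------------------------------------------------


def provenance_header(cfg: SimConfig) -> str:
    return f"# trucphylo v{__version__} seed={cfg.seed}"


def write_assignments_tsv(
    m: PresenceAbsenceMatrix, dest: str | Path, cfg: SimConfig | None = None
) -> None:
    """Dump a matrix as the two-column assignment table the readers ingest."""
    lines = []
    if cfg is not None:
        lines.append(provenance_header(cfg))
    for i, taxon in enumerate(m.taxa):
        for j, feat in enumerate(m.features):
            if m.data[i, j]:
                lines.append(f"{taxon}\t{feat}")
    Path(dest).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_truth_families_tsv(
    truth: Mapping[str, Mapping[str, str]], dest: str | Path,
    cfg: SimConfig | None = None,
) -> None:
    lines = []
    if cfg is not None:
        lines.append(provenance_header(cfg))
    lines.append("gene_id\tfamily_id\tgenome")
    for gid, row in truth.items():
        lines.append(f"{gid}\t{row['family']}\t{row['genome']}")
    Path(dest).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_truth_donors_tsv(
    truth: Mapping[str, str], dest: str | Path, cfg: SimConfig | None = None
) -> None:
    lines = []
    if cfg is not None:
        lines.append(provenance_header(cfg))
    lines.append("gene_id\tdonor")
    for gid, donor in truth.items():
        lines.append(f"{gid}\t{donor}")
    Path(dest).write_text("\n".join(lines) + "\n", encoding="utf-8")


def config_to_dict(cfg: SimConfig) -> dict:
    """JSON/YAML-serializable form of a configuration."""
    d = asdict(cfg)
    d["genome_names"] = list(cfg.genome_names)
    d["family_spec"] = [
        {**asdict(f), "genomes": list(f.genomes)} for f in cfg.family_spec
    ]
    return d


def config_from_dict(d: Mapping) -> SimConfig:
    d = dict(d)
    if "family_spec" in d:
        d["family_spec"] = [
            FamilySpec(
                f["family_id"], tuple(f["genomes"]),
                f.get("genes_per_genome", 1), f.get("length", 120),
            )
            for f in d["family_spec"]
        ]
    if "genome_names" in d:
        d["genome_names"] = tuple(d["genome_names"])
    if "donor_props" in d:
        d["donor_props"] = dict(d["donor_props"])
    return SimConfig(**d)
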