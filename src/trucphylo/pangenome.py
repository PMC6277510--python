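"""Four-genome pangenome: homology search, gene families, core/shared/unique.

Gene repertoires are compared all-vs-all by local protein alignment at
ProteinOrtho-style thresholds (e-value <= 1e-3, identity >= 20%, query
coverage >= 30%), reciprocal passing hits become edges of a homology graph,
connected components define gene families, and families are partitioned by
the number of genomes they span: the core genome (all genomes), partially
shared families, and genes unique to one genome.  Percentages are reported
to one decimal as counts over genome size.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import networkx as nx
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1
#: (the standard gapped protein-search statistics).
KA_LAMBDA = 0.267
KA_K = 0.041


class PangenomeError(ValueError):
    """Raised for invalid genomes, hits or family structures."""


@dataclass
class GeneRecord:
    """One protein-coding gene: genome of origin, id and amino-acid sequence."""

    genome: str
    gene: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - set(AMINO_ACIDS + "X")
        if bad:
            raise PangenomeError(
                f"gene {self.gene}: invalid residues {sorted(bad)}"
            )


@dataclass
class HomologyHit:
    """A pairwise local-alignment hit in BLAST tabular spirit.

    ``taxonomy`` is the ordered taxonomy path of the subject (superkingdom
    first), used by the rhizome classifier; it may be empty for
    within-dataset hits.
    """

    query: str
    subject: str
    identity: float  # percent, 0-100
    query_coverage: float  # fraction of query, 0-1
    subject_coverage: float  # fraction of subject, 0-1
    score: float
    evalue: float
    taxonomy: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise PangenomeError(f"identity {self.identity} outside [0, 100]")
        if not (0.0 <= self.query_coverage <= 1.0) or not (
            0.0 <= self.subject_coverage <= 1.0
        ):
            raise PangenomeError("coverage fractions must lie in [0, 1]")
        if self.evalue < 0:
            raise PangenomeError("e-value must be >= 0")


@dataclass
class Thresholds:
    """ProteinOrtho-style hit acceptance thresholds."""

    evalue: float = 1e-3
    identity: float = 20.0  # percent
    coverage: float = 0.30  # fraction of the query

    def passes(self, hit: HomologyHit) -> bool:
        return (
            hit.evalue <= self.evalue
            and hit.identity >= self.identity
            and hit.query_coverage >= self.coverage
        )


@dataclass
class GeneFamily:
    family_id: str
    members: list[GeneRecord]

    @property
    def span(self) -> frozenset[str]:
        return frozenset(g.genome for g in self.members)

    def genes_of(self, genome: str) -> list[GeneRecord]:
        return [g for g in self.members if g.genome == genome]


# -- alignment -----------------------------------------------------------


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def align_pair(
    query: GeneRecord,
    subject: GeneRecord,
    search_space: float | None = None,
    aligner: PairwiseAligner | None = None,
) -> HomologyHit | None:
    """Best local alignment between two genes as a HomologyHit.

    The e-value follows Karlin-Altschul statistics with standard gapped
    BLOSUM62 parameters: bitscore = (lambda*S - ln K)/ln 2 and
    E = search_space / 2**bitscore, where the search space defaults to
    query length x subject length.  Returns None when no positive-score
    local alignment exists.
    """
    aligner = aligner or _make_aligner()
    q, s = query.sequence.upper(), subject.sequence.upper()
    if not q or not s:
        raise PangenomeError("cannot align an empty sequence")
    alignments = aligner.align(q, s)
    if alignments.score <= 0:
        return None
    aln = alignments[0]
    counts = aln.counts()
    aln_len = counts.gaps + counts.identities + counts.mismatches
    identity = 100.0 * counts.identities / aln_len if aln_len else 0.0
    q_blocks, s_blocks = aln.aligned
    q_span = q_blocks[-1][1] - q_blocks[0][0]
    s_span = s_blocks[-1][1] - s_blocks[0][0]
    raw = float(aln.score)
    bits = (KA_LAMBDA * raw - _LN_K) / _LN2
    space = search_space if search_space is not None else len(q) * len(s)
    evalue = space / 2.0**bits
    return HomologyHit(
        query=query.gene,
        subject=subject.gene,
        identity=identity,
        query_coverage=q_span / len(q),
        subject_coverage=s_span / len(s),
        score=bits,
        evalue=evalue,
    )


_LN_K = math.log(KA_K)
_LN2 = math.log(2.0)


def all_vs_all_homology(
    genomes: Mapping[str, Sequence[GeneRecord]],
    thresholds: Thresholds | None = None,
) -> list[HomologyHit]:
    """All inter-genome pairwise hits passing the acceptance thresholds.

    Both directions of every gene pair are evaluated (coverage is
    query-sided, so A->B and B->A can differ); downstream family building
    requires reciprocity.

    Raises
    ------
    PangenomeError
        If fewer than two genomes are given or any genome is empty.
    """
    if len(genomes) < 2:
        raise PangenomeError("need >= 2 genomes for an all-vs-all comparison")
    for name, genes in genomes.items():
        if not genes:
            raise PangenomeError(f"genome {name!r} is empty")
    thresholds = thresholds or Thresholds()
    aligner = _make_aligner()
    total_residues = sum(
        len(g.sequence) for genes in genomes.values() for g in genes
    )
    hits: list[HomologyHit] = []
    names = sorted(genomes)
    for i, ga in enumerate(names):
        for gb in names[i + 1:]:
            for a in genomes[ga]:
                for b in genomes[gb]:
                    for query, subject in ((a, b), (b, a)):
                        hit = align_pair(
                            query,
                            subject,
                            search_space=len(query.sequence) * total_residues,
                            aligner=aligner,
                        )
                        if hit is not None and thresholds.passes(hit):
                            hits.append(hit)
    return hits


def filter_hits(
    hits: Iterable[HomologyHit], thresholds: Thresholds | None = None
) -> list[HomologyHit]:
    """Threshold-filter precomputed (ingested) hits."""
    thresholds = thresholds or Thresholds()
    return [h for h in hits if thresholds.passes(h)]


# -- family construction and partitioning --------------------------------


def build_families(
    hits: Iterable[HomologyHit],
    genomes: Mapping[str, Sequence[GeneRecord]],
) -> list[GeneFamily]:
    """Gene families as connected components of the reciprocal-hit graph.

    An edge joins two genes only when passing hits exist in both
    directions.  Genes with no edges become singleton (unique) families.
    Families are numbered deterministically by their lexicographically
    smallest member.

    Raises
    ------
    PangenomeError
        If a hit references a gene absent from the genomes.
    """
    by_id: dict[str, GeneRecord] = {}
    for genes in genomes.values():
        for g in genes:
            if g.gene in by_id:
                raise PangenomeError(f"duplicate gene id {g.gene!r} across genomes")
            by_id[g.gene] = g
    directed: set[tuple[str, str]] = set()
    for h in hits:
        if h.query not in by_id:
            raise PangenomeError(f"hit references unknown gene {h.query!r}")
        if h.subject not in by_id:
            raise PangenomeError(f"hit references unknown gene {h.subject!r}")
        if h.query != h.subject:
            directed.add((h.query, h.subject))
    graph = nx.Graph()
    graph.add_nodes_from(by_id)
    graph.add_edges_from(
        (a, b) for a, b in directed if (b, a) in directed and a < b
    )
    components = sorted(nx.connected_components(graph), key=min)
    return [
        GeneFamily(f"fam{i + 1:05d}", [by_id[g] for g in sorted(comp)])
        for i, comp in enumerate(components)
    ]


def round_percentage(count: int, total: int) -> float:
    """100*count/total to one decimal, rounding half away from zero."""
    if total == 0:
        raise PangenomeError("cannot report a percentage of an empty genome")
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class PangenomePartition:
    """Core/shared/unique partition of a multi-genome gene set.

    ``per_genome[g]`` carries the gene counts of genome ``g`` in families
    spanning all genomes (``n_core``), exactly three (``n_span3``), exactly
    two (``n_span2``), at least two (``n_shared_any``) and one
    (``n_unique``), plus the corresponding percentages of the genome's
    ``total`` gene count at one-decimal rounding.
    """

    genomes: list[str]
    per_genome: dict[str, dict[str, float]]
    pangenome_families: int
    core_families: int
    pangenome_genes: int = 0

    @classmethod
    def from_families(
        cls,
        families: Sequence[GeneFamily],
        genome_sizes: Mapping[str, int] | None = None,
    ) -> "PangenomePartition":
        """Partition derived from explicit gene families.

        ``genome_sizes`` defaults to the gene counts present in the
        families (every gene, including singletons, belongs to exactly one
        family).
        """
        genomes = sorted({g.genome for fam in families for g in fam.members})
        n_genomes = len(genomes)
        counted: dict[str, int] = {g: 0 for g in genomes}
        for fam in families:
            for g in fam.members:
                counted[g.genome] += 1
        sizes = dict(genome_sizes) if genome_sizes is not None else counted
        for g in genomes:
            if counted[g] > sizes.get(g, 0):
                raise PangenomeError(
                    f"families contain more genes for {g!r} than its size"
                )
        per: dict[str, dict[str, float]] = {}
        core_families = sum(1 for f in families if len(f.span) == n_genomes)
        for g in genomes:
            counts = {"n_core": 0, "n_span3": 0, "n_span2": 0, "n_unique": 0}
            for fam in families:
                k = len(fam.span)
                n = len(fam.genes_of(g))
                if n == 0:
                    continue
                if k == n_genomes:
                    counts["n_core"] += n
                if k == 3:
                    counts["n_span3"] += n
                if k == 2:
                    counts["n_span2"] += n
                if k == 1:
                    counts["n_unique"] += n
            # genes of the genome absent from every family are unique
            counts["n_unique"] += sizes[g] - counted[g]
            counts["n_shared_any"] = sizes[g] - counts["n_unique"]
            total = sizes[g]
            per[g] = {
                "total": total,
                **counts,
                "pct_core": round_percentage(counts["n_core"], total),
                "pct_span3": round_percentage(counts["n_span3"], total),
                "pct_shared_any": round_percentage(counts["n_shared_any"], total),
                "pct_unique": round_percentage(counts["n_unique"], total),
            }
        return cls(
            genomes=genomes,
            per_genome=per,
            pangenome_families=len(families),
            core_families=core_families,
            pangenome_genes=sum(len(f.members) for f in families),
        )

    @classmethod
    def from_counts(
        cls,
        totals: Mapping[str, int],
        core: Mapping[str, int],
        span3: Mapping[str, int],
        shared_any: Mapping[str, int],
        pangenome_genes: int = 0,
        core_families: int = 0,
    ) -> "PangenomePartition":
        """Percentage report from externally determined counts.

        Used when the family analysis was run elsewhere and only the
        per-genome gene counts are available: the reporting arithmetic
        (percent of genome size at one-decimal rounding) is identical to
        :meth:`from_families`.
        """
        genomes = sorted(totals)
        per = {}
        for g in genomes:
            total = totals[g]
            n_unique = total - shared_any[g]
            per[g] = {
                "total": total,
                "n_core": core[g],
                "n_span3": span3[g],
                "n_span2": shared_any[g] - core[g] - span3[g],
                "n_shared_any": shared_any[g],
                "n_unique": n_unique,
                "pct_core": round_percentage(core[g], total),
                "pct_span3": round_percentage(span3[g], total),
                "pct_shared_any": round_percentage(shared_any[g], total),
                "pct_unique": round_percentage(n_unique, total),
            }
        return cls(
            genomes=genomes,
            per_genome=per,
            pangenome_families=0,
            core_families=core_families,
            pangenome_genes=pangenome_genes,
        )


def partition_pangenome(
    families: Sequence[GeneFamily],
    genome_sizes: Mapping[str, int] | None = None,
) -> PangenomePartition:
    """Convenience wrapper around :meth:`PangenomePartition.from_families`."""
    return PangenomePartition.from_families(families, genome_sizes)


# -- I/O -----------------------------------------------------------------


def write_fasta(genes: Iterable[GeneRecord], dest: str | Path | TextIO) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.gene, description=f"genome={g.genome}")
        for g in genes
    ]
    if isinstance(dest, (str, Path)):
        with open(dest, "wt", encoding="utf-8") as fh:
            SeqIO.write(records, fh, "fasta")
    else:
        SeqIO.write(records, dest, "fasta")


def read_fasta(source: str | Path | TextIO, genome: str | None = None) -> list[GeneRecord]:
    """Read genes from FASTA; genome comes from ``genome=`` in the
    description unless overridden."""
    records = list(SeqIO.parse(source, "fasta"))
    out = []
    for r in records:
        g = genome
        if g is None:
            for tok in r.description.split():
                if tok.startswith("genome="):
                    g = tok.split("=", 1)[1]
        if g is None:
            raise PangenomeError(f"no genome annotation for {r.id}")
        out.append(GeneRecord(g, r.id, str(r.seq)))
    return out


OUTFMT6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend "
    "sstart send evalue bitscore"
).split()


def write_hits_tsv(hits: Iterable[HomologyHit], dest: str | Path | TextIO) -> None:
    """BLAST outfmt-6-like TSV (12 standard columns + taxonomy column 13).

    Alignment coordinate columns not tracked by :class:`HomologyHit`
    (length, mismatch, gapopen, start/end) are written as 0; coverages are
    encoded in two extra trailing columns so the table round-trips.
    """
    out = io.StringIO()
    out.write("# " + "\t".join(OUTFMT6_COLUMNS + ["staxpath", "qcov", "scov"]) + "\n")
    for h in hits:
        out.write(
            f"{h.query}\t{h.subject}\t{h.identity:.2f}\t0\t0\t0\t0\t0\t0\t0\t"
            f"{h.evalue:.3g}\t{h.score:.1f}\t{';'.join(h.taxonomy)}\t"
            f"{h.query_coverage:.4f}\t{h.subject_coverage:.4f}\n"
        )
    text = out.getvalue()
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text, encoding="utf-8")
    else:
        dest.write(text)


def read_hits_tsv(source: str | Path | TextIO) -> list[HomologyHit]:
    """Read hit tables written by :func:`write_hits_tsv` or plain outfmt 6.

    Plain 12-column tables get taxonomy () and coverages 0 (coverage
    filtering then requires explicit values, so such tables are only
    suitable for e-value/identity filtering or rhizome classification with
    a 13th taxonomy column).
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    hits = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        p = line.split("\t")
        taxonomy = tuple(t for t in p[12].split(";") if t) if len(p) > 12 else ()
        qcov = float(p[13]) if len(p) > 13 else 0.0
        scov = float(p[14]) if len(p) > 14 else 0.0
        hits.append(
            HomologyHit(
                query=p[0],
                subject=p[1],
                identity=float(p[2]),
                query_coverage=qcov,
                subject_coverage=scov,
                score=float(p[11]),
                evalue=float(p[10]),
                taxonomy=taxonomy,
            )
        )
    return hits
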