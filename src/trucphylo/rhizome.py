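"""Genome and gene mosaicism: best-hit donor classification ("rhizomes").

A rhizome drops the single-tree picture of genome evolution: every gene
(or every 40-residue fragment of a gene) is linked to the lineage of its
own best database match.  The classifier maps each query unit to a donor
class — virus, eukaryota, bacteria, archaea — from the superkingdom of the
top-scoring hit after excluding close relatives (same family or genus),
or to ORFan when no usable hit remains.  Aggregated counts are emitted as
a Circos-tableviewer ribbon matrix for circular visualization.

Taxonomy paths are ordered tuples of ranks from superkingdom down to
genus, e.g. ``("Viruses", "Megavirales", "Mimiviridae", "Tupanvirus")``;
by convention the last two ranks are family and genus.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

from .pangenome import GeneRecord, HomologyHit

DONOR_CLASSES = ("virus", "eukaryota", "bacteria", "archaea")
ORFAN = "ORFan"

_SUPERKINGDOM_TO_CLASS = {
    "viruses": "virus",
    "virus": "virus",
    "eukaryota": "eukaryota",
    "eukarya": "eukaryota",
    "bacteria": "bacteria",
    "archaea": "archaea",
}

EXCLUSION_RANKS = ("none", "genus", "family")


class RhizomeError(ValueError):
    """Raised for invalid fragments or classification inputs."""


@dataclass
class Fragment:
    """A sliding-window slice of a protein (0-based, half-open)."""

    parent: str
    start: int
    end: int
    sequence: str

    @property
    def fragment_id(self) -> str:
        return f"{self.parent}:{self.start}-{self.end}"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise RhizomeError("fragment end must exceed start")
        if len(self.sequence) != self.end - self.start:
            raise RhizomeError("fragment sequence length mismatch")


@dataclass
class MosaicAssignment:
    """Donor-class call for one gene or fragment.

    ``donor`` is ORFan iff ``best_hit`` is None.  ``tie`` flags a score tie
    between hits of different donor classes, resolved deterministically by
    (higher identity, then lexicographic subject id).
    """

    unit: str
    donor: str
    best_hit: HomologyHit | None = None
    tie: bool = False

    def __post_init__(self) -> None:
        if (self.donor == ORFAN) != (self.best_hit is None):
            raise RhizomeError("donor is ORFan iff there is no best hit")


def fragment_protein(
    sequence: str,
    parent: str = "gene",
    window: int = 40,
    step: int = 20,
    min_len: int = 20,
) -> list[Fragment]:
    """Cut a protein into overlapping sliding-window fragments.

    Windows start at 0, step, 2*step, ...; the final window is truncated at
    the sequence end and dropped when shorter than ``min_len``.  An empty
    sequence yields no fragments.

    Raises
    ------
    RhizomeError
        If window <= 0 or step outside (0, window].
    """
    if window <= 0 or step <= 0 or step > window:
        raise RhizomeError("require window > 0 and 0 < step <= window")
    n = len(sequence)
    fragments: list[Fragment] = []
    start = 0
    while start < n:
        end = min(start + window, n)
        if end - start >= min_len:
            fragments.append(Fragment(parent, start, end, sequence[start:end]))
        start += step
    return fragments


def donor_class_of(taxonomy: Sequence[str]) -> str | None:
    """Donor class from a taxonomy path, or None when unclassifiable."""
    if not taxonomy:
        return None
    return _SUPERKINGDOM_TO_CLASS.get(taxonomy[0].strip().lower())


def _excluded(
    hit: HomologyHit, query_taxonomy: Sequence[str], exclusion_rank: str
) -> bool:
    if exclusion_rank == "none" or len(query_taxonomy) < 2:
        return False
    q_family, q_genus = query_taxonomy[-2], query_taxonomy[-1]
    if len(hit.taxonomy) < 2:
        return False
    h_family, h_genus = hit.taxonomy[-2], hit.taxonomy[-1]
    if exclusion_rank == "genus":
        return h_genus == q_genus
    if exclusion_rank == "family":
        # excluding at family level also removes same-genus relatives
        return h_family == q_family or h_genus == q_genus
    raise RhizomeError(f"exclusion_rank must be one of {EXCLUSION_RANKS}")


def classify_best_hits(
    hits_by_unit: Mapping[str, Sequence[HomologyHit]],
    query_taxonomy: Sequence[str],
    exclusion_rank: str = "family",
) -> list[MosaicAssignment]:
    """Best-hit donor classification with self-taxon exclusion.

    For each unit, hits matching the query at ``exclusion_rank`` (same
    family and/or genus) are removed, hits without a classifiable taxonomy
    are skipped with a warning, and the top of the remaining hits — sorted
    by descending score, then descending identity, then subject id — sets
    the donor class.  Units with nothing left become ORFans.
    """
    if exclusion_rank not in EXCLUSION_RANKS:
        raise RhizomeError(f"exclusion_rank must be one of {EXCLUSION_RANKS}")
    assignments: list[MosaicAssignment] = []
    for unit in hits_by_unit:
        usable: list[HomologyHit] = []
        for h in hits_by_unit[unit]:
            if donor_class_of(h.taxonomy) is None:
                warnings.warn(
                    f"hit {h.query}->{h.subject}: missing/unclassified "
                    f"taxonomy, skipped",
                    stacklevel=2,
                )
                continue
            if _excluded(h, query_taxonomy, exclusion_rank):
                continue
            usable.append(h)
        if not usable:
            assignments.append(MosaicAssignment(unit, ORFAN, None))
            continue
        usable.sort(key=lambda h: (-h.score, -h.identity, h.subject))
        best = usable[0]
        tie = any(
            h.score == best.score
            and donor_class_of(h.taxonomy) != donor_class_of(best.taxonomy)
            for h in usable[1:]
        )
        assignments.append(
            MosaicAssignment(unit, donor_class_of(best.taxonomy), best, tie)
        )
    return assignments


@dataclass
class RhizomeSummary:
    """Donor-class counts and one-decimal percentages for one genome."""

    genome: str
    counts: dict[str, int]
    percentages: dict[str, float]
    total: int


def aggregate_rhizome(
    assignments: Sequence[MosaicAssignment],
    genome_size: int | None = None,
    genome: str = "genome",
) -> RhizomeSummary:
    """Aggregate per-unit donor calls into class counts and percentages.

    ``genome_size`` defaults to the number of assignments; when larger,
    unassessed genes are counted as ORFans so the counts always partition
    the gene set.
    """
    total = genome_size if genome_size is not None else len(assignments)
    if total < len(assignments):
        raise RhizomeError("genome_size smaller than number of assignments")
    counts = {c: 0 for c in DONOR_CLASSES}
    counts[ORFAN] = 0
    for a in assignments:
        counts[a.donor] += 1
    counts[ORFAN] += total - len(assignments)
    pct = {
        c: float(
            (Decimal(100 * n) / Decimal(total)).quantize(
                Decimal("0.1"), rounding=ROUND_HALF_UP
            )
        )
        if total
        else 0.0
        for c, n in counts.items()
    }
    return RhizomeSummary(genome, counts, pct, total)


def write_circos_table(
    summaries: Iterable[RhizomeSummary], dest: str | Path | TextIO
) -> None:
    """Circos tableviewer ribbon matrix: genome rows vs donor-class columns."""
    out = io.StringIO()
    cols = list(DONOR_CLASSES) + [ORFAN]
    out.write("data\t" + "\t".join(cols) + "\n")
    for s in summaries:
        out.write(s.genome + "\t" + "\t".join(str(s.counts[c]) for c in cols) + "\n")
    text = out.getvalue()
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text, encoding="utf-8")
    else:
        dest.write(text)


@dataclass
class FragmentRhizome:
    """Per-fragment donor calls for one gene plus summary counts."""

    gene: str
    fragments: list[Fragment]
    assignments: list[MosaicAssignment]
    summary: dict[str, int]


def fragment_rhizome(
    gene: GeneRecord,
    hits_per_fragment: Mapping[str, Sequence[HomologyHit]],
    query_taxonomy: Sequence[str],
    exclusion_rank: str = "family",
    window: int = 40,
    step: int = 20,
    min_len: int = 20,
) -> FragmentRhizome:
    """Gene-level rhizome: classify each sliding-window fragment.

    ``hits_per_fragment`` maps fragment ids (``gene:start-end``) to their
    hit lists; fragments without an entry are ORFans.  Summary counts sum
    to the number of fragments.
    """
    fragments = fragment_protein(
        gene.sequence, parent=gene.gene, window=window, step=step, min_len=min_len
    )
    by_unit = {
        f.fragment_id: list(hits_per_fragment.get(f.fragment_id, []))
        for f in fragments
    }
    assignments = classify_best_hits(by_unit, query_taxonomy, exclusion_rank)
    summary = {c: 0 for c in list(DONOR_CLASSES) + [ORFAN]}
    for a in assignments:
        summary[a.donor] += 1
    return FragmentRhizome(gene.gene, fragments, assignments, summary)
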