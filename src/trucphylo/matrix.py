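"""Binary presence/absence matrices over proteomes and structural features.

The central container of the structural-phylogenomics pipeline: rows are
proteomes (taxa) labelled by one of the four microbial groups (archaea,
bacteria, eukaryota, megavirales), columns are binary characters such as
protein fold superfamilies (FSFs) or informational COGs.  A feature may
carry a relative evolutionary age ``nd`` in [0, 1] (0 = most ancient).

Readers/writers cover the tab-separated assignment dumps produced by
domain-annotation scans (one ``proteome_id<TAB>feature_id`` row per
detected occurrence), a plain matrix TSV, and a NEXUS DATA block suitable
for parsimony software interchange.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np

#: Canonical group labels, in the fixed order used throughout the package.
GROUPS = ("archaea", "bacteria", "eukaryota", "megavirales")

#: One-letter Venn labels for the four groups (A, B, E, V as in the field).
GROUP_LETTERS = {"archaea": "A", "bacteria": "B", "eukaryota": "E", "megavirales": "V"}


class MatrixError(ValueError):
    """Raised for malformed or inconsistent presence/absence matrices."""


@dataclass
class PresenceAbsenceMatrix:
    """Taxa x features binary matrix with group labels and optional ages.

    Parameters
    ----------
    taxa
        Ordered unique taxon (proteome) identifiers.
    groups
        Group label for each taxon, aligned with ``taxa``; each must be one
        of :data:`GROUPS`.
    features
        Ordered unique feature (character) identifiers.
    data
        ``(n_taxa, n_features)`` array of 0/1 indicators.
    ages
        Optional map ``feature -> nd`` with every value in [0, 1].
    """

    taxa: list[str]
    groups: list[str]
    features: list[str]
    data: np.ndarray
    ages: dict[str, float] | None = field(default=None)

    def __post_init__(self) -> None:
        self.taxa = list(self.taxa)
        self.groups = list(self.groups)
        self.features = list(self.features)
        self.data = np.asarray(self.data, dtype=np.uint8)
        if len(set(self.taxa)) != len(self.taxa):
            raise MatrixError("duplicate taxon identifiers")
        if len(set(self.features)) != len(self.features):
            raise MatrixError("duplicate feature identifiers")
        if len(self.groups) != len(self.taxa):
            raise MatrixError("one group label required per taxon")
        bad = sorted({g for g in self.groups} - set(GROUPS))
        if bad:
            raise MatrixError(f"unknown group labels: {bad}")
        if self.data.shape != (len(self.taxa), len(self.features)):
            raise MatrixError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.features)} features"
            )
        if not np.isin(self.data, (0, 1)).all():
            raise MatrixError("matrix cells must be 0 or 1")
        if self.ages is not None:
            missing = [f for f in self.ages if f not in set(self.features)]
            if missing:
                raise MatrixError(f"ages given for unknown features: {missing[:5]}")
            out = [f for f, v in self.ages.items() if not (0.0 <= v <= 1.0)]
            if out:
                raise MatrixError(f"ages outside [0, 1] for: {out[:5]}")

    # -- basic accessors -------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def group_of(self, taxon: str) -> str:
        return self.groups[self.taxa.index(taxon)]

    def column(self, feature: str) -> np.ndarray:
        """Binary column for one feature, ordered as ``taxa``."""
        return self.data[:, self.features.index(feature)].copy()

    def age_vector(self) -> np.ndarray:
        """Ages aligned with ``features``; raises if any age is missing."""
        if self.ages is None:
            raise MatrixError("matrix carries no feature ages")
        missing = [f for f in self.features if f not in self.ages]
        if missing:
            raise MatrixError(f"missing ages for features: {missing[:10]}")
        return np.array([self.ages[f] for f in self.features], dtype=float)

    def subset_features(self, keep: Sequence[str]) -> "PresenceAbsenceMatrix":
        keep = list(keep)
        idx = [self.features.index(f) for f in keep]
        ages = None
        if self.ages is not None:
            ages = {f: self.ages[f] for f in keep if f in self.ages}
        return PresenceAbsenceMatrix(
            self.taxa, self.groups, keep, self.data[:, idx], ages
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PresenceAbsenceMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.groups == other.groups
            and self.features == other.features
            and np.array_equal(self.data, other.data)
        )


# -- assignment-table ingestion -----------------------------------------


def read_assignments(
    source: str | Path | TextIO, group_map: Mapping[str, str]
) -> PresenceAbsenceMatrix:
    """Build a presence/absence matrix from a two-column assignment TSV.

    Each row is ``proteome_id<TAB>feature_id``; a cell is 1 iff at least one
    assignment row exists for that (taxon, feature) pair, regardless of copy
    number.  Lines starting with ``#`` are comments.  Taxon and feature
    order follow first appearance.

    Raises
    ------
    MatrixError
        If a proteome is missing from ``group_map`` or the file is empty.
    """
    handle: TextIO
    if isinstance(source, (str, Path)):
        handle = open(source, "rt", encoding="utf-8")
        close = True
    else:
        handle, close = source, False
    taxa: list[str] = []
    features: list[str] = []
    t_idx: dict[str, int] = {}
    f_idx: dict[str, int] = {}
    pairs: set[tuple[int, int]] = set()
    try:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise MatrixError(f"malformed assignment row: {line!r}")
            taxon, feat = parts[0], parts[1]
            if taxon not in group_map:
                raise MatrixError(f"proteome {taxon!r} missing from group map")
            if taxon not in t_idx:
                t_idx[taxon] = len(taxa)
                taxa.append(taxon)
            if feat not in f_idx:
                f_idx[feat] = len(features)
                features.append(feat)
            pairs.add((t_idx[taxon], f_idx[feat]))
    finally:
        if close:
            handle.close()
    if not taxa:
        raise MatrixError("assignment table contains no data rows")
    data = np.zeros((len(taxa), len(features)), dtype=np.uint8)
    rows, cols = zip(*pairs)
    data[list(rows), list(cols)] = 1
    return PresenceAbsenceMatrix(
        taxa, [group_map[t] for t in taxa], features, data
    )


# -- filters -------------------------------------------------------------


def select_universal(m: PresenceAbsenceMatrix) -> PresenceAbsenceMatrix:
    """Keep only features detected in at least one taxon of every group.

    A 'universal' feature must occur in >= 1 archaeon, >= 1 bacterium,
    >= 1 eukaryote and >= 1 megavirales member.  The taxon set is unchanged.

    Raises
    ------
    MatrixError
        If any of the four groups has no taxa (criterion undefined).
    """
    groups = np.array(m.groups)
    absent = [g for g in GROUPS if g not in set(m.groups)]
    if absent:
        raise MatrixError(f"universality undefined: no taxa for groups {absent}")
    keep_mask = np.ones(m.n_features, dtype=bool)
    for g in GROUPS:
        keep_mask &= m.data[groups == g].any(axis=0)
    keep = [f for f, k in zip(m.features, keep_mask) if k]
    return m.subset_features(keep)


def filter_parsimony_informative(m: PresenceAbsenceMatrix) -> PresenceAbsenceMatrix:
    """Keep characters whose both states are each carried by >= 2 taxa.

    Constant characters and autapomorphies (single-taxon presences or
    absences) cannot discriminate topologies under parsimony and are
    dropped.
    """
    ones = m.data.sum(axis=0)
    keep_mask = (ones >= 2) & (m.n_taxa - ones >= 2)
    keep = [f for f, k in zip(m.features, keep_mask) if k]
    return m.subset_features(keep)


def sharing_pattern_counts(m: PresenceAbsenceMatrix) -> dict[str, int]:
    """Venn-style sharing-pattern counts over the four groups.

    Each feature is assigned to exactly one of the 15 nonempty subsets of
    {A, B, E, V} — the set of groups in which it occurs at least once.
    Features present in no taxon at all are counted under the empty-string
    key (they occupy no Venn cell).

    Returns
    -------
    dict
        Keys are subset strings in canonical 'ABEV' letter order (e.g.
        ``"ABEV"``, ``"AV"``); values are feature counts.  All 15 nonempty
        subsets are present, zero-filled.
    """
    groups = np.array(m.groups)
    present = {
        g: m.data[groups == g].any(axis=0) if (groups == g).any()
        else np.zeros(m.n_features, dtype=bool)
        for g in GROUPS
    }
    letters = [GROUP_LETTERS[g] for g in GROUPS]
    counts: dict[str, int] = {}
    for mask in range(1, 16):
        key = "".join(l for i, l in enumerate(letters) if mask >> i & 1)
        counts[key] = 0
    counts[""] = 0
    for j in range(m.n_features):
        key = "".join(
            GROUP_LETTERS[g] for g in GROUPS if present[g][j]
        )
        counts[key] += 1
    if counts[""] == 0:
        del counts[""]
    return counts


# -- serialization -------------------------------------------------------

_NEXUS_SAFE = re.compile(r"^[A-Za-z0-9_.]+$")


def _nexus_label(name: str) -> str:
    if _NEXUS_SAFE.match(name):
        return name
    return "'" + name.replace("'", "''") + "'"


def write_nexus(m: PresenceAbsenceMatrix, dest: str | Path | TextIO) -> None:
    """Write a NEXUS DATA block (SYMBOLS="01", MISSING=?).

    Taxon labels needing quoting (spaces, punctuation) are single-quoted
    per NEXUS rules.  Feature identifiers are recorded as CHARLABELS so the
    matrix round-trips through :func:`read_nexus`.
    """
    out = io.StringIO()
    out.write("#NEXUS\n")
    out.write("BEGIN DATA;\n")
    out.write(f"  DIMENSIONS NTAX={m.n_taxa} NCHAR={m.n_features};\n")
    out.write('  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n')
    out.write("  CHARLABELS\n    ")
    out.write(" ".join(_nexus_label(f) for f in m.features))
    out.write("\n  ;\n")
    out.write("  MATRIX\n")
    width = max(len(_nexus_label(t)) for t in m.taxa)
    for i, t in enumerate(m.taxa):
        row = "".join(str(c) for c in m.data[i])
        out.write(f"    {_nexus_label(t):<{width}}  {row}\n")
    out.write("  ;\nEND;\n")
    _write_text(dest, out.getvalue())


_TOKEN = re.compile(r"'(?:[^']|'')*'|[^\s]+")


def _unquote(tok: str) -> str:
    if tok.startswith("'") and tok.endswith("'"):
        return tok[1:-1].replace("''", "'")
    return tok


def read_nexus(
    source: str | Path | TextIO, group_map: Mapping[str, str] | None = None
) -> PresenceAbsenceMatrix:
    """Read a binary NEXUS DATA block written by :func:`write_nexus`.

    ``group_map`` is required: NEXUS carries no group metadata, but a
    presence/absence matrix always carries a group label per taxon.
    """
    text = _read_text(source)
    if group_map is None:
        raise MatrixError("group_map required to reconstruct group labels")
    char_m = re.search(r"CHARLABELS(.*?);", text, re.S | re.I)
    features: list[str] | None = None
    if char_m:
        features = [_unquote(t) for t in _TOKEN.findall(char_m.group(1))]
    mat_m = re.search(r"MATRIX(.*?);", text, re.S | re.I)
    if not mat_m:
        raise MatrixError("no MATRIX block found")
    taxa: list[str] = []
    rows: list[list[int]] = []
    for line in mat_m.group(1).strip().splitlines():
        line = line.strip()
        if not line:
            continue
        toks = _TOKEN.findall(line)
        name = _unquote(toks[0])
        states = "".join(toks[1:])
        taxa.append(name)
        rows.append([int(c) for c in states])
    if features is None:
        features = [f"char{j + 1}" for j in range(len(rows[0]))]
    missing = [t for t in taxa if t not in group_map]
    if missing:
        raise MatrixError(f"taxa missing from group map: {missing[:5]}")
    return PresenceAbsenceMatrix(
        taxa, [group_map[t] for t in taxa], features, np.array(rows, dtype=np.uint8)
    )


def write_tsv(m: PresenceAbsenceMatrix, dest: str | Path | TextIO) -> None:
    """Matrix TSV with taxa as rows; columns: taxon, group, then features."""
    out = io.StringIO()
    out.write("taxon\tgroup\t" + "\t".join(m.features) + "\n")
    for i, (t, g) in enumerate(zip(m.taxa, m.groups)):
        out.write(t + "\t" + g + "\t" + "\t".join(str(c) for c in m.data[i]) + "\n")
    _write_text(dest, out.getvalue())


def read_tsv(source: str | Path | TextIO) -> PresenceAbsenceMatrix:
    """Read a matrix TSV written by :func:`write_tsv`."""
    text = _read_text(source)
    lines = [l for l in text.splitlines() if l and not l.startswith("#")]
    header = lines[0].split("\t")
    features = header[2:]
    taxa, groups, rows = [], [], []
    for line in lines[1:]:
        parts = line.split("\t")
        taxa.append(parts[0])
        groups.append(parts[1])
        rows.append([int(c) for c in parts[2:]])
    return PresenceAbsenceMatrix(
        taxa, groups, features, np.array(rows, dtype=np.uint8)
    )


def write_ages_tsv(ages: Mapping[str, float], dest: str | Path | TextIO,
                   header: Iterable[str] = ()) -> None:
    """Write ``feature<TAB>nd`` rows, with optional '#'-prefixed header lines."""
    out = io.StringIO()
    for h in header:
        out.write(f"# {h}\n")
    out.write("feature_id\tnd\n")
    for f, v in ages.items():
        out.write(f"{f}\t{v:.6f}\n")
    _write_text(dest, out.getvalue())


def read_ages_tsv(source: str | Path | TextIO) -> dict[str, float]:
    text = _read_text(source)
    ages: dict[str, float] = {}
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("feature_id"):
            continue
        f, v = line.split("\t")
        ages[f] = float(v)
    return ages


def _write_text(dest: str | Path | TextIO, text: str) -> None:
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text, encoding="utf-8")
    else:
        dest.write(text)


def _read_text(source: str | Path | TextIO) -> str:
    if isinstance(source, (str, Path)):
        return Path(source).read_text(encoding="utf-8")
    return source.read()
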