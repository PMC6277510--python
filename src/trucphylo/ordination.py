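"""Evolutionary PCoA: proteome ordination over age-weighted feature vectors.

Each proteome is represented as a real-valued vector whose entry for
feature ``f`` is ``1 - nd_f`` when the feature is present (0 when absent),
so that ancient features (nd near 0) dominate the geometry and the most
recent features (nd near 1) drop out of the distance.  Classical principal
coordinate analysis of the Euclidean distances between these vectors then
projects the proteomes into a low-dimensional "temporal" space in which the
four microbial groups are expected to form distinct clouds.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import TextIO

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

from .matrix import MatrixError, PresenceAbsenceMatrix


@dataclass
class OrdinationResult:
    """Principal-coordinate embedding of taxa.

    ``coordinates`` is ``(n_taxa, K)``; ``eigenvalues`` holds all
    eigenvalues of the centered Gower matrix in descending order;
    ``pct_variance`` gives the percentage of (positive) inertia captured by
    each of the K reported axes.
    """

    taxa: list[str]
    groups: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    coordinates_full: np.ndarray | None = None


def age_weight(m: PresenceAbsenceMatrix) -> np.ndarray:
    """Age-weighted real matrix: (1 - nd) where present, 0 where absent.

    Raises
    ------
    MatrixError
        If any feature lacks an age, listing the offenders.
    """
    nd = m.age_vector()  # raises with the missing features listed
    return m.data.astype(float) * (1.0 - nd)[None, :]


def evo_distances(m: PresenceAbsenceMatrix) -> np.ndarray:
    """Euclidean distance matrix between age-weighted proteome vectors."""
    return squareform(pdist(age_weight(m), metric="euclidean"))


def pcoa(
    distances: np.ndarray,
    taxa: list[str],
    groups: list[str],
    k: int = 3,
    correction: str | None = None,
) -> OrdinationResult:
    """Classical (metric) PCoA by double-centering and eigendecomposition.

    Axis signs are fixed by forcing the largest-magnitude loading on each
    axis positive, so repeated runs and taxon reorderings give reproducible
    coordinates up to row order.  ``correction="lingoes"`` adds the Lingoes
    constant for ingested non-Euclidean matrices; the default applies no
    correction since age-weighted distances are Euclidean by construction.

    Raises
    ------
    MatrixError
        For a non-square, asymmetric, negative-entry or non-zero-diagonal
        matrix.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise MatrixError(f"distance matrix must be square, got {d.shape}")
    if (d < 0).any():
        raise MatrixError("distance matrix has negative entries")
    if not np.allclose(d, d.T, atol=1e-12):
        raise MatrixError("distance matrix is not symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise MatrixError("distance matrix diagonal is not zero")
    n = d.shape[0]
    if len(taxa) != n or len(groups) != n:
        raise MatrixError("taxa/groups length must match distance matrix")

    a = -0.5 * d**2
    if correction == "lingoes":
        # make the Gower matrix PSD by adding a constant to squared distances
        g0 = _double_center(a)
        w0 = eigh(g0, eigvals_only=True)
        c = max(0.0, -w0.min())
        off = ~np.eye(n, dtype=bool)
        a = a.copy()
        a[off] -= c
    g = _double_center(a)
    eigval, eigvec = eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    k = min(k, n)
    pos = eigval.clip(min=0.0)
    coords_full = eigvec * np.sqrt(pos)[None, :]
    # deterministic axis orientation
    for j in range(n):
        col = coords_full[:, j]
        if col.any() and col[np.argmax(np.abs(col))] < 0:
            coords_full[:, j] = -col
    coords = coords_full[:, :k]
    total = pos.sum()
    pct = 100.0 * pos[:k] / total if total > 0 else np.zeros(k)
    return OrdinationResult(
        list(taxa), list(groups), coords, eigval, pct, coords_full
    )


def _double_center(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return j @ a @ j


def evo_pcoa(m: PresenceAbsenceMatrix, k: int = 3) -> OrdinationResult:
    """Age-weighted PCoA of a presence/absence matrix (the evo-PCoA)."""
    return pcoa(evo_distances(m), m.taxa, m.groups, k=k)


def reconstructed_distances(result: OrdinationResult) -> np.ndarray:
    """Pairwise distances implied by all positive-eigenvalue axes.

    For Euclidean input these reproduce the original distances; used as the
    self-check that the embedding is faithful.
    """
    coords = (
        result.coordinates_full
        if result.coordinates_full is not None
        else result.coordinates
    )
    return squareform(pdist(coords, metric="euclidean"))


def group_separation(result: OrdinationResult) -> dict[str, float]:
    """Silhouette-style separation score per group, each in [-1, 1].

    Per-taxon silhouette values (mean within-group vs nearest other-group
    distance contrast) are computed on the embedded coordinates and
    averaged within each group.  Positive scores near 1 indicate a compact,
    well-separated cloud; scores <= 0 indicate overlap with another group.
    """
    from sklearn.metrics import silhouette_samples

    labels = np.array(result.groups)
    if len(set(result.groups)) < 2:
        raise MatrixError("separation undefined for a single group")
    sil = silhouette_samples(result.coordinates, labels)
    return {g: float(sil[labels == g].mean()) for g in dict.fromkeys(result.groups)}


def write_coordinates_tsv(result: OrdinationResult, dest: str | Path | TextIO) -> None:
    """TSV scatter export: taxon, group, one column per axis.

    The header comment carries the percentage of variance per axis so
    external plotting tools can label axes as in a 3D drop-line plot.
    """
    out = io.StringIO()
    pct = ", ".join(f"PCo{i + 1}={p:.2f}%" for i, p in enumerate(result.pct_variance))
    out.write(f"# variance explained: {pct}\n")
    axes = [f"PCo{i + 1}" for i in range(result.coordinates.shape[1])]
    out.write("taxon\tgroup\t" + "\t".join(axes) + "\n")
    for i, (t, g) in enumerate(zip(result.taxa, result.groups)):
        coords = "\t".join(f"{c:.6f}" for c in result.coordinates[i])
        out.write(f"{t}\t{g}\t{coords}\n")
    text = out.getvalue()
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text, encoding="utf-8")
    else:
        dest.write(text)
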