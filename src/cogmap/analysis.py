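"""Eigenmaps, low-dimensional embeddings and clustering diagnostics.

Reshaped eigenvectors of a successor-representation matrix over a grid
environment form periodic, grid-cell-like spatial fields; the larger the
eigenvalue, the coarser the field. Rows of transition or SR matrices can be
embedded in the plane with multidimensional scaling, where word classes (or
spatial neighborhoods) appear as clusters; a centroid-clustering purity
score quantifies how well the embedding separates the labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.manifold import smacof

from .environments import GridEnvironment
from .sr import SuccessorRepresentation

__all__ = [
    "EigenMaps",
    "Embedding2D",
    "eigenmaps_of_sr",
    "mds_embed",
    "embedding_stress",
    "cluster_purity",
    "dominant_frequency_radius",
    "within_class_spread",
]


@dataclass(frozen=True)
class EigenMaps:
    """Leading eigenvalues of an SR matrix with eigenvectors as 2D fields.

    ``maps[i]`` is the real part of the i-th eigenvector reshaped row-major
    to the environment's ``height x width`` lattice. SR matrices are not
    symmetric in general; near-degenerate complex pairs may mix after taking
    real parts, which leaves the field's spatial frequency intact.
    """

    eigenvalues: np.ndarray
    maps: np.ndarray
    order: str

    @property
    def k(self) -> int:
        return len(self.eigenvalues)


@dataclass(frozen=True)
class Embedding2D:
    """2D coordinates per item with item labels."""

    coords: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        if len(self.coords) != len(self.labels):
            raise ValueError("one label per embedded point required")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding coordinates must be finite")


def eigenmaps_of_sr(
    sr: SuccessorRepresentation | np.ndarray,
    env: GridEnvironment,
    k: int = 30,
    order: str = "descending",
) -> EigenMaps:
    """Top-``k`` eigenvectors of the SR, reshaped onto the environment.

    Eigenpairs are sorted by the real part of the eigenvalue (``descending``
    puts the coarsest map first). Wall cells simply carry their (near-zero)
    eigenvector entries; rendering may mask them.
    """
    M = sr.M if isinstance(sr, SuccessorRepresentation) else np.asarray(sr, float)
    n = env.n_cells
    if M.shape != (n, n):
        raise ValueError(
            f"SR shape {M.shape} does not cover the full {env.height}x{env.width} lattice"
        )
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    if order not in ("descending", "ascending"):
        raise ValueError(f"order must be 'descending' or 'ascending', got {order!r}")
    vals, vecs = np.linalg.eig(M)
    idx = np.argsort(vals.real)
    if order == "descending":
        idx = idx[::-1]
    idx = idx[:k]
    maps = np.stack([vecs[:, i].real.reshape(env.height, env.width) for i in idx])
    return EigenMaps(eigenvalues=vals[idx].real, maps=maps, order=order)


def _classical_mds(D: np.ndarray) -> np.ndarray:
    """Torgerson scaling: eigendecomposition of the double-centered -D^2/2."""
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    top = np.argsort(vals)[::-1][:2]
    coords = vecs[:, top] * np.sqrt(np.clip(vals[top], 0.0, None))
    return coords


def mds_embed(
    rows: np.ndarray,
    labels: np.ndarray | None = None,
    method: str = "classical",
    seed: int | None = None,
) -> Embedding2D:
    """Embed row vectors into the plane by multidimensional scaling.

    ``classical`` is the deterministic Torgerson eigendecomposition of the
    double-centered squared Euclidean distance matrix; ``stress`` refines
    that solution with metric SMACOF stress majorization (seeded, and
    initialized from the classical coordinates so its stress can only
    improve). Identical rows embed at identical points; an all-identical
    input set degenerates to the origin with a warning.
    """
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2 or len(rows) < 3:
        raise ValueError("need at least 3 row vectors to embed")
    if labels is None:
        labels = np.arange(len(rows))
    labels = np.asarray(labels)
    D = np.linalg.norm(rows[:, None, :] - rows[None, :, :], axis=-1)
    if np.allclose(D, 0.0):
        warnings.warn("all rows identical; embedding degenerates to the origin")
        return Embedding2D(np.zeros((len(rows), 2)), labels)
    coords = _classical_mds(D)
    if method == "classical":
        return Embedding2D(coords, labels)
    if method != "stress":
        raise ValueError(f"method must be 'classical' or 'stress', got {method!r}")
    coords, _ = smacof(
        D, n_components=2, init=coords, n_init=1,
        random_state=seed, normalized_stress=False,
    )
    return Embedding2D(coords, labels)


def embedding_stress(embedding: Embedding2D, rows: np.ndarray) -> float:
    """Raw stress: sum of squared errors between embedded and true distances."""
    rows = np.asarray(rows, dtype=float)
    D = np.linalg.norm(rows[:, None, :] - rows[None, :, :], axis=-1)
    d = np.linalg.norm(
        embedding.coords[:, None, :] - embedding.coords[None, :, :], axis=-1
    )
    return float(((D - d) ** 2).sum() / 2.0)


def cluster_purity(embedding: Embedding2D, k: int, seed: int | None = 0) -> float:
    """Purity of a k-means clustering of the embedded points.

    Purity is the fraction of items whose cluster's majority label matches
    their own; ties in the majority break toward the lexicographically
    smaller label (which leaves the score unchanged).
    """
    n = len(embedding.coords)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assign = km.fit_predict(embedding.coords)
    correct = 0
    for c in range(k):
        members = embedding.labels[assign == c]
        if members.size == 0:
            continue
        uniq, counts = np.unique(members, return_counts=True)
        majority = uniq[np.lexsort((uniq, -counts))][0]
        correct += int((members == majority).sum())
    return correct / n


def within_class_spread(embedding: Embedding2D) -> float:
    """Mean distance of points to their own class centroid."""
    spreads = []
    for lab in np.unique(embedding.labels):
        pts = embedding.coords[embedding.labels == lab]
        spreads.append(np.linalg.norm(pts - pts.mean(axis=0), axis=1).mean())
    return float(np.mean(spreads))


def dominant_frequency_radius(field: np.ndarray) -> float:
    """Dominant 2D spatial-frequency radius of a field, in cycles per field.

    Uses the type-II discrete cosine transform: cosine modes are the natural
    eigenbasis of a walk with reflecting boundaries, so the half-cycle
    boundary modes land on single DCT bins instead of leaking across the
    periodic-FFT spectrum. Bin ``(ky, kx)`` carries ``hypot(ky, kx) / 2``
    cycles; a near-constant field returns 0. Used to check that eigenmaps
    get finer (smaller mesh) as the eigenvalue shrinks.
    """
    from scipy.fft import dctn

    F = np.abs(dctn(np.asarray(field, float), type=2, norm="ortho"))
    ky, kx = np.unravel_index(int(np.argmax(F)), F.shape)
    return float(np.hypot(ky, kx) / 2.0)
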