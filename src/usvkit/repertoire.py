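"""Vocal repertoire analysis with diffusion maps.

Each syllable is summarised by its probability distribution over the 11
vocal classes; a repertoire is a cloud of such 11-dimensional points.
Diffusion maps embed the cloud into a low-dimensional Euclidean space: a
Gaussian kernel on pairwise distances is row-normalised into a Markov
matrix, whose spectrum (computed through the symmetric conjugate) yields
diffusion coordinates.  Repertoire structure is then summarised by the
pairwise distances between per-class centroids, and repertoires are
compared by the Pearson correlation of those distance matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

__all__ = [
    "ProbabilityDataset",
    "DiffusionEmbedding",
    "CentroidDistanceMatrix",
    "diffusion_embed",
    "centroid_distances",
    "matrix_correlation",
]

DEFAULT_SIGMA = 0.5   # kernel width, set to typical intra-class distances
DEFAULT_T_STEPS = 2   # diffusion time


@dataclass
class ProbabilityDataset:
    """n x k class-probability rows with a label per row."""

    probs: np.ndarray
    labels: list
    group: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2:
            raise ValueError("probs must be a 2-D array")
        if len(self.labels) != self.probs.shape[0]:
            raise ValueError("one label per row required")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("each probability row must sum to 1")

    @classmethod
    def from_csv(cls, path, group: str = "") -> "ProbabilityDataset":
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise ValueError("probability CSV needs a 'label' column")
        value_cols = [c for c in df.columns if c not in ("label", "group")]
        return cls(probs=df[value_cols].to_numpy(), labels=list(df["label"]),
                   group=group)


@dataclass
class DiffusionEmbedding:
    W: np.ndarray          # Gaussian kernel matrix
    M: np.ndarray          # row-stochastic Markov matrix
    eigvals: np.ndarray    # descending, leading value 1
    psi: np.ndarray        # right eigenvectors of M
    phi: np.ndarray        # left eigenvectors of M
    coords: np.ndarray     # n x 3 diffusion coordinates (columns 2-4)
    sigma: float
    t_steps: int
    labels: list


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each eigenvector positive."""
    out = vectors.copy()
    idx = np.argmax(np.abs(out), axis=0)
    signs = np.sign(out[idx, np.arange(out.shape[1])])
    signs[signs == 0] = 1.0
    return out * signs


def diffusion_embed(
    data: ProbabilityDataset,
    sigma: float = DEFAULT_SIGMA,
    t_steps: int = DEFAULT_T_STEPS,
) -> DiffusionEmbedding:
    """Embed probability rows with diffusion maps.

    Kernel ``W_ij = exp(-||x_i - x_j||^2 / (2 sigma^2))`` on plain Euclidean
    distances; ``M = D^-1 W``; the symmetric conjugate
    ``M_s = D^1/2 M D^-1/2`` is eigendecomposed, giving right/left
    eigenvectors ``Psi = D^-1/2 Omega`` and ``Phi = D^1/2 Omega``.  Diffusion
    time enters as ``Lambda^t`` and the coordinates are columns 2-4 of
    ``Psi Lambda^t`` (the first column is constant and uninformative).
    """
    X = data.probs
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 rows to embed")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    sq = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    W = np.exp(-sq / (2.0 * sigma ** 2))
    d = W.sum(axis=1)
    d_is = 1.0 / np.sqrt(d)
    M = W / d[:, None]
    Ms = d_is[:, None] * W * d_is[None, :]
    Ms = 0.5 * (Ms + Ms.T)  # enforce exact symmetry before eigh
    eigvals, omega = np.linalg.eigh(Ms)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    omega = _fix_signs(omega[:, order])
    psi = d_is[:, None] * omega
    phi = np.sqrt(d)[:, None] * omega
    gamma = psi * eigvals[None, :] ** t_steps
    coords = gamma[:, 1:4]
    return DiffusionEmbedding(W=W, M=M, eigvals=eigvals, psi=psi, phi=phi,
                              coords=coords, sigma=sigma, t_steps=t_steps,
                              labels=list(data.labels))


@dataclass
class CentroidDistanceMatrix:
    """Pairwise Euclidean distances between per-class centroids."""

    dist: np.ndarray
    labels: list

    def __post_init__(self) -> None:
        d = np.asarray(self.dist, dtype=np.float64)
        if not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        self.dist = d


def centroid_distances(emb: DiffusionEmbedding,
                       labels: list | None = None) -> CentroidDistanceMatrix:
    """Mean embedding coordinate per class, then pairwise distances."""
    labels = list(emb.labels if labels is None else labels)
    if len(labels) != emb.coords.shape[0]:
        raise ValueError("one label per embedded row required")
    present = []
    centroids = []
    for lab in dict.fromkeys(labels):  # preserve first-seen order
        rows = [i for i, l in enumerate(labels) if l == lab]
        if not rows:
            warnings.warn(f"label {lab!r} has no rows; excluded")
            continue
        present.append(lab)
        centroids.append(emb.coords[rows].mean(axis=0))
    if len(present) < 2:
        raise ValueError("need at least two labels with rows")
    C = np.asarray(centroids)
    diff = C[:, None, :] - C[None, :, :]
    dist = np.sqrt(np.sum(diff ** 2, axis=-1))
    np.fill_diagonal(dist, 0.0)
    return CentroidDistanceMatrix(dist=dist, labels=present)


def matrix_correlation(a: CentroidDistanceMatrix, b: CentroidDistanceMatrix) -> float:
    """Pearson correlation of the upper triangles of two distance matrices."""
    if a.labels != b.labels:
        raise ValueError("distance matrices cover different label sets")
    ua = squareform(a.dist, checks=False)
    ub = squareform(b.dist, checks=False)
    if np.ptp(ua) == 0 and np.ptp(ub) == 0:
        return 1.0
    return float(pearsonr(ua, ub).statistic)
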