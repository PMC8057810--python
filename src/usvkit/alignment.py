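"""Manifold alignment of two repertoires and agreement statistics.

Two repertoires (feature matrices with shared class labels) are projected
into one joint space by the graph-Laplacian alignment eigenproblem

    Z (L + mu * Ls) Z^T V = lambda * Z Ld Z^T V

where ``L`` preserves each domain's own topology, ``Ls`` pulls same-label
samples of different domains together, ``Ld`` pushes different-label samples
apart, and ``mu`` weights topology preservation against instance matching.
Alignment quality is scored by training a linear discriminant on half of the
projected samples and predicting the other half: overall accuracy, Cohen's
kappa with its asymptotic variance, Z-score, and 95% CI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "DomainGraph",
    "AlignmentModel",
    "AgreementStats",
    "build_graphs",
    "align_domains",
    "agreement_stats",
    "kappa_statistics",
]

log = logging.getLogger(__name__)

DEFAULT_KNN = 10
DEFAULT_SIGMA = 0.5
EIG_FLOOR_REL = 1e-8  # relative floor separating "zero" eigenvalues


@dataclass
class DomainGraph:
    """One domain: d x n features, labels, and its graph Laplacian."""

    X: np.ndarray          # (d, n) feature matrix
    labels: list
    L: np.ndarray          # (n, n) within-domain Laplacian

    @property
    def n(self) -> int:
        return self.X.shape[1]

    @property
    def d(self) -> int:
        return self.X.shape[0]


def _knn_laplacian(X: np.ndarray, knn: int, sigma: float) -> np.ndarray:
    """Gaussian-weighted k-NN graph Laplacian, symmetrised by max."""
    n = X.shape[1]
    k = min(knn, n - 1)
    nbrs = NearestNeighbors(n_neighbors=k + 1).fit(X.T)
    dist, idx = nbrs.kneighbors(X.T)
    W = np.zeros((n, n))
    weights = np.exp(-(dist[:, 1:] ** 2) / (2.0 * sigma ** 2))
    rows = np.repeat(np.arange(n), k)
    W[rows, idx[:, 1:].ravel()] = weights.ravel()
    W = np.maximum(W, W.T)
    return np.diag(W.sum(axis=1)) - W


def _cross_laplacian(labels_a: list, labels_b: list, same: bool) -> np.ndarray:
    """Laplacian of the bipartite cross-domain graph linking samples with
    the same (``same=True``) or different labels, with unit weights."""
    na, nb = len(labels_a), len(labels_b)
    A = np.asarray(labels_a).reshape(-1, 1)
    B = np.asarray(labels_b).reshape(1, -1)
    match = (A == B) if same else (A != B)
    W = np.zeros((na + nb, na + nb))
    W[:na, na:] = match
    W[na:, :na] = match.T
    return np.diag(W.sum(axis=1)) - W


def build_graphs(
    domains: list[tuple[np.ndarray, list]],
    knn: int = DEFAULT_KNN,
    sigma: float = DEFAULT_SIGMA,
) -> tuple[list[DomainGraph], np.ndarray, np.ndarray]:
    """Build within-domain graphs plus the cross-domain Ls/Ld Laplacians.

    ``domains`` holds (features, labels) pairs with features as (d, n)
    matrices (rows are dimensions, columns samples).  Returns the per-domain
    graphs and the joint similarity/dissimilarity Laplacians.  A label
    present in only one domain contributes no Ls links (warned).
    """
    if len(domains) != 2:
        raise ValueError("alignment is pairwise: exactly two domains")
    graphs = []
    for X, labels in domains:
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != len(labels):
            raise ValueError("features and labels disagree on sample count")
        graphs.append(DomainGraph(X=X, labels=list(labels),
                                  L=_knn_laplacian(X, knn, sigma)))
    la, lb = graphs[0].labels, graphs[1].labels
    only = set(la) ^ set(lb)
    if only:
        log.warning("labels present in a single domain (no Ls links): %s",
                    sorted(only))
    Ls = _cross_laplacian(la, lb, same=True)
    Ld = _cross_laplacian(la, lb, same=False)
    return graphs, Ls, Ld


@dataclass
class AlignmentModel:
    """Solved alignment: eigenvector map and per-domain projections."""

    Z: np.ndarray
    Ls: np.ndarray
    Ld: np.ndarray
    mu: float
    V: np.ndarray                    # (Nf, Nf) eigenvector columns
    eigvals: np.ndarray
    projections: list[np.ndarray]    # per-domain (Nf, n_i) joint coordinates
    labels: list                     # concatenated domain labels
    domain: np.ndarray               # 0/1 per projected sample


def align_domains(
    graphs: list[DomainGraph],
    Ls: np.ndarray,
    Ld: np.ndarray,
    mu: float = 1.0,
    n_features: int | None = None,
) -> AlignmentModel:
    """Solve the alignment eigenproblem and project both domains.

    Eigenvectors of the smallest nonzero eigenvalues of
    ``Z (L + mu Ls) Z^T V = lambda Z Ld Z^T V`` form the map; domain ``i``
    with features ``X_i`` projects as ``v_i^T X_i`` where ``v_i`` is the
    block of V for that domain's dimensions.  ``Nf`` (sum of domain
    dimensions) features are retained by default.  A singular right-hand
    side is ridge-regularised by ``1e-9 * trace``.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    ga, gb = graphs
    L = sla.block_diag(ga.L, gb.L)
    Z = sla.block_diag(ga.X, gb.X)  # (d1+d2, n1+n2)
    A = Z @ (L + mu * Ls) @ Z.T
    B = Z @ Ld @ Z.T
    A = 0.5 * (A + A.T)
    B = 0.5 * (B + B.T)
    nf = A.shape[0] if n_features is None else min(n_features, A.shape[0])

    try:
        eigvals, vecs = sla.eigh(A, B)
    except (np.linalg.LinAlgError, sla.LinAlgError):
        eps = 1e-9 * max(np.trace(B), 1.0)
        log.info("singular RHS in alignment eigenproblem; adding %g * I", eps)
        B = B + eps * np.eye(B.shape[0])
        eigvals, vecs = sla.eigh(A, B)

    floor = EIG_FLOOR_REL * max(np.abs(eigvals).max(), 1.0)
    nonzero = np.flatnonzero(np.abs(eigvals) > floor)
    keep = nonzero[np.argsort(eigvals[nonzero])][:nf]
    V = vecs[:, keep]
    kept_vals = eigvals[keep]

    d1 = ga.d
    v1, v2 = V[:d1], V[d1:]
    projections = [v1.T @ ga.X, v2.T @ gb.X]
    return AlignmentModel(
        Z=Z, Ls=Ls, Ld=Ld, mu=mu, V=V, eigvals=kept_vals,
        projections=projections,
        labels=list(ga.labels) + list(gb.labels),
        domain=np.r_[np.zeros(ga.n, int), np.ones(gb.n, int)],
    )


@dataclass
class AgreementStats:
    """Cohen's kappa with its asymptotic variance and companions."""

    kappa: float
    p0: float
    pe: float
    variance: float
    z: float
    ci95: tuple[float, float]
    oa: float
    theta: tuple[float, float, float, float]
    confusion: np.ndarray


def kappa_statistics(n: np.ndarray) -> AgreementStats:
    """Kappa, asymptotic variance, Z and CI from a raw confusion matrix.

    ``theta1`` equals overall accuracy; variance follows the standard
    large-sample expansion; the CI is ``kappa +/- 1.96 sqrt(variance)``.
    """
    n = np.asarray(n, dtype=np.float64)
    N = n.sum()
    if N <= 0:
        raise ValueError("empty confusion matrix")
    p = n / N
    p0 = float(np.trace(p))
    row = n.sum(axis=1)
    col = n.sum(axis=0)
    pe = float(np.sum(row * col) / N ** 2)
    kappa = (p0 - pe) / (1.0 - pe) if pe < 1.0 else 1.0

    theta1 = float(np.trace(n) / N)
    theta2 = float(np.sum(row * col) / N ** 2)
    theta3 = float(np.sum(np.diag(n) * (row + col)) / N ** 2)
    # theta4 = (1/N^3) sum_ij n_ij (n_j. + n_.i)^2
    outer = row[None, :] + col[:, None]     # element (i, j): n_j. + n_.i
    theta4 = float(np.sum(n * outer ** 2) / N ** 3)

    denom = (1.0 - theta2)
    if denom <= 0:
        variance = 0.0
    else:
        variance = (theta1 * (1 - theta1) / denom ** 2
                    + 2 * (1 - theta1) * (2 * theta1 * theta2 - theta3) / denom ** 3
                    + (1 - theta1) ** 2 * (theta4 - 4 * theta2 ** 2) / denom ** 4) / N
    variance = max(variance, 0.0)
    z = kappa / np.sqrt(variance) if variance > 0 else np.inf
    half = 1.96 * np.sqrt(variance)
    return AgreementStats(
        kappa=float(kappa), p0=p0, pe=pe, variance=float(variance), z=float(z),
        ci95=(float(kappa - half), float(kappa + half)), oa=theta1,
        theta=(theta1, theta2, theta3, theta4), confusion=n,
    )


def agreement_stats(model: AlignmentModel, seed: int = 0,
                    n_components: int | None = None,
                    split: str = "domain") -> AgreementStats:
    """Score an alignment by half-split linear discriminant prediction.

    With ``split="domain"`` (default) the discriminant is trained on the
    first domain's projected samples — half of the pooled samples when the
    domains are balanced — and predicts the second domain's labels, so the
    statistic measures cross-domain transfer: a misaligned joint space
    scores at chance level even when each domain is internally separable.
    ``split="half"`` instead uses a seeded, label-stratified random half of
    the pooled samples.

    ``n_components`` selects the leading joint-space coordinates (smallest
    alignment eigenvalues).  The default keeps half of the extracted
    features: trailing eigenvectors carry single-domain structure that does
    not transfer and would let the discriminant overfit it.  A singular
    within-class scatter falls back to a shrinkage discriminant.
    """
    X = np.hstack(model.projections).T
    if n_components is None:
        n_components = int(np.ceil(X.shape[1] / 2))
    X = X[:, :n_components]
    y = np.asarray(model.labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two labels")
    if counts.min() < 4:
        raise ValueError("need at least 4 samples per label")

    if split == "domain":
        train = model.domain == 0
    elif split == "half":
        rng = np.random.default_rng(seed)
        train_idx = []
        for cls in classes:
            members = rng.permutation(np.flatnonzero(y == cls))
            train_idx.extend(members[: members.size // 2])
        train = np.zeros(y.size, dtype=bool)
        train[train_idx] = True
    else:
        raise ValueError("split must be 'domain' or 'half'")
    if len(set(y[train])) < classes.size:
        raise ValueError("training split does not cover every label")

    try:
        lda = LinearDiscriminantAnalysis()
        lda.fit(X[train], y[train])
        pred = lda.predict(X[~train])
    except np.linalg.LinAlgError:
        log.info("singular scatter; using shrinkage discriminant")
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        lda.fit(X[train], y[train])
        pred = lda.predict(X[~train])
    n = confusion_matrix(y[~train], pred, labels=classes)
    return kappa_statistics(n)
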