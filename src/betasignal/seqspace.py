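"""Peptide sequence spaces: PCA reduction, Gaussian fits, Hellinger distances.

An organism's "peptide sequence space" is the multivariate Gaussian fitted to
the PCA-reduced physicochemical vectors of its C-terminal insertion-signal
decamers.  The overlap between two such spaces is measured by the Hellinger
distance between the fitted Gaussians,

    D_H^2(Org1, Org2) = 1 - BC(Org1, Org2),

where the Bhattacharyya coefficient (overlap) of two Gaussians
N(mu1, S1), N(mu2, S2) in d dimensions is

    BC = 2^(d/2) (det S1 det S2)^(1/4) / det(S1 + S2)^(1/2)
         * exp(-1/4 (mu1-mu2)^T (S1+S2)^(-1) (mu1-mu2)).

D_H is symmetric and bounded in [0, 1]: 0 for identical distributions, 1 for
non-overlapping ones.  All determinant work is done in log space and the
quadratic form via a Cholesky solve, so d = 12 poses no conditioning or
overflow problems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

DEFAULT_N_COMPONENTS = 12
DEFAULT_REGULARIZATION = 1e-6


@dataclass(frozen=True)
class PcaModel:
    """Centered principal-component reduction of the 50-dim encoding.

    ``components`` has orthonormal rows; the sign convention is that the
    largest-magnitude loading of every component is positive, which makes the
    fit deterministic.
    """

    mean: np.ndarray
    components: np.ndarray
    explained_variance_fraction: np.ndarray

    @property
    def k(self) -> int:
        return self.components.shape[0]

    @property
    def cumulative_explained(self) -> float:
        return float(self.explained_variance_fraction.sum())

    def project(self, matrix: np.ndarray) -> np.ndarray:
        """Project rows onto the principal components (mean-centered)."""
        X = np.asarray(matrix, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.mean.shape[0]:
            raise ValueError(
                f"expected {self.mean.shape[0]} columns, got {X.shape[1]}"
            )
        return (X - self.mean) @ self.components.T


def fit_pca(matrix, k: int = DEFAULT_N_COMPONENTS) -> PcaModel:
    """Fit a centered (not rescaled) PCA and keep the top-k components."""
    X = _as_array(matrix)
    if X.shape[0] <= k:
        raise ValueError(f"need more than k={k} rows, got {X.shape[0]}")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if k > rank:
        raise ValueError(f"k={k} exceeds rank {rank} of the centered matrix")
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(X)
    components = pca.components_.copy()
    for row in components:  # deterministic sign convention
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return PcaModel(
        mean=pca.mean_.copy(),
        components=components,
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
    )


def project(model: PcaModel, matrix) -> np.ndarray:
    """Functional alias for :meth:`PcaModel.project`."""
    return model.project(_as_array(matrix))


def _as_array(matrix) -> np.ndarray:
    if hasattr(matrix, "data") and isinstance(getattr(matrix, "data"), np.ndarray):
        return matrix.data
    return np.asarray(matrix, dtype=float)


@dataclass(frozen=True)
class SequenceSpace:
    """A fitted multivariate Gaussian for one organism or entity."""

    entity_id: str
    n_peptides: int
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        d = self.mu.shape[0]
        if self.sigma.shape != (d, d):
            raise ValueError("sigma shape does not match mu")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")

    @property
    def d(self) -> int:
        return self.mu.shape[0]


def fit_gaussian(
    entity_id: str,
    reduced_rows,
    regularization: float = DEFAULT_REGULARIZATION,
    shrinkage: float = 0.0,
    shrinkage_target: np.ndarray | None = None,
) -> SequenceSpace:
    """Fit mean and (unbiased) covariance in the reduced space.

    A ridge ``regularization * (trace/d)`` is added to the covariance
    diagonal; entities near the minimum peptide count can otherwise yield
    ill-conditioned or singular covariances in 12 dimensions.

    With ``shrinkage`` lambda in (0, 1] the covariance is the convex
    combination ``(1-lambda) * S_entity + lambda * target`` where the target
    is typically the pooled within-entity covariance.  Small entities (a few
    dozen peptides in 12+ dimensions) have noise-dominated sample
    covariances; shrinking toward the pooled estimate trades a little
    entity-specific structure for a large variance reduction.
    """
    X = np.asarray(reduced_rows, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an n x d matrix with n >= 2")
    if regularization < 0:
        raise ValueError("regularization must be >= 0")
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must be in [0, 1]")
    if shrinkage > 0 and shrinkage_target is None:
        raise ValueError("shrinkage requires a shrinkage_target covariance")
    d = X.shape[1]
    mu = X.mean(axis=0)
    sigma = np.cov(X, rowvar=False, ddof=1).reshape(d, d)
    if shrinkage > 0:
        sigma = (1.0 - shrinkage) * sigma + shrinkage * np.asarray(shrinkage_target)
    scale = np.trace(sigma) / d
    if scale > 0:
        sigma = sigma + regularization * scale * np.eye(d)
    sigma = (sigma + sigma.T) / 2.0
    try:
        linalg.cholesky(sigma, lower=True)
    except linalg.LinAlgError:
        raise ValueError(f"singular covariance for entity {entity_id!r}") from None
    return SequenceSpace(entity_id=entity_id, n_peptides=X.shape[0], mu=mu, sigma=sigma)


# ---------------------------------------------------------------------------
# Hellinger distance


def _log_bhattacharyya(mu1, sigma1, mu2, sigma2, mahal_correction: float = 0.0) -> float:
    d = mu1.shape[0]
    s = sigma1 + sigma2
    chol = linalg.cholesky(s, lower=True)
    logdet_s = 2.0 * np.sum(np.log(np.diag(chol)))
    logdet_1 = _logdet_pd(sigma1)
    logdet_2 = _logdet_pd(sigma2)
    diff = mu2 - mu1
    y = linalg.solve_triangular(chol, diff, lower=True)
    mahal = max(float(y @ y) - mahal_correction, 0.0)
    return (
        0.5 * d * np.log(2.0)
        + 0.25 * (logdet_1 + logdet_2)
        - 0.5 * logdet_s
        - 0.25 * mahal
    )


def _logdet_pd(sigma: np.ndarray) -> float:
    try:
        chol = linalg.cholesky(sigma, lower=True)
    except linalg.LinAlgError:
        raise ValueError("covariance matrix is not positive-definite") from None
    return 2.0 * float(np.sum(np.log(np.diag(chol))))


def bhattacharyya_coefficient(a: SequenceSpace, b: SequenceSpace, debias: bool = False) -> float:
    """Gaussian overlap BC in [0, 1]; BC = 1 - D_H^2.

    With ``debias`` the squared Mahalanobis term is reduced by its expected
    finite-sample inflation ``d * (1/n_a + 1/n_b) / 2`` (the expectation of
    the quadratic form when both entities share the same distribution and
    their means are estimated from n_a and n_b peptides), floored at zero.
    Without it, small entities appear spuriously distant from everything.
    """
    if a.d != b.d:
        raise ValueError(f"dimension mismatch: {a.d} vs {b.d}")
    correction = 0.0
    if debias:
        correction = a.d * (1.0 / a.n_peptides + 1.0 / b.n_peptides) / 2.0
    return float(np.exp(_log_bhattacharyya(a.mu, a.sigma, b.mu, b.sigma, correction)))


def hellinger(a: SequenceSpace, b: SequenceSpace, squared: bool = False,
              debias: bool = False) -> float:
    """Hellinger distance D_H (or D_H^2) between two fitted Gaussians.

    Squared distances below 1e-12 are snapped to exactly zero: the log-
    determinant arithmetic carries ~1e-16 roundoff, which the square root
    would otherwise amplify into a spurious ~1e-8 distance between
    identical distributions.
    """
    bc = bhattacharyya_coefficient(a, b, debias=debias)
    h2 = min(max(1.0 - bc, 0.0), 1.0)
    if h2 < 1e-12:
        h2 = 0.0
    return h2 if squared else float(np.sqrt(h2))


def hellinger_1d(mu1: float, sigma1: float, mu2: float, sigma2: float) -> float:
    """Hellinger distance between two univariate Gaussians.

    ``sigma1``/``sigma2`` are standard deviations.  Agrees with
    :func:`hellinger` on 1x1 covariance matrices.
    """
    if sigma1 <= 0 or sigma2 <= 0:
        raise ValueError("standard deviations must be positive")
    v1, v2 = sigma1**2, sigma2**2
    bc = np.sqrt(2.0 * sigma1 * sigma2 / (v1 + v2)) * np.exp(
        -0.25 * (mu1 - mu2) ** 2 / (v1 + v2)
    )
    return float(np.sqrt(min(max(1.0 - bc, 0.0), 1.0)))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise Hellinger distances with entity labels."""

    entity_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.entity_ids)
        v = self.values
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match entity count")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("Hellinger distances must lie in [0, 1]")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.entity_ids, columns=self.entity_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(entity_ids=tuple(map(str, df.index)), values=df.to_numpy(dtype=float))


def pairwise_distances(spaces: Sequence[SequenceSpace], debias: bool = False) -> DistanceMatrix:
    """All-vs-all Hellinger distances between fitted sequence spaces."""
    spaces = list(spaces)
    if len(spaces) < 2:
        raise ValueError("need at least two sequence spaces")
    d0 = spaces[0].d
    if any(s.d != d0 for s in spaces):
        raise ValueError("all sequence spaces must share the same dimension")
    n = len(spaces)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = hellinger(spaces[i], spaces[j], debias=debias)
    return DistanceMatrix(entity_ids=tuple(s.entity_id for s in spaces), values=out)


def distances_to_weights(dm: DistanceMatrix, contrast: bool = False) -> pd.DataFrame:
    """Convert distances to attraction weights w = 1 - D_H^2 (the overlap).

    The weight is exactly the Bhattacharyya coefficient: monotone decreasing
    in D_H, 1 for identical spaces, 0 for disjoint ones.  The diagonal is
    zeroed (a node does not attract itself).

    With ``contrast`` the off-diagonal weights are additionally min-max
    rescaled to span [0, 1].  Highly conserved signals give near-uniform
    overlaps, under which every force-directed map collapses into one blob;
    the monotone rescaling plays the role of the significance transform that
    graph-layout tools apply to raw similarities before clustering.
    """
    w = 1.0 - dm.values**2
    np.fill_diagonal(w, 0.0)
    if contrast:
        n = w.shape[0]
        off = w[~np.eye(n, dtype=bool)]
        span = off.max() - off.min()
        if span > 0:
            w = np.clip((w - off.min()) / span, 0.0, 1.0)
        np.fill_diagonal(w, 0.0)
    return pd.DataFrame(w, index=dm.entity_ids, columns=dm.entity_ids)


def choose_n_components(matrix, evr_target: float = 0.69, max_k: int = 20) -> int:
    """Smallest k whose cumulative explained variance reaches ``evr_target``.

    Operationalizes "the lowest number of dimensions that still contains
    most of the variation": the default target is the variance fraction
    retained by the 12-component reduction of the full-scale peptide set
    (69%), capped so the dimension stays below the minimum entity size.
    """
    X = _as_array(matrix)
    cap = min(max_k, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=cap, svd_solver="full")
    pca.fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    return int(min(np.searchsorted(cum, evr_target) + 1, cap))


def fit_spaces(
    entities: dict[str, np.ndarray], regularization: float = DEFAULT_REGULARIZATION
) -> list[SequenceSpace]:
    """Fit one sequence space per entity from reduced coordinate blocks."""
    return [fit_gaussian(eid, rows, regularization) for eid, rows in entities.items()]
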