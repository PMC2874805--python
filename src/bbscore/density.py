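"""Density estimation for relative-coordinate distributions.

Distance-only (1D) distributions are fit by Gaussian kernel density
estimation evaluated on a regular grid and interpolated linearly.  The 3D
(r, theta, phi) and 6D (r, theta, phi, alpha, beta, gamma) distributions are
fit by full-covariance Gaussian mixture models; the number of components is
chosen by minimising the Bayes Information Criterion over a geometric
candidate schedule (hard cap 100 components), so model complexity adapts to
the amount of training data.

Periodic angles (phi, alpha, gamma, each with range (-pi, pi]) are handled
by replicating training points that fall within a guard band of width pi/2
of a boundary, shifted by +/- 2 pi, before fitting; densities are always
evaluated at the canonical representative.  This removes boundary leakage at
the cost of a bounded normalisation factor that is identical for the native
and background fits and therefore cancels in every log-odds score.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import KernelDensity

__all__ = [
    "Density1D",
    "GMMDensity",
    "InsufficientDataError",
    "silverman_bandwidth",
    "fit_kde_1d",
    "fit_gmm",
    "gmm_logpdf",
    "bic",
    "gmm_n_params",
    "augment_periodic",
    "DEFAULT_COMPONENT_SCHEDULE",
    "density_to_dict",
    "density_from_dict",
    "save_density",
    "load_density",
]

#: Floor applied to any density before taking a log, so scores stay finite.
DENSITY_FLOOR = 1e-12

#: Candidate component counts examined during BIC selection (the best one is
#: then refined by +/- 1).  BIC curves are smooth enough that this geometric
#: schedule finds the minimum without fitting every K up to the cap of 100.
DEFAULT_COMPONENT_SCHEDULE = (1, 2, 3, 4, 5, 7, 10, 14, 20, 28, 40, 56, 80, 100)

#: Indices of the periodic coordinates within the 3D and 6D vectors.
PERIODIC_DIMS = {1: (), 3: (2,), 6: (2, 3, 5)}

#: Width of the replication guard band beyond each periodic boundary.
GUARD_BAND = math.pi / 2.0


class InsufficientDataError(ValueError):
    """Raised when too few samples are available for a density fit."""


@dataclass
class Density1D:
    """A 1D density tabulated on a regular grid, evaluated by interpolation."""

    grid: np.ndarray
    values: np.ndarray
    bandwidth_lambda: float
    n_samples: int

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("density values must be non-negative")

    @property
    def dim(self) -> int:
        return 1

    def pdf(self, x) -> np.ndarray:
        """Linear interpolation on the grid; the floor value outside it."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.interp(x, self.grid, self.values, left=DENSITY_FLOOR, right=DENSITY_FLOOR)
        return np.maximum(out, DENSITY_FLOOR)

    def logpdf(self, x) -> np.ndarray:
        return np.log(self.pdf(x))

    def integral(self) -> float:
        return float(np.trapezoid(self.values, self.grid))


@dataclass
class GMMDensity:
    """A fitted Gaussian mixture: weights, means and full covariances."""

    dim: int
    weights: np.ndarray
    means: np.ndarray  # (K, dim)
    covariances: np.ndarray  # (K, dim, dim)
    bic_value: float = math.nan
    n_samples: int = 0

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.dim not in (3, 6):
            raise ValueError("GMM densities are used for dim 3 or 6")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if self.n_components > 100:
            raise ValueError("component count exceeds the cap of 100")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def logpdf(self, x) -> np.ndarray:
        return gmm_logpdf(self, x)

    def pdf(self, x) -> np.ndarray:
        return np.exp(self.logpdf(x))


def silverman_bandwidth(samples: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth for a Gaussian KDE."""
    samples = np.asarray(samples, dtype=float)
    n = len(samples)
    std = samples.std(ddof=1)
    iqr = np.subtract(*np.percentile(samples, [75, 25]))
    spread = min(std, iqr / 1.34) if iqr > 0 else std
    if spread <= 0:
        spread = max(abs(samples.mean()), 1.0) * 1e-3
    return 0.9 * spread * n ** (-0.2)


def fit_kde_1d(
    samples,
    bandwidth: float | None = None,
    grid_min: float = 0.0,
    grid_max: float | None = None,
    n_grid: int = 512,
) -> Density1D:
    """Gaussian KDE of a 1D sample, tabulated on a regular grid.

    The default bandwidth is Silverman's rule of thumb; a Sheather-Jones (or
    any other) value may be passed instead.  The grid spans
    [grid_min, max(samples) + 4 bandwidth] with at least 512 points.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if len(samples) < 2:
        raise InsufficientDataError("KDE needs at least 2 samples")
    if bandwidth is None:
        bandwidth = silverman_bandwidth(samples)
        if len(np.unique(samples)) < 2:
            bandwidth = 0.5  # all samples identical: any positive width works
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if grid_max is None:
        grid_max = samples.max() + 4.0 * bandwidth
    grid = np.linspace(grid_min, grid_max, max(n_grid, 512))
    kde = KernelDensity(kernel="gaussian", bandwidth=bandwidth)
    kde.fit(samples[:, None])
    values = np.exp(kde.score_samples(grid[:, None]))
    return Density1D(
        grid=grid, values=values, bandwidth_lambda=float(bandwidth), n_samples=len(samples)
    )


def gmm_n_params(n_components: int, dim: int) -> int:
    """Free-parameter count of a full-covariance GMM (means + covariances +
    mixture proportions, which lose one degree of freedom to normalisation)."""
    return n_components * (dim + dim * (dim + 1) // 2) + (n_components - 1)


def bic(loglik: float, n_params: int, n_samples: int) -> float:
    """Bayes Information Criterion: -2 log L + n_params ln(n_samples)."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    return -2.0 * loglik + n_params * math.log(n_samples)


def augment_periodic(
    X: np.ndarray,
    periodic_dims,
    period: float = 2.0 * math.pi,
    guard: float = GUARD_BAND,
) -> np.ndarray:
    """Replicate points near periodic boundaries, shifted by one period.

    For each periodic coordinate (canonical range (-period/2, period/2]),
    points within ``guard`` of a boundary are duplicated with the coordinate
    shifted by +/- period.  Applied dimension by dimension, so corner points
    near several boundaries generate all shift combinations.
    """
    X = np.asarray(X, dtype=float)
    half = period / 2.0
    for d in periodic_dims:
        low = X[X[:, d] < -half + guard].copy()
        low[:, d] += period
        high = X[X[:, d] > half - guard].copy()
        high[:, d] -= period
        X = np.vstack([X, low, high])
    return X


def _candidate_components(max_components: int, n_samples: int, dim: int) -> list[int]:
    cap = min(max_components, 100, max(1, n_samples // (10 * dim)))
    return [k for k in DEFAULT_COMPONENT_SCHEDULE if k <= cap] or [1]


def fit_gmm(
    samples,
    max_components: int = 100,
    seed: int = 0,
    reg_covar: float = 1e-6,
    n_init: int = 1,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> GMMDensity:
    """Fit a full-covariance GMM, selecting the component count by BIC.

    EM runs from a seeded k-means++ initialisation (``n_init`` restarts per
    candidate); the candidate minimising the BIC is refined by also fitting
    K - 1 and K + 1.  Deterministic given (samples, seed).
    """
    X = np.asarray(samples, dtype=float)
    if X.ndim != 2:
        raise ValueError("samples must be a 2D array (n_samples, dim)")
    n, dim = X.shape
    if n < 10 * dim:
        raise InsufficientDataError(
            f"GMM fit needs at least {10 * dim} samples in dim {dim}, got {n}"
        )

    def _fit(k: int) -> tuple[float, GaussianMixture]:
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            reg_covar=reg_covar,
            n_init=n_init,
            init_params="k-means++",
            random_state=seed,
            max_iter=max_iter,
            tol=tol,
        )
        gm.fit(X)
        loglik = float(gm.score(X)) * n
        return bic(loglik, gmm_n_params(k, dim), n), gm

    results: dict[int, tuple[float, GaussianMixture]] = {}
    for k in _candidate_components(max_components, n, dim):
        results[k] = _fit(k)
    best_k = min(results, key=lambda k: results[k][0])
    for k in (best_k - 1, best_k + 1):
        if 1 <= k <= min(max_components, 100) and k not in results:
            results[k] = _fit(k)
    best_k = min(results, key=lambda k: results[k][0])
    best_bic, best_gm = results[best_k]
    return GMMDensity(
        dim=dim,
        weights=best_gm.weights_,
        means=best_gm.means_,
        covariances=best_gm.covariances_,
        bic_value=best_bic,
        n_samples=n,
    )


def gmm_logpdf(m: GMMDensity, x) -> np.ndarray:
    """log sum_k w_k N(x; mu_k, Sigma_k), computed via per-component Cholesky
    factors and a log-sum-exp reduction for numerical stability."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != m.dim:
        raise ValueError(f"expected points of dimension {m.dim}, got {x.shape[1]}")
    comp = np.empty((len(x), m.n_components))
    for k in range(m.n_components):
        chol = np.linalg.cholesky(m.covariances[k])
        diff = x - m.means[k]
        z = solve_triangular(chol, diff.T, lower=True).T
        maha = np.einsum("ij,ij->i", z, z)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        comp[:, k] = (
            math.log(m.weights[k])
            - 0.5 * (m.dim * math.log(2.0 * math.pi) + logdet + maha)
        )
    return logsumexp(comp, axis=1)


# ---------------------------------------------------------------------------
# Serialization: a plain JSON-compatible schema, row-major matrices.

SCHEMA_VERSION = "bbscore-density-1"


def density_to_dict(d) -> dict:
    if isinstance(d, Density1D):
        return {
            "schema": SCHEMA_VERSION,
            "kind": "kde1d",
            "grid": d.grid.tolist(),
            "values": d.values.tolist(),
            "bandwidth_lambda": d.bandwidth_lambda,
            "n_samples": d.n_samples,
        }
    if isinstance(d, GMMDensity):
        return {
            "schema": SCHEMA_VERSION,
            "kind": "gmm",
            "dim": d.dim,
            "weights": d.weights.tolist(),
            "means": d.means.tolist(),
            "covariances": d.covariances.tolist(),
            "bic_value": d.bic_value,
            "n_samples": d.n_samples,
        }
    raise TypeError(f"not a density object: {type(d)!r}")


def density_from_dict(payload: dict):
    if payload.get("schema") != SCHEMA_VERSION:
        raise ValueError(f"unknown density schema {payload.get('schema')!r}")
    if payload["kind"] == "kde1d":
        return Density1D(
            grid=np.array(payload["grid"]),
            values=np.array(payload["values"]),
            bandwidth_lambda=payload["bandwidth_lambda"],
            n_samples=payload["n_samples"],
        )
    if payload["kind"] == "gmm":
        return GMMDensity(
            dim=payload["dim"],
            weights=np.array(payload["weights"]),
            means=np.array(payload["means"]),
            covariances=np.array(payload["covariances"]),
            bic_value=payload["bic_value"],
            n_samples=payload["n_samples"],
        )
    raise ValueError(f"unknown density kind {payload['kind']!r}")


def save_density(d, path: str | Path) -> None:
    Path(path).write_text(json.dumps(density_to_dict(d)))


def load_density(path: str | Path):
    return density_from_dict(json.loads(Path(path).read_text()))
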