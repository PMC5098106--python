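"""Seeded generators for the synthetic benchmarks.

Two families of data are produced:

* **Regression scenarios** — rows of the design are i.i.d. draws from
  N(0, Sigma) with AR(1) covariance Sigma_ij = r^|i-j| (r in {0, 0.3, 0.6,
  0.8}), and the response follows the sparse linear model
  y = 2 x1 - 3 x2 + 4 x5 + eps with eps ~ N(0, sigma^2), sigma = 1 by
  default.  Only three of the m coefficients are nonzero, which is the
  regime subset-selection methods are meant for.

* **Network scenarios** — Gaussian samples whose conditional-independence
  graph is a band structure.  Band 1: Sigma_ij = 0.6^|i-j| (AR(1)), whose
  precision matrix is tridiagonal, so true edges sit at |i-j| = 1.  Band 2:
  a precision matrix with unit diagonal and off-diagonals 0.25 at lag 1 and
  0.4 at lag 2 (true edges at |i-j| <= 2); positive definiteness is checked
  at construction.

All generators are pure functions of (scenario parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, toeplitz

__all__ = [
    "SimScenario",
    "NetworkScenario",
    "default_theta_true",
    "gen_ar1_design",
    "gen_response",
    "gen_regression",
    "gen_band_network",
]


def default_theta_true(m: int) -> np.ndarray:
    """Sparse truth with 2, -3, 4 at (0-based) positions 0, 1, 4."""
    if m < 5:
        raise ValueError("default truth needs m >= 5")
    theta = np.zeros(m)
    theta[0], theta[1], theta[4] = 2.0, -3.0, 4.0
    return theta


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one sparse-regression simulation."""

    n: int
    m: int
    r: float = 0.0
    theta_true: np.ndarray | None = None
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r < 1.0:
            raise ValueError("r must lie in [0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        theta = (default_theta_true(self.m) if self.theta_true is None
                 else np.asarray(self.theta_true, dtype=float).ravel())
        if theta.shape[0] != self.m:
            raise ValueError("theta_true length must equal m")
        object.__setattr__(self, "theta_true", theta)

    @property
    def true_support(self) -> np.ndarray:
        return np.flatnonzero(self.theta_true)


@dataclass(frozen=True)
class NetworkScenario:
    """Parameters of one band-network simulation."""

    n: int
    band: int
    m: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.band not in (1, 2):
            raise ValueError("band must be 1 or 2")
        if self.m < 3:
            raise ValueError("m must be >= 3")


# Cholesky factors depend only on (m, r) / (m, band); cache across replicates.
_CHOL_CACHE: dict[tuple, np.ndarray] = {}


def _ar1_chol(m: int, r: float) -> np.ndarray:
    key = ("ar1", m, round(float(r), 12))
    if key not in _CHOL_CACHE:
        sigma = toeplitz(r ** np.arange(m))
        _CHOL_CACHE[key] = cholesky(sigma, lower=True)
    return _CHOL_CACHE[key]


def _band2_chol(m: int) -> np.ndarray:
    """Lower Cholesky factor of Sigma = Omega^-1 for the band-2 precision."""
    key = ("band2", m)
    if key not in _CHOL_CACHE:
        lags = np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
        omega = np.where(lags == 0, 1.0, 0.0)
        omega += np.where(lags == 1, 0.25, 0.0)
        omega += np.where(lags == 2, 0.4, 0.0)
        min_eig = float(np.linalg.eigvalsh(omega)[0])
        if min_eig <= 0:
            raise ValueError(
                f"band-2 precision matrix is not positive definite "
                f"(min eigenvalue {min_eig:g})"
            )
        sigma = np.linalg.inv(omega)
        _CHOL_CACHE[key] = cholesky(sigma, lower=True)
    return _CHOL_CACHE[key]


def gen_ar1_design(scenario: SimScenario,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """n x m design with i.i.d. N(0, Sigma) rows, Sigma_ij = r^|i-j|."""
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    L = _ar1_chol(scenario.m, scenario.r)
    Z = rng.standard_normal((scenario.n, scenario.m))
    return Z @ L.T


def gen_response(
    X: np.ndarray,
    theta_true: np.ndarray,
    sigma: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """y = X theta_true + eps with eps ~ N(0, sigma^2)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    theta_true = np.asarray(theta_true, dtype=float).ravel()
    if X.shape[1] != theta_true.shape[0]:
        raise ValueError("theta_true length does not match X columns")
    return X @ theta_true + sigma * rng.standard_normal(X.shape[0])


def gen_regression(scenario: SimScenario) -> tuple[np.ndarray, np.ndarray]:
    """Design and response of one seeded replicate (single RNG stream)."""
    rng = np.random.default_rng(scenario.seed)
    X = gen_ar1_design(scenario, rng=rng)
    y = gen_response(X, scenario.theta_true, scenario.sigma, rng=rng)
    return X, y


def band_truth(m: int, band: int) -> np.ndarray:
    """Symmetric 0/1 adjacency with edges at index distance <= band."""
    lags = np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
    truth = ((lags >= 1) & (lags <= band)).astype(int)
    return truth


def gen_band_network(scenario: NetworkScenario,
                     rng: np.random.Generator | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Sampled n x m matrix and the true band adjacency.

    Band 1 draws from the AR(1) covariance 0.6^|i-j|; band 2 draws from the
    inverse of the banded precision matrix described in the module docstring.
    """
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    if scenario.band == 1:
        L = _ar1_chol(scenario.m, 0.6)
    else:
        L = _band2_chol(scenario.m)
    Z = rng.standard_normal((scenario.n, scenario.m))
    X = Z @ L.T
    return X, band_truth(scenario.m, scenario.band)
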