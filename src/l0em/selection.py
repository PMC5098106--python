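"""Choosing the penalty weight lambda.

Three routes are provided:

* **Cross-validation** over a log-spaced grid, scoring each lambda by the
  held-out mean squared error; ``lam_mse`` minimizes the mean test MSE.
* **Stability selection**: ``lam_ss`` is the smallest grid lambda at which
  every fold selects the same number of features (zero SD of support size);
  the combined rule takes ``lam_opt = max(lam_mse, lam_ss)``.
* **Information criteria**, which for an L0 penalty fix lambda directly with
  no resampling at all: lambda = 2 (AIC), log n (BIC), or 2 log m (RIC).

The grid runs from ``lam_min`` up to the null threshold
``lam_max = max_j (x_j'y)^2 / (4 x_j'x_j)``, above which the fitted model is
empty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .solver import RegressionData, SolverSettings, em_fit

__all__ = [
    "LambdaGrid",
    "CVResult",
    "RegularizationPath",
    "lambda_grid",
    "info_criterion_lambda",
    "cross_validate",
    "stability_select",
    "fit_path",
]


@dataclass(frozen=True)
class LambdaGrid:
    """Strictly positive, log-equally-spaced penalties, stored descending."""

    values: np.ndarray
    lam_min: float
    lam_max: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("grid must be a nonempty 1-D array")
        if np.any(v <= 0):
            raise ValueError("grid values must be > 0")
        if np.any(np.diff(v) > 0):
            raise ValueError("grid values must be descending")
        object.__setattr__(self, "values", v)

    @property
    def n_points(self) -> int:
        return int(self.values.size)


def lambda_grid(
    data: RegressionData, n_points: int = 100, lam_min: float = 1e-4
) -> LambdaGrid:
    """Log-spaced grid from ``lam_min`` to the L0 null threshold.

    ``lam_max = max_j (x_j'y)^2 / (4 x_j'x_j)``: for any larger lambda every
    coefficient is driven to zero, so the grid spans the whole informative
    range.
    """
    X, y = data.X, data.y
    col_ss = np.einsum("ij,ij->j", X, X)
    if np.any(col_ss == 0):
        raise ValueError("X contains an all-zero column")
    lam_max = float(np.max((X.T @ y) ** 2 / (4.0 * col_ss)))
    if lam_max <= lam_min:
        raise ValueError(
            f"lam_max = {lam_max:g} <= lam_min = {lam_min:g}; "
            "signal too weak for a meaningful grid"
        )
    values = np.geomspace(lam_min, lam_max, n_points)[::-1].copy()
    return LambdaGrid(values=values, lam_min=lam_min, lam_max=lam_max)


def info_criterion_lambda(criterion: str, n: int, m: int) -> float:
    """Penalty weight fixed by an information criterion (natural log).

    AIC: 2; BIC: log n; RIC: 2 log m.
    """
    if n < 2 or m < 1:
        raise ValueError("need n >= 2 and m >= 1")
    crit = criterion.lower()
    if crit == "aic":
        return 2.0
    if crit == "bic":
        return math.log(n)
    if crit == "ric":
        return 2.0 * math.log(m)
    raise ValueError(f"unknown criterion {criterion!r} (use AIC, BIC or RIC)")


def stability_select(k_counts: np.ndarray, grid: LambdaGrid) -> float:
    """Smallest lambda whose support size is identical across folds.

    ``k_counts`` is a folds x n_lambda matrix of selected-feature counts,
    columns ordered like ``grid.values`` (descending).  If no lambda attains
    zero SD, the lambda with the smallest SD is returned, ties broken toward
    the larger (sparser) lambda.

    Note: on data with no signal and few features the dense end of the grid
    can saturate (every fold selecting everything), which also has zero SD;
    the rule is kept literal because realistic feature counts never
    saturate, but it is why the combined rule degrades slightly on
    pure-noise inputs.
    """
    k_counts = np.asarray(k_counts, dtype=float)
    if k_counts.ndim != 2 or k_counts.shape[1] != grid.n_points:
        raise ValueError("k_counts must be folds x n_lambda")
    sd = k_counts.std(axis=0, ddof=0)
    zero = np.flatnonzero(sd == 0.0)
    if zero.size:
        # descending grid: the last zero-SD column is the smallest lambda
        return float(grid.values[zero[-1]])
    best = float(np.min(sd))
    idx = np.flatnonzero(sd == best)[0]  # first index = largest lambda
    return float(grid.values[idx])


@dataclass(frozen=True)
class CVResult:
    """Per-lambda cross-validation summaries and the selected penalties."""

    grid: LambdaGrid
    mse_mean: np.ndarray
    mse_sd: np.ndarray
    k_mean: np.ndarray
    k_sd: np.ndarray
    lam_mse: float
    lam_ss: float
    lam_opt: float
    fold_assignment: np.ndarray
    k_counts: np.ndarray = field(repr=False)
    mse_folds: np.ndarray = field(repr=False)

    def mse_at(self, lam: float) -> float:
        idx = int(np.argmin(np.abs(self.grid.values - lam)))
        return float(self.mse_mean[idx])


def _kfold_indices(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold label per sample from a seeded uniform random partition."""
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        labels[chunk] = f
    return labels


def cross_validate(
    data: RegressionData,
    grid: LambdaGrid,
    k: int = 5,
    settings: SolverSettings | None = None,
    seed: int | None = None,
    dual: bool | None = None,
) -> CVResult:
    """k-fold CV of the EM fit over a lambda grid.

    For each fold and each lambda, fits on the training part (ridge init at
    that lambda) and records the held-out MSE and the support size.  Selects
    ``lam_mse`` (minimum mean test MSE, ties toward larger lambda),
    ``lam_ss`` (stability selection) and ``lam_opt = max`` of the two.
    """
    if settings is None:
        settings = SolverSettings(lam=1.0)
    if k < 2:
        raise ValueError("need k >= 2 folds")
    n = data.n_samples
    if n < k:
        raise ValueError("need n >= k samples")
    rng = np.random.default_rng(seed)
    folds = _kfold_indices(n, k, rng)
    n_lam = grid.n_points
    mse_folds = np.empty((k, n_lam))
    k_counts = np.empty((k, n_lam), dtype=int)
    X, y = data.X, data.y
    for f in range(k):
        test = folds == f
        train = ~test
        if train.sum() < 2 or test.sum() < 1:
            raise ValueError("fold with too few samples")
        d_train = RegressionData(X[train], y[train])
        use_dual = d_train.n_samples < d_train.n_features if dual is None else dual
        gram = None
        if not use_dual:
            gram = {"XtX": d_train.X.T @ d_train.X, "Xty": d_train.X.T @ d_train.y}
        else:
            gram = {"XXt": d_train.X @ d_train.X.T}
        X_test, y_test = X[test], y[test]
        for i, lam in enumerate(grid.values):
            fit = em_fit(d_train, replace(settings, lam=float(lam)),
                         dual=use_dual, _gram=gram)
            resid = y_test - X_test @ fit.theta
            mse_folds[f, i] = float(resid @ resid) / y_test.size
            k_counts[f, i] = fit.n_selected
    mse_mean = mse_folds.mean(axis=0)
    mse_sd = mse_folds.std(axis=0, ddof=0)
    k_mean = k_counts.mean(axis=0)
    k_sd = k_counts.std(axis=0, ddof=0)
    # descending grid: argmin returns the first (largest-lambda) minimizer
    lam_mse = float(grid.values[int(np.argmin(mse_mean))])
    lam_ss = stability_select(k_counts, grid)
    lam_opt = max(lam_mse, lam_ss)
    return CVResult(
        grid=grid, mse_mean=mse_mean, mse_sd=mse_sd,
        k_mean=k_mean, k_sd=k_sd,
        lam_mse=lam_mse, lam_ss=lam_ss, lam_opt=lam_opt,
        fold_assignment=folds, k_counts=k_counts, mse_folds=mse_folds,
    )


@dataclass(frozen=True)
class RegularizationPath:
    """Coefficients per grid lambda (columns ordered like ``grid.values``)."""

    grid: LambdaGrid
    coefficients: np.ndarray  # m x n_points
    support_size: np.ndarray

    def __post_init__(self) -> None:
        if self.coefficients.shape[1] != self.grid.n_points:
            raise ValueError("coefficient columns must match grid size")


def fit_path(
    data: RegressionData,
    grid: LambdaGrid,
    settings: SolverSettings | None = None,
    dual: bool | None = None,
    warm_start: bool = False,
) -> RegularizationPath:
    """Fit every grid lambda in descending order.

    Each lambda is cold-started from its own ridge solution by default:
    exact zeros are absorbing in the EM, so naive warm starts would freeze
    supports along the path.  The opt-in ``warm_start`` mode keeps the
    previous nonzero coefficients and fills zeroed entries from the ridge
    solution at the current lambda, so coordinates can re-enter the support
    as lambda decreases while converged coordinates skip most iterations.
    """
    if settings is None:
        settings = SolverSettings(lam=1.0)
    m = data.n_features
    use_dual = data.n_samples < m if dual is None else dual
    gram: dict | None
    if use_dual:
        gram = {"XXt": data.X @ data.X.T}
    else:
        gram = {"XtX": data.X.T @ data.X, "Xty": data.X.T @ data.y}
    coefs = np.zeros((m, grid.n_points))
    prev: np.ndarray | None = None
    for i, lam in enumerate(grid.values):
        s = replace(settings, lam=float(lam))
        if warm_start and prev is not None and np.any(prev):
            from .solver import ridge_init
            ridge = ridge_init(data, float(lam), _gram=gram)
            init = np.where(prev == 0.0, ridge, prev)
            s = replace(s, init=init)
        fit = em_fit(data, s, dual=use_dual, _gram=gram)
        coefs[:, i] = fit.theta
        prev = fit.theta
    support_size = np.count_nonzero(coefs, axis=0)
    return RegularizationPath(grid=grid, coefficients=coefs,
                              support_size=support_size)
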