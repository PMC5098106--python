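"""Evaluation quantities for the simulation benchmarks.

Per-replicate measures: held-out (or in-sample) mean squared error, the
Euclidean bias ||theta_hat - theta_true|| over all coordinates, the selected
feature count, and the exact-support indicator.  ``run_experiment``
aggregates them as mean +/- SD over seeded replicates, regenerating fresh
data for every replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .selection import cross_validate, info_criterion_lambda, lambda_grid
from .simulate import SimScenario, gen_regression
from .solver import RegressionData, SolverSettings, em_fit

__all__ = [
    "ReplicateSummary",
    "mse",
    "bias_norm",
    "true_model_indicator",
    "run_experiment",
]


def mse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean squared error sum((y - yhat)^2) / n."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    d = y_true - y_pred
    return float(d @ d) / d.size


def bias_norm(theta_hat: np.ndarray, theta_true: np.ndarray,
              norm: str = "l2") -> float:
    """||theta_hat - theta_true|| over all m coordinates (Euclidean default,
    ``norm='l1'`` for the summed absolute deviation)."""
    d = np.asarray(theta_hat, dtype=float).ravel() - np.asarray(
        theta_true, dtype=float).ravel()
    if norm == "l2":
        return float(np.linalg.norm(d))
    if norm == "l1":
        return float(np.abs(d).sum())
    raise ValueError("norm must be 'l2' or 'l1'")


def true_model_indicator(support, true_support) -> bool:
    """True iff the selected support equals the true support exactly."""
    return set(np.asarray(support).ravel().tolist()) == set(
        np.asarray(true_support).ravel().tolist())


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean +/- SD aggregates over replicates, plus the raw records."""

    n_selected_mean: float
    n_selected_sd: float
    mse_mean: float
    mse_sd: float
    bias_mean: float
    bias_sd: float
    true_model_count: int
    n_replicates: int
    records: tuple[dict, ...] = field(repr=False, default=())

    @property
    def true_model_rate(self) -> float:
        return self.true_model_count / self.n_replicates


def _fit_one_replicate(
    scenario: SimScenario,
    selection: str,
    k: int,
    n_points: int,
    lam_min: float,
    settings: SolverSettings,
    cv_seed: int,
) -> dict:
    """Fit one fresh replicate and return its per-replicate measures.

    ``selection``: 'cv' (lambda by minimal test MSE), 'cv+ss' (combined rule
    lambda = max(lam_mse, lam_ss)), or 'aic'/'bic'/'ric' (fixed lambda, no
    resampling; MSE is then the in-sample MSE* of the single fit).
    """
    X, y = gen_regression(scenario)
    data = RegressionData(X, y)
    n, m = X.shape
    dual = n < m
    if selection in ("cv", "cv+ss"):
        grid = lambda_grid(data, n_points=n_points, lam_min=lam_min)
        cv = cross_validate(data, grid, k=k, settings=settings,
                            seed=cv_seed, dual=dual)
        lam = cv.lam_mse if selection == "cv" else cv.lam_opt
        fit = em_fit(data, replace(settings, lam=lam), dual=dual)
        rep_mse = cv.mse_at(lam)  # held-out test MSE at the chosen lambda
    else:
        lam = info_criterion_lambda(selection, n, m)
        fit = em_fit(data, replace(settings, lam=lam), dual=dual)
        rep_mse = mse(y, X @ fit.theta)  # in-sample MSE*
    return {
        "seed": scenario.seed,
        "lam": lam,
        "n_selected": fit.n_selected,
        "mse": rep_mse,
        "bias": bias_norm(fit.theta, scenario.theta_true),
        "true_model": bool(
            true_model_indicator(fit.support, scenario.true_support)),
        "converged": fit.converged,
    }


def summarize(records) -> ReplicateSummary:
    """Aggregate per-replicate records into a ReplicateSummary."""
    records = tuple(records)
    ns = np.array([r["n_selected"] for r in records], dtype=float)
    ms = np.array([r["mse"] for r in records], dtype=float)
    bs = np.array([r["bias"] for r in records], dtype=float)
    return ReplicateSummary(
        n_selected_mean=float(ns.mean()), n_selected_sd=float(ns.std(ddof=0)),
        mse_mean=float(ms.mean()), mse_sd=float(ms.std(ddof=0)),
        bias_mean=float(bs.mean()), bias_sd=float(bs.std(ddof=0)),
        true_model_count=int(sum(r["true_model"] for r in records)),
        n_replicates=len(records),
        records=records,
    )


def run_experiment(
    scenario: SimScenario,
    selection: str = "cv+ss",
    n_replicates: int = 100,
    seed: int = 0,
    k: int = 5,
    n_points: int = 100,
    lam_min: float = 1e-4,
    settings: SolverSettings | None = None,
) -> ReplicateSummary:
    """Repeat a simulation scenario and aggregate the per-replicate measures.

    Every replicate draws a fresh design and response from ``scenario``
    (its ``seed`` field is replaced by a stream derived from ``seed``).
    """
    if n_replicates < 1:
        raise ValueError("need n_replicates >= 1")
    if settings is None:
        settings = SolverSettings(lam=1.0)
    master = np.random.default_rng(seed)
    rep_seeds = master.integers(0, 2**31 - 1, size=2 * n_replicates)
    records = []
    for i in range(n_replicates):
        rep_scen = replace(scenario, seed=int(rep_seeds[2 * i]))
        records.append(
            _fit_one_replicate(
                rep_scen, selection, k, n_points, lam_min, settings,
                cv_seed=int(rep_seeds[2 * i + 1]),
            )
        )
    return summarize(records)
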