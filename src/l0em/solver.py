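"""EM fixed-point solvers for L0- (and general Lp-) penalized linear regression.

The estimator minimizes the penalized least-squares objective

    E(theta) = 1/2 ||y - X theta||^2 + (lambda/2) ||theta||_0,

where ``||theta||_0`` counts the nonzero coefficients.  Direct minimization is
a combinatorial (NP-hard) best-subset problem; the solvers here approximate it
by a fixed-point iteration that alternates a reweighted ridge solve (M-step)

    theta <- (D X'X + lambda I_m)^{-1} D X' y,      D = diag(eta_j^2)

with the update ``eta <- theta`` (E-step).  Small coefficients shrink
super-linearly across iterations and are clamped to exact zero once below
``zero_eps``; zeros are absorbing, so the active set only ever shrinks.

Two algebraically identical forms are provided: the primal iteration above,
solving an m x m system per step, and a dual iteration

    theta <- D X' (X D X' + lambda I_n)^{-1} y

solving an n x n system, which is the efficient choice when n << m.

The same machinery with ``D = diag(|eta_j|^{2-p})`` covers the whole family of
Lp penalties for p in [0, 2]: p = 0 is the L0 iteration, p = 1 has the lasso
stationary conditions (penalty lambda * ||theta||_1), and p = 2 is plain ridge
(the first iterate is already the fixed point).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "RegressionData",
    "SolverSettings",
    "FitResult",
    "ridge_init",
    "em_fit",
    "l0em_fit",
    "dl0em_fit",
    "lpem_fit",
    "objective",
    "check_contraction",
    "prune",
]


@dataclass(frozen=True)
class RegressionData:
    """A design matrix / response pair for penalized linear regression.

    Parameters
    ----------
    X : array-like, shape (n_samples, n_features)
        Design matrix. Assumed appropriately scaled by the caller; no
        intercept column is added (the model has none).
    y : array-like, shape (n_samples,)
        Response vector.
    feature_names : sequence of str, optional
        Column labels; defaults to ``x1 .. xm`` when written out.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        X = np.ascontiguousarray(np.asarray(self.X, dtype=float))
        y = np.ascontiguousarray(np.asarray(self.y, dtype=float)).ravel()
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        n, m = X.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if m < 1:
            raise ValueError("need at least 1 feature")
        if y.shape[0] != n:
            raise ValueError(f"y has length {y.shape[0]}, X has {n} rows")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite entries")
        if not np.all(np.isfinite(y)):
            raise ValueError("y contains non-finite entries")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if self.feature_names is not None:
            names = tuple(str(s) for s in self.feature_names)
            if len(names) != m:
                raise ValueError("feature_names length does not match X")
            object.__setattr__(self, "feature_names", names)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class SolverSettings:
    """Tuning knobs for the EM fixed-point solvers.

    lam
        Penalty weight lambda >= 0 of the objective.
    p
        Penalty exponent in [0, 2]; 0 gives the L0 iteration.
    tol
        Convergence tolerance on the max-abs coefficient change.
    max_iter
        Iteration cap; the fit is returned (flagged unconverged) on hitting it.
    zero_eps
        Hard-zeroing threshold: coefficients with |theta_j| < zero_eps are set
        to exact zero and stay zero.
    init
        'ridge' (default: ridge solution at the same lambda) or an explicit
        coefficient vector.
    positive_only
        Clamp negative coefficients to zero after every M-step (used for
        positive-dependency network fits).
    """

    lam: float
    p: float = 0.0
    tol: float = 1e-8
    max_iter: int = 500
    zero_eps: float = 1e-6
    init: str | np.ndarray = "ridge"
    positive_only: bool = False

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if not 0.0 <= self.p <= 2.0:
            raise ValueError("p must lie in [0, 2]")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.zero_eps < 0:
            raise ValueError("zero_eps must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class FitResult:
    """Outcome of one EM fit.

    ``theta`` is the full-length coefficient vector (exact zeros off the
    support); ``support`` the sorted indices of nonzero coefficients;
    ``objective`` the value of the penalized objective at ``theta``.
    """

    theta: np.ndarray
    support: np.ndarray
    n_iter: int
    converged: bool
    objective: float
    lam: float
    p: float
    history: tuple[np.ndarray, ...] | None = field(default=None, repr=False)

    @property
    def n_selected(self) -> int:
        return int(self.support.size)


def prune(theta: np.ndarray, zero_eps: float) -> np.ndarray:
    """Return a copy of ``theta`` with entries below ``zero_eps`` set to 0."""
    if zero_eps < 0:
        raise ValueError("zero_eps must be >= 0")
    out = np.array(theta, dtype=float, copy=True)
    out[np.abs(out) < zero_eps] = 0.0
    return out


def objective(data: RegressionData, theta: np.ndarray, lam: float) -> float:
    """Penalized objective 1/2 ||y - X theta||^2 + (lam/2) * #nonzero."""
    theta = np.asarray(theta, dtype=float).ravel()
    if theta.shape[0] != data.n_features:
        raise ValueError("theta length does not match number of features")
    resid = data.y - data.X @ theta
    return 0.5 * float(resid @ resid) + 0.5 * lam * int(np.count_nonzero(theta))


def ridge_init(
    data: RegressionData,
    lam: float,
    *,
    _gram: dict | None = None,
) -> np.ndarray:
    """Ridge solution argmin 1/2||y - X theta||^2 + (lam/2)||theta||^2.

    Solved through the n x n dual system when n < m.  Used as the default
    nonzero initializer of the EM iterations (an all-zero start is a trivial
    fixed point).
    """
    if lam <= 0:
        raise ValueError("ridge_init requires lam > 0")
    X, y = data.X, data.y
    n, m = X.shape
    if n < m:
        if _gram is not None and "XXt" in _gram:
            G = _gram["XXt"] + lam * np.eye(n)
        else:
            G = X @ X.T + lam * np.eye(n)
        alpha = cho_solve(cho_factor(G, lower=True, check_finite=False), y,
                          check_finite=False)
        return X.T @ alpha
    if _gram is not None and "XtX" in _gram:
        A = _gram["XtX"] + lam * np.eye(m)
        b = _gram["Xty"]
    else:
        A = X.T @ X + lam * np.eye(m)
        b = X.T @ y
    return cho_solve(cho_factor(A, lower=True, check_finite=False), b,
                     check_finite=False)


def _m_step_primal(X, y, active, w, lam, gram):
    """theta_active of the reweighted ridge solve, primal (|A| x |A|) form."""
    if gram is not None:
        A = gram["XtX"][np.ix_(active, active)] * np.outer(w, w)
        b = w * gram["Xty"][active]
    else:
        Xw = X[:, active] * w
        A = Xw.T @ Xw
        b = Xw.T @ y
    A[np.diag_indices_from(A)] += lam
    z = cho_solve(cho_factor(A, lower=True, check_finite=False), b,
                  check_finite=False)
    return w * z


def _m_step_dual(X, y, active, w, lam):
    """theta_active via the n x n dual system theta = D X'(X D X' + lam I)^-1 y."""
    Xw = X[:, active] * w
    G = Xw @ Xw.T
    G[np.diag_indices_from(G)] += lam
    alpha = cho_solve(cho_factor(G, lower=True, check_finite=False), y,
                      check_finite=False)
    return w * (Xw.T @ alpha)


def em_fit(
    data: RegressionData,
    settings: SolverSettings,
    *,
    dual: bool | None = None,
    history: bool = False,
    _gram: dict | None = None,
) -> FitResult:
    """Run the Lp EM fixed-point iteration.

    Parameters
    ----------
    dual : bool, optional
        Force the dual (n x n) or primal (m x m) M-step; by default the dual
        form is used when n < m.
    history : bool
        Record the iterate sequence (for convergence diagnostics).
    """
    X, y = data.X, data.y
    n, m = X.shape
    lam, p = settings.lam, settings.p
    if dual is None:
        dual = n < m

    if isinstance(settings.init, str):
        if settings.init != "ridge":
            raise ValueError(f"unknown init policy {settings.init!r}")
        if lam > 0:
            theta = ridge_init(data, lam, _gram=_gram)
        else:
            theta, *_ = np.linalg.lstsq(X, y, rcond=None)
        user_init = False
    else:
        theta = np.asarray(settings.init, dtype=float).ravel().copy()
        if theta.shape[0] != m:
            raise ValueError("init vector length does not match n_features")
        user_init = True

    theta[np.abs(theta) < settings.zero_eps] = 0.0
    if not np.any(theta):
        if user_init:
            raise ValueError(
                "all-zero initialization is a trivial fixed point; "
                "supply a nonzero start"
            )
        # ridge init vanished (e.g. y = 0): the zero fit is the answer
        theta = np.zeros(m)
        return FitResult(
            theta=theta, support=np.flatnonzero(theta), n_iter=0,
            converged=True, objective=objective(data, theta, lam),
            lam=lam, p=p, history=(theta.copy(),) if history else None,
        )

    exponent = (2.0 - p) / 2.0  # D = diag(|eta|^(2-p)) = W^2
    active = np.flatnonzero(theta)
    trace: list[np.ndarray] = [theta.copy()] if history else []
    converged = False
    n_iter = 0
    for it in range(settings.max_iter):
        n_iter = it + 1
        theta_old = theta
        if active.size == 0:
            theta = np.zeros(m)
            converged = True
            if history:
                trace.append(theta.copy())
            break
        w = np.abs(theta[active]) ** exponent
        if lam == 0.0:
            # penalty-free fixed point: plain least squares on the active set
            theta_a, *_ = np.linalg.lstsq(X[:, active], y, rcond=None)
        elif dual:
            theta_a = _m_step_dual(X, y, active, w, lam)
        else:
            theta_a = _m_step_primal(X, y, active, w, lam, _gram)
        if settings.positive_only:
            theta_a = np.maximum(theta_a, 0.0)
        theta_a[np.abs(theta_a) < settings.zero_eps] = 0.0
        theta = np.zeros(m)
        theta[active] = theta_a
        active = active[theta_a != 0.0]
        if history:
            trace.append(theta.copy())
        if np.max(np.abs(theta - theta_old)) < settings.tol:
            converged = True
            break
        if p == 2.0:
            # D = I: the map no longer depends on eta, so one step suffices
            converged = True
            break

    if not converged:
        warnings.warn(
            f"EM did not converge in {settings.max_iter} iterations "
            f"(lam={lam:g}); returning last iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    return FitResult(
        theta=theta,
        support=np.flatnonzero(theta),
        n_iter=n_iter,
        converged=converged,
        objective=objective(data, theta, lam),
        lam=lam,
        p=p,
        history=tuple(trace) if history else None,
    )


def l0em_fit(data: RegressionData, settings: SolverSettings, **kw) -> FitResult:
    """Primal L0 EM fit (m x m M-step); requires ``settings.p == 0``."""
    if settings.p != 0.0:
        raise ValueError("l0em_fit requires p = 0; use lpem_fit for p > 0")
    kw.setdefault("dual", False)
    return em_fit(data, settings, **kw)


def dl0em_fit(data: RegressionData, settings: SolverSettings, **kw) -> FitResult:
    """Dual L0 EM fit (n x n M-step), the efficient form for n << m."""
    if settings.p != 0.0:
        raise ValueError("dl0em_fit requires p = 0; use lpem_fit for p > 0")
    kw.setdefault("dual", True)
    return em_fit(data, settings, **kw)


def lpem_fit(data: RegressionData, settings: SolverSettings, **kw) -> FitResult:
    """Lp EM fit for any p in [0, 2] (weights D = diag(|eta|^(2-p)))."""
    return em_fit(data, settings, **kw)


def check_contraction(
    data: RegressionData, theta: np.ndarray, lam: float
) -> dict:
    """Sufficient-condition diagnostic for convergence of the fixed point.

    Computes ``gamma_bound = 2 lam ||(D X'X + lam I)^-2||_inf ||D X'y||_inf``
    with ``D = diag(theta^2)``.  The iteration map is a contraction near
    ``theta`` when ``gamma_bound < 1``; the solvers run regardless, this is
    purely informative.
    """
    theta = np.asarray(theta, dtype=float).ravel()
    X, y = data.X, data.y
    m = data.n_features
    if theta.shape[0] != m:
        raise ValueError("theta length does not match n_features")
    D = theta**2
    M = D[:, None] * (X.T @ X) + lam * np.eye(m)
    Minv = np.linalg.inv(M)
    Minv2 = Minv @ Minv
    norm_inf = float(np.max(np.abs(Minv2).sum(axis=1)))
    rhs = float(np.max(np.abs(D * (X.T @ y)))) if m else 0.0
    gamma_bound = 2.0 * lam * norm_inf * rhs
    return {"gamma_bound": gamma_bound, "satisfied": bool(gamma_bound < 1.0)}
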