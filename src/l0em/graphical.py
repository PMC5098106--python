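"""Gaussian graphical model by L0 neighborhood selection.

Each variable x_j is regressed on all remaining variables with an
L0-penalized fit; the nonzero coefficients measure partial association, and
the collected nonzero coefficients across the m regressions are the edges of
the graph.  Because the penalty weight can be fixed directly by AIC
(lambda = 2) or BIC (lambda = log n), only m regressions are needed — no
cross-validation — which is what makes the construction fast on expression
matrices.

An optional positive-dependency mode clamps negative coefficients to zero
inside every EM step, keeping only positive partial associations (the
convention of most coexpression databases).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .selection import info_criterion_lambda
from .solver import RegressionData, SolverSettings, em_fit

__all__ = [
    "Graph",
    "StructureMetrics",
    "fit_neighborhood",
    "build_network",
    "structure_metrics",
]


@dataclass(frozen=True)
class Graph:
    """Neighborhood-regression network.

    ``weights[j, i]`` is the coefficient of variable i in the regression of
    x_j on the others (diagonal zero).  ``adjacency`` is the symmetrized
    binary edge matrix; ``score[i, j] = max(|W[j, i]|, |W[i, j]|)`` ranks
    pairs for ROC analysis.
    """

    weights: np.ndarray
    adjacency: np.ndarray
    score: np.ndarray
    node_names: tuple[str, ...]
    symmetrization: str

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())

    def edge_list(self) -> list[tuple[str, str, float]]:
        i_idx, j_idx = np.nonzero(np.triu(self.adjacency, 1))
        return [
            (self.node_names[i], self.node_names[j], float(self.score[i, j]))
            for i, j in zip(i_idx, j_idx)
        ]

    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=0)


@dataclass(frozen=True)
class StructureMetrics:
    """Edge-recovery scores against a known adjacency.

    ``auc`` in [0, 1]; ``fdr`` and ``fnr`` in percent.  ``no_selection`` marks
    the degenerate case of an empty predicted edge set, for which the FDR is
    reported as 0.
    """

    auc: float
    fdr: float
    fnr: float
    no_selection: bool = False


def _solver_settings(lam: float, positive_only: bool,
                     base: SolverSettings | None) -> SolverSettings:
    if base is None:
        return SolverSettings(lam=lam, positive_only=positive_only)
    from dataclasses import replace
    return replace(base, lam=lam, positive_only=positive_only)


def fit_neighborhood(
    X: np.ndarray,
    j: int,
    lam: float | None = None,
    criterion: str = "bic",
    settings: SolverSettings | None = None,
    positive_only: bool = False,
    _gram: dict | None = None,
) -> np.ndarray:
    """L0 regression of column j on the remaining columns.

    Returns the coefficient vector over the other m - 1 variables (in column
    order with j removed).  ``lam`` overrides the information-criterion
    default (AIC/BIC on the sample count).
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if m < 2:
        raise ValueError("need at least 2 variables")
    y = X[:, j]
    if np.ptp(y) == 0.0:
        warnings.warn(f"variable {j} is constant; empty neighborhood",
                      RuntimeWarning, stacklevel=2)
        return np.zeros(m - 1)
    if lam is None:
        lam = info_criterion_lambda(criterion, n, m - 1)
    others = np.delete(np.arange(m), j)
    data = RegressionData(X[:, others], y)
    s = _solver_settings(lam, positive_only, settings)
    fit = em_fit(data, s, dual=n < m - 1)
    return fit.theta


def build_network(
    X: np.ndarray,
    criterion: str = "bic",
    lam: float | None = None,
    positive_only: bool = False,
    symmetrization: str = "OR",
    node_names: list[str] | None = None,
    settings: SolverSettings | None = None,
) -> Graph:
    """Assemble the neighborhood regressions of every variable into a graph.

    OR rule (default): an edge is present if either directed regression
    selects it; AND rule requires both.  Scores are the symmetrized absolute
    coefficient magnitudes.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    sym = symmetrization.upper()
    if sym not in ("OR", "AND"):
        raise ValueError("symmetrization must be 'OR' or 'AND'")
    if node_names is None:
        node_names = [f"x{i + 1}" for i in range(m)]
    W = np.zeros((m, m))
    for j in range(m):
        coef = fit_neighborhood(
            X, j, lam=lam, criterion=criterion,
            settings=settings, positive_only=positive_only,
        )
        others = np.delete(np.arange(m), j)
        W[j, others] = coef
    present = W.T != 0.0  # present[i, j]: regression of x_j selected x_i
    if sym == "OR":
        adjacency = (present | present.T).astype(int)
    else:
        adjacency = (present & present.T).astype(int)
    score = np.maximum(np.abs(W), np.abs(W.T))
    np.fill_diagonal(score, 0.0)
    return Graph(
        weights=W, adjacency=adjacency, score=score,
        node_names=tuple(node_names), symmetrization=sym,
    )


def structure_metrics(graph: Graph, truth: np.ndarray) -> StructureMetrics:
    """AUC / FDR / FNR of edge recovery against a true adjacency.

    All unordered pairs are ranked by the symmetrized coefficient magnitude
    (unselected pairs tied at 0) for the AUC; FDR and FNR are computed from
    the binary adjacency and reported in percent.
    """
    truth = np.asarray(truth)
    m = graph.n_nodes
    if truth.shape != (m, m):
        raise ValueError("truth shape does not match graph")
    if not np.array_equal(truth, truth.T) or np.any(np.diag(truth) != 0):
        raise ValueError("truth must be symmetric with zero diagonal")
    iu = np.triu_indices(m, 1)
    y_true = (truth[iu] != 0).astype(int)
    if y_true.sum() == 0:
        raise ValueError("truth has no edges; AUC undefined")
    scores = graph.score[iu]
    auc = float(roc_auc_score(y_true, scores))
    selected = graph.adjacency[iu] != 0
    n_sel = int(selected.sum())
    n_true = int(y_true.sum())
    if n_sel == 0:
        fdr = 0.0
        no_selection = True
    else:
        fdr = 100.0 * float((selected & (y_true == 0)).sum()) / n_sel
        no_selection = False
    fnr = 100.0 * float(((~selected) & (y_true == 1)).sum()) / n_true
    return StructureMetrics(auc=auc, fdr=fdr, fnr=fnr,
                            no_selection=no_selection)
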