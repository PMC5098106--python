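"""Reading delimited matrices and writing results.

Inputs are plain CSV/TSV with samples as rows and features as columns
(delimiter inferred from the extension, overridable).  Outputs are JSON for
fits and CV summaries, TSV edge lists / SIF for graphs, and TSV + JSON for
experiment tables.  Every written file embeds the seed and a short hash of
the generating configuration so runs can be traced.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .graphical import Graph
from .metrics import ReplicateSummary
from .selection import CVResult
from .solver import FitResult, RegressionData

__all__ = [
    "read_matrix",
    "read_regression",
    "config_hash",
    "write_fit",
    "write_cv",
    "write_graph",
    "write_experiment",
]

_DELIMS = {".csv": ",", ".tsv": "\t", ".txt": "\t"}


def _delimiter(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return _DELIMS.get(path.suffix.lower(), ",")


def read_matrix(path, sep: str | None = None, header: bool = True) -> pd.DataFrame:
    """Read a numeric samples x variables matrix from delimited text.

    NaN/Inf (including unparseable cells coerced to NaN) are rejected with a
    row/column-located error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_delimiter(path, sep),
                     header=0 if header else None)
    if not header:
        df.columns = [f"x{i + 1}" for i in range(df.shape[1])]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(numeric.to_numpy(dtype=float, na_value=np.nan))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-numeric or non-finite value at data row {i + 1}, "
            f"column {numeric.columns[j]!r}"
        )
    return numeric


def read_regression(
    path, response: str | None = None, response_path=None,
    sep: str | None = None,
) -> RegressionData:
    """Load a design/response pair.

    The response is either a named column of the matrix file or a separate
    single-column file.
    """
    df = read_matrix(path, sep=sep)
    if response_path is not None:
        ydf = read_matrix(response_path, sep=sep)
        if ydf.shape[1] != 1:
            raise ValueError("response file must have exactly one column")
        y = ydf.iloc[:, 0].to_numpy(dtype=float)
    elif response is not None:
        if response not in df.columns:
            raise ValueError(f"response column {response!r} not found")
        y = df.pop(response).to_numpy(dtype=float)
    else:
        raise ValueError("give a response column name or a response file")
    return RegressionData(df.to_numpy(dtype=float), y,
                          feature_names=tuple(df.columns))


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _meta(config: dict | None, seed) -> dict:
    meta = {"seed": seed}
    if config is not None:
        meta["config_hash"] = config_hash(config)
    return meta


def write_fit(fit: FitResult, outdir, feature_names=None,
              config: dict | None = None, seed=None) -> Path:
    """Serialize a fit to ``fit.json`` (support coefficients as a name map)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m = fit.theta.size
    names = list(feature_names) if feature_names else [
        f"x{i + 1}" for i in range(m)]
    payload = {
        "lam": fit.lam,
        "p": fit.p,
        "n_iter": fit.n_iter,
        "converged": fit.converged,
        "objective": fit.objective,
        "n_selected": fit.n_selected,
        "theta": {names[j]: float(fit.theta[j]) for j in fit.support},
        **_meta(config, seed),
    }
    path = outdir / "fit.json"
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def write_cv(cv: CVResult, outdir, config: dict | None = None,
             seed=None) -> Path:
    """Serialize a CV summary to ``cv.json`` plus a per-lambda ``cv.tsv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "lam_mse": cv.lam_mse,
        "lam_ss": cv.lam_ss,
        "lam_opt": cv.lam_opt,
        "lam_min": cv.grid.lam_min,
        "lam_max": cv.grid.lam_max,
        "n_points": cv.grid.n_points,
        **_meta(config, seed),
    }
    path = outdir / "cv.json"
    path.write_text(json.dumps(payload, indent=2) + "\n")
    pd.DataFrame({
        "lambda": cv.grid.values,
        "mse_mean": cv.mse_mean,
        "mse_sd": cv.mse_sd,
        "k_mean": cv.k_mean,
        "k_sd": cv.k_sd,
    }).to_csv(outdir / "cv.tsv", sep="\t", index=False)
    return path


def write_graph(graph: Graph, outdir, config: dict | None = None,
                seed=None, graphml: bool = False,
                positive_only: bool = False) -> Path:
    """Write edge list TSV, SIF and degree table (optional GraphML)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    edges = graph.edge_list()
    pd.DataFrame(edges, columns=["nodeA", "nodeB", "score"]).to_csv(
        outdir / "edges.tsv", sep="\t", index=False)
    interaction = "pd" if positive_only else "assoc"
    with open(outdir / "graph.sif", "w") as fh:
        for a, b, _ in edges:
            fh.write(f"{a}\t{interaction}\t{b}\n")
    pd.DataFrame({
        "node": graph.node_names,
        "degree": graph.degree(),
    }).to_csv(outdir / "degree.tsv", sep="\t", index=False)
    (outdir / "graph.json").write_text(json.dumps({
        "n_nodes": graph.n_nodes,
        "n_edges": graph.n_edges,
        "symmetrization": graph.symmetrization,
        **_meta(config, seed),
    }, indent=2) + "\n")
    if graphml:
        import networkx as nx
        G = nx.Graph()
        G.add_nodes_from(graph.node_names)
        for a, b, s in edges:
            G.add_edge(a, b, score=s)
        nx.write_graphml(G, outdir / "graph.graphml")
    return outdir / "edges.tsv"


def write_experiment(summary: ReplicateSummary, outdir,
                     config: dict | None = None, seed=None) -> Path:
    """Write ``summary.json`` and the tidy per-replicate ``replicates.tsv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "n_selected_mean": summary.n_selected_mean,
        "n_selected_sd": summary.n_selected_sd,
        "mse_mean": summary.mse_mean,
        "mse_sd": summary.mse_sd,
        "bias_mean": summary.bias_mean,
        "bias_sd": summary.bias_sd,
        "true_model_count": summary.true_model_count,
        "n_replicates": summary.n_replicates,
        **_meta(config, seed),
    }
    path = outdir / "summary.json"
    path.write_text(json.dumps(payload, indent=2) + "\n")
    pd.DataFrame(list(summary.records)).to_csv(
        outdir / "replicates.tsv", sep="\t", index=False)
    return path
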