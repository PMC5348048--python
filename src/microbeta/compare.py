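"""Co-occurrence baseline and network / profile exports.

Spearman rank correlation between taxa is the field's standard symmetric
co-occurrence measure; contrasting its network against the directed
interaction network is the point of the comparison: correlation cannot be
asymmetric, interaction can.  Edge direction convention for the interaction
network: an edge j -> i means taxon j influences taxon i (columns act on
rows in the global matrix).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

from .fields import LocalInteractionField
from .summarize import GlobalInteractionMatrix, Status
from .tables import AbundanceTable, EnvironmentTable

#: Default display thresholds for the two network types.
BETA_THRESHOLD = 0.1
RHO_THRESHOLD = 0.4


class CompareError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Spearman rank-correlation matrix over taxa."""

    rho: np.ndarray
    taxon_ids: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=list(self.taxon_ids),
                            columns=list(self.taxon_ids))


def spearman_matrix(a: AbundanceTable) -> CorrelationMatrix:
    """Pairwise Spearman rho (average ranks for ties, NaN for constant taxa)."""
    if a.n_samples < 3:
        raise CompareError("need at least 3 samples for rank correlation")
    if a.n_taxa == 1:
        rho = np.array([[1.0]])
    elif a.n_taxa == 2:
        r = float(scipy.stats.spearmanr(a.values[:, 0], a.values[:, 1]).statistic)
        rho = np.array([[1.0, r], [r, 1.0]])
    else:
        rho = np.asarray(scipy.stats.spearmanr(a.values).statistic)
    constant = a.values.std(axis=0) == 0
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(rho, a.taxon_ids)


def _strength_category(w: float) -> str:
    w = abs(w)
    if w >= 0.8:
        return "strong"
    if w >= 0.4:
        return "moderate"
    return "weak"


def export_network(matrix: GlobalInteractionMatrix | CorrelationMatrix,
                   threshold: float | None = None) -> nx.Graph:
    """Thresholded network: directed for interactions, undirected for rho.

    Interaction edges run source -> target = influencer -> influenced (the
    matrix column acts on the row); the self-loop diagonal is included when
    it passes the threshold.  Correlation edges are deduplicated (one
    undirected edge per unordered pair, no self-loops).  Edge attributes:
    ``weight``, ``sign``, ``strength``.
    """
    directed = isinstance(matrix, GlobalInteractionMatrix)
    if threshold is None:
        threshold = BETA_THRESHOLD if directed else RHO_THRESHOLD
    if threshold <= 0:
        raise CompareError("threshold must be positive")
    taxa = matrix.taxon_ids
    g: nx.Graph = nx.DiGraph() if directed else nx.Graph()
    g.add_nodes_from(taxa)
    values = matrix.beta if directed else matrix.rho
    for i, ti in enumerate(taxa):
        for j, tj in enumerate(taxa):
            if not directed and j <= i:
                continue  # deduplicate the symmetric matrix, skip diagonal
            w = values[i, j]
            if directed and matrix.status[i, j] is not Status.DETERMINATE:
                continue
            if not np.isfinite(w) or abs(w) < threshold:
                continue
            src, dst = (tj, ti) if directed else (ti, tj)
            g.add_edge(src, dst, weight=float(w),
                       sign="positive" if w > 0 else "negative",
                       strength=_strength_category(float(w)))
    return g


def write_network(g: nx.Graph, graphml_path: str | Path | None = None,
                  tsv_path: str | Path | None = None) -> None:
    """Serialize an edge network as GraphML and/or TSV edge list."""
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)
    if tsv_path is not None:
        rows = [{"source": u, "target": v, "weight": d["weight"],
                 "sign": d["sign"], "directed": g.is_directed()}
                for u, v, d in g.edges(data=True)]
        pd.DataFrame(rows, columns=["source", "target", "weight", "sign",
                                    "directed"]).to_csv(
            tsv_path, sep="\t", index=False, float_format="%.17g")


def export_gradient_profile(field: LocalInteractionField, e: EnvironmentTable,
                            pair: tuple[str, str], param: str) -> pd.DataFrame:
    """Per-sample interaction values of one pair along one gradient.

    Rows are sorted by the parameter value; columns: sample, the parameter
    value, and the local interaction coefficient of ``pair[1]`` on
    ``pair[0]``.
    """
    try:
        i = field.taxon_ids.index(pair[0])
        j = field.taxon_ids.index(pair[1])
    except ValueError as exc:
        raise CompareError(f"unknown taxon in pair {pair}") from exc
    try:
        a = field.param_ids.index(param)
    except ValueError as exc:
        raise CompareError(f"unknown parameter {param!r}") from exc
    if field.sample_ids != e.sample_ids:
        raise CompareError("field and environment table are not aligned")
    theta = e.values[:, e.param_ids.index(param)]
    frame = pd.DataFrame({
        "sample": list(field.sample_ids),
        param: theta,
        "beta": field.beta[i, j, a, :],
    })
    return frame.sort_values(param, kind="stable").reset_index(drop=True)


def write_heatmap(matrix: GlobalInteractionMatrix | CorrelationMatrix,
                  path: str | Path) -> None:
    """Dense matrix as TSV (the plotting-tool-ready heatmap payload)."""
    matrix.to_frame().to_csv(path, sep="\t", float_format="%.17g")
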