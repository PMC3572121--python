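"""Egocentric network metrics and cross-network metric associations.

Five per-node metrics (degree, betweenness, closeness, eigenvector
centrality, transitivity) are computed on the largest connected component
of each network, log-transformed (except closeness) and z-scored, and the
agreement between a survey metric and the same metric on an email network
is estimated as the slope of a no-intercept regression with SAR-disturbance
errors adjusted by *both* row-standardized adjacency matrices.

Conventions: betweenness uses the standard fractional shortest-path
accumulation with endpoints excluded; closeness is the inverse of the total
shortest-path distance to all others; eigenvector centrality is the
principal eigenvector scaled to maximum 1; transitivity is the local
clustering coefficient, undefined (NaN) for nodes of degree <= 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import TieNetwork
from .sar import SARFit, fit_sar, weight_matrix_from_network

__all__ = [
    "METRICS",
    "LOG_TRANSFORMED",
    "AssociationResult",
    "largest_component",
    "compute_metrics",
    "transform_metrics",
    "metric_association",
    "degree_summary",
]

METRICS = ["degree", "betweenness", "closeness", "eigenvector", "transitivity"]
LOG_TRANSFORMED = ["degree", "betweenness", "eigenvector", "transitivity"]


def largest_component(net: TieNetwork) -> TieNetwork:
    """Induced subnetwork on the largest connected component (undirected view).

    Directed networks are union-symmetrized first, since component structure
    and the egocentric metrics are compared on undirected ties only. Equal
    component sizes break toward the component containing the smallest node ID.
    """
    g = net.undirected_graph()
    if g.number_of_nodes() == 0:
        raise ValueError("empty network has no components")
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    sub = nx.Graph(g.subgraph(comps[0]))
    return TieNetwork(sub, method=net.method, threshold=net.threshold)


def compute_metrics(net: TieNetwork) -> pd.DataFrame:
    """All five egocentric metrics per node of a connected undirected network."""
    g = net.undirected_graph()
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if not nx.is_connected(g):
        raise ValueError("network must be connected; pass largest_component(net)")
    nodes = sorted(g.nodes)
    degree = {v: g.degree(v) for v in nodes}
    betweenness = nx.betweenness_centrality(g, normalized=False)
    # closeness = 1 / (total shortest-path distance to all others)
    nx_close = nx.closeness_centrality(g)
    n = len(nodes)
    closeness = {v: (nx_close[v] / (n - 1) if n > 1 else np.nan) for v in nodes}
    if n > 2:
        # dense symmetric eigendecomposition: deterministic (no iterative
        # solver start vector) and exact at these component sizes
        A = nx.to_numpy_array(g, nodelist=nodes)
        _, evecs = np.linalg.eigh(A)
        v = evecs[:, -1]
        if v.sum() < 0:  # Perron vector is single-signed on a connected graph
            v = -v
        v = v / v.max()
        eig = {node: float(v[i]) for i, node in enumerate(nodes)}
    else:
        eig = {v: 1.0 for v in nodes}
    clust = nx.clustering(g)
    transitivity = {v: (clust[v] if degree[v] > 1 else np.nan) for v in nodes}
    return pd.DataFrame(
        {
            "degree": [float(degree[v]) for v in nodes],
            "betweenness": [float(betweenness[v]) for v in nodes],
            "closeness": [float(closeness[v]) for v in nodes],
            "eigenvector": [float(eig[v]) for v in nodes],
            "transitivity": [float(transitivity[v]) for v in nodes],
        },
        index=pd.Index(nodes, name="person_id"),
    )


def _log_offset(col: pd.Series) -> float:
    """Half the smallest positive observed value (0 when the column is all-positive-free)."""
    pos = col[col > 0]
    return float(pos.min()) / 2.0 if len(pos) else 1.0


def transform_metrics(metric_table: pd.DataFrame, skip_zero_variance: bool = False) -> pd.DataFrame:
    """Log-transform right-skewed metrics and z-score every column.

    Degree, betweenness, eigenvector centrality and transitivity are
    log-transformed as ``log(x + eps)`` with ``eps`` half the smallest
    positive value in the column (betweenness and eigenvector values can be
    exactly zero); closeness is z-scored untransformed. NaN transitivity
    (degree <= 1) stays NaN — those individuals drop out of the
    transitivity comparison only. A zero-variance column raises unless
    ``skip_zero_variance``, in which case it is omitted from the output.
    """
    if not len(metric_table):
        raise ValueError("empty metric table")
    out = {}
    for col in METRICS:
        x = metric_table[col].astype(float)
        if col in LOG_TRANSFORMED:
            x = np.log(x + _log_offset(x))
        sd = x.std(ddof=1, skipna=True)
        if not np.isfinite(sd) or sd == 0:
            if skip_zero_variance:
                continue
            raise ValueError(f"zero variance in metric column {col!r}; cannot z-score")
        out[col] = (x - x.mean(skipna=True)) / sd
    return pd.DataFrame(out, index=metric_table.index)


@dataclass
class AssociationResult:
    """Slope of survey metric on email metric with SAR-adjusted residuals."""

    metric: str
    slope: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    fit: SARFit

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "slope": self.slope,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_half_width": 1.96 * self.se,
            "n": self.n,
        }


def metric_association(
    ng_metric_z: pd.Series,
    email_metric_z: pd.Series,
    W_ng,
    W_email,
    metric: str = "metric",
) -> AssociationResult:
    """Two-weight-matrix autoregressive regression of a survey metric on an email metric.

    Both z-scored metric vectors must be indexed by the same node set (the
    intersection of the two largest components); both weight matrices must
    share that node order. The model has no intercept (both variables are
    centered); the 95% interval is Wald (slope +- 1.96 se).
    """
    if not ng_metric_z.index.equals(email_metric_z.index):
        raise ValueError("metric vectors must share the same node index")
    y = ng_metric_z.to_numpy(float)
    x = email_metric_z.to_numpy(float)[:, None]
    fit = fit_sar(
        y, x, [W_ng, W_email],
        w_names=["survey", "email"], x_names=[f"email_{metric}"],
        name=f"association_{metric}",
    )
    slope = float(fit.beta[0])
    se = float(fit.beta_se[0])
    return AssociationResult(
        metric=metric,
        slope=slope,
        se=se,
        ci_low=slope - 1.96 * se,
        ci_high=slope + 1.96 * se,
        n=fit.n,
        fit=fit,
    )


def degree_summary(nets: dict[str, TieNetwork]) -> pd.DataFrame:
    """Median and range of degree on each network's largest component."""
    rows = []
    for name, net in nets.items():
        comp = largest_component(net)
        degs = np.array([d for _, d in comp.graph.degree()], dtype=float)
        rows.append(
            {
                "network": name,
                "median_degree": float(np.median(degs)),
                "min_degree": float(degs.min()),
                "max_degree": float(degs.max()),
                "component_size": comp.graph.number_of_nodes(),
            }
        )
    return pd.DataFrame(rows)
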