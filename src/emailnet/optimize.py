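"""Threshold sweeps scored against the name-generator reference network.

Each email construction is evaluated on a grid of thresholds; the scalar
score is the Pearson correlation between the vectorized 0/1 adjacency
matrices of the candidate network and the survey network over a fixed
comparison node set (directed candidates are union-symmetrized first,
because the reference is undirected). The sweep also records tie density,
the proportion of survey ties recovered, and false/true-positive
diagnostics, and picks the threshold with the largest correlation
(tie-break: the sparser network).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from . import ingest
from .network import TieNetwork

__all__ = [
    "SweepResult",
    "adjacency_correlation",
    "confusion_counts",
    "network_diagnostics",
    "sweep",
    "default_single_recipient_grid",
    "default_logistic_grid",
    "default_rank_grid",
    "respondents_only_view",
    "stability_curve",
    "plot_sweep",
    "plot_stability",
]


def _tie_vector(net: TieNetwork, node_order: Sequence) -> np.ndarray:
    """0/1 vector over unordered pairs within node_order (union-symmetrized)."""
    idx = {v: i for i, v in enumerate(node_order)}
    k = len(node_order)
    A = np.zeros((k, k), dtype=np.int8)
    for u, v in net.undirected_graph().edges:
        iu, iv = idx.get(u), idx.get(v)
        if iu is not None and iv is not None:
            A[iu, iv] = A[iv, iu] = 1
    return A[np.triu_indices(k, 1)]


def _check_node_set(net_a: TieNetwork, net_b: TieNetwork, node_set) -> list:
    nodes = sorted(node_set)
    if len(nodes) < 3:
        raise ValueError("node_set must contain at least 3 nodes")
    missing_a = set(nodes) - net_a.nodes
    missing_b = set(nodes) - net_b.nodes
    if missing_a or missing_b:
        raise ValueError(
            f"node_set not contained in both networks (missing: "
            f"{sorted(missing_a)[:3]} / {sorted(missing_b)[:3]})"
        )
    return nodes


def adjacency_correlation(net_a: TieNetwork, net_b: TieNetwork, node_set) -> float:
    """Pearson correlation of the two tie vectors over pairs within node_set."""
    nodes = _check_node_set(net_a, net_b, node_set)
    va = _tie_vector(net_a, nodes).astype(float)
    vb = _tie_vector(net_b, nodes).astype(float)
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("zero tie-vector variance (empty or complete network)")
    return float(np.corrcoef(va, vb)[0, 1])


def confusion_counts(
    email_net: TieNetwork, survey_net: TieNetwork, node_set
) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) over unordered pairs within node_set.

    An email tie is a true positive when the survey network holds the same
    (undirected) tie, a false positive otherwise.
    """
    nodes = _check_node_set(email_net, survey_net, node_set)
    ve = _tie_vector(email_net, nodes)
    vs = _tie_vector(survey_net, nodes)
    tp = int(np.sum((ve == 1) & (vs == 1)))
    fp = int(np.sum((ve == 1) & (vs == 0)))
    fn = int(np.sum((ve == 0) & (vs == 1)))
    tn = int(np.sum((ve == 0) & (vs == 0)))
    return tp, fp, fn, tn


def network_diagnostics(email_net: TieNetwork, survey_net: TieNetwork, node_set) -> dict:
    """Correlation, density and confusion diagnostics for one candidate network."""
    nodes = _check_node_set(email_net, survey_net, node_set)
    ve = _tie_vector(email_net, nodes).astype(float)
    vs = _tie_vector(survey_net, nodes).astype(float)
    tp = int(np.sum((ve == 1) & (vs == 1)))
    fp = int(np.sum((ve == 1) & (vs == 0)))
    fn = int(np.sum((ve == 0) & (vs == 1)))
    tn = int(np.sum((ve == 0) & (vs == 0)))
    if ve.std() == 0 or vs.std() == 0:
        corr = np.nan
    else:
        corr = float(np.corrcoef(ve, vs)[0, 1])
    survey_ties = tp + fn
    return {
        "correlation": corr,
        "density": float(ve.mean()),
        "recovery": tp / survey_ties if survey_ties else np.nan,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "fp_rate": fp / (fp + tn) if (fp + tn) else np.nan,
        "fp_tp_ratio": fp / tp if tp else np.inf,
    }


@dataclass
class SweepResult:
    """Diagnostics of one builder across its threshold grid."""

    method: str
    table: pd.DataFrame  # one row per threshold
    best_threshold: float

    @property
    def best_row(self) -> pd.Series:
        return self.table.set_index("threshold").loc[self.best_threshold]

    def to_dict(self) -> dict:
        best = self.best_row
        return {
            "method": self.method,
            "best_threshold": self.best_threshold,
            "best_correlation": float(best["correlation"]),
            "best_density": float(best["density"]),
            "best_recovery": float(best["recovery"]),
            "best_fp_tp_ratio": float(best["fp_tp_ratio"]),
            "thresholds": self.table["threshold"].tolist(),
            "correlations": self.table["correlation"].tolist(),
        }


def sweep(
    builder: Callable[[float], TieNetwork],
    grid: Iterable[float],
    survey_net: TieNetwork,
    node_set,
    method: str = "email",
) -> SweepResult:
    """Evaluate ``builder`` at each grid threshold against the survey network.

    Grid points whose network has zero tie variance on the node set score
    NaN; if every point does, the sweep fails. The best threshold maximizes
    correlation; exact ties go to the sparser network.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty threshold grid")
    rows = []
    for thr in grid:
        net = builder(thr)
        d = network_diagnostics(net, survey_net, node_set)
        d["threshold"] = float(thr)
        rows.append(d)
    table = pd.DataFrame(rows)[
        ["threshold", "correlation", "density", "recovery", "tp", "fp", "fn", "tn",
         "fp_rate", "fp_tp_ratio"]
    ]
    if table["correlation"].isna().all():
        raise ValueError(f"every grid point produced a zero-variance network ({method})")
    best_corr = table["correlation"].max()
    cand = table[np.isclose(table["correlation"], best_corr, rtol=0, atol=1e-12)]
    best = cand.sort_values(["density", "threshold"], kind="stable").iloc[0]
    return SweepResult(method=method, table=table, best_threshold=float(best["threshold"]))


def default_single_recipient_grid(n_steps: int = 40) -> np.ndarray:
    """Log-spaced grid from 1 email/month (0.25/week) to 20/week."""
    return np.geomspace(0.25, 20.0, n_steps)


def default_logistic_grid(max_probability: float) -> np.ndarray:
    """Probability thresholds at steps of 0.01 from 0.01 up to the fitted maximum."""
    top = max(0.01, np.floor(max_probability * 100) / 100)
    return np.round(np.arange(0.01, top + 1e-9, 0.01), 2)


def default_rank_grid() -> np.ndarray:
    """Rank thresholds 2..25 at intervals of one rank."""
    return np.arange(2, 26)


def respondents_only_view(
    builders: dict[str, Callable[[float], TieNetwork]],
    grids: dict[str, Iterable[float]],
    survey_net: TieNetwork,
    respondents: set | frozenset,
    email_nodes: set | frozenset,
) -> dict[str, SweepResult]:
    """Re-run each sweep restricted to survey respondents present in the email data.

    Mirrors the robustness check of re-optimizing thresholds on the
    respondent subset, where both endpoints of every reference tie were
    actually asked about their contacts.
    """
    node_set = (set(respondents) & set(email_nodes)) & set(survey_net.nodes)
    if not node_set:
        raise ValueError("no respondents present in both the survey and email data")
    return {
        name: sweep(builders[name], grids[name], survey_net, node_set, method=name)
        for name in builders
    }


def stability_curve(
    email_log: pd.DataFrame,
    builder_at_best: Callable[[pd.DataFrame, float], TieNetwork],
    week_grid: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Correlation of cumulative-week networks: weeks 1..N vs weeks 1..N+1.

    Weeks are consecutive 7-day bins from the first timestamp in the log.
    ``builder_at_best(pair_summaries, n_weeks)`` must build the network at
    its already-chosen threshold for a window of ``n_weeks`` weeks.
    """
    if not len(email_log):
        raise ValueError("empty email log")
    t0 = email_log["timestamp"].min()
    span_weeks = int(np.floor((email_log["timestamp"].max() - t0) / pd.Timedelta(weeks=1))) + 1
    if span_weeks < 2:
        raise ValueError("need at least 2 weeks of email to assess stability")
    if week_grid is None:
        week_grid = range(1, span_weeks)
    week_grid = [int(w) for w in week_grid]
    if any(w < 1 or w + 1 > span_weeks for w in week_grid):
        raise ValueError(f"week_grid must lie within 1..{span_weeks - 1}")

    def net_at(n_weeks: int) -> TieNetwork:
        pairs = ingest.aggregate_pairs(email_log, window=(t0, t0 + pd.Timedelta(weeks=n_weeks)))
        return builder_at_best(pairs, n_weeks)

    cache: dict[int, TieNetwork] = {}
    rows = []
    for n in week_grid:
        for m in (n, n + 1):
            if m not in cache:
                cache[m] = net_at(m)
        a, b = cache[n], cache[n + 1]
        common = a.nodes & b.nodes
        try:
            corr = adjacency_correlation(a, b, common)
        except ValueError:
            corr = np.nan
        rows.append({"weeks": n, "correlation": corr})
    return pd.DataFrame(rows)


def plot_sweep(results: dict[str, SweepResult], path) -> None:
    """Correlation and FP:TP ratio against threshold for each method."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, len(results), figsize=(4.2 * len(results), 6.5),
                             squeeze=False, sharex="col")
    for j, (name, res) in enumerate(results.items()):
        t = res.table
        axes[0][j].plot(t["threshold"], t["correlation"], marker=".")
        axes[0][j].axvline(res.best_threshold, color="k", lw=0.8, ls="--")
        axes[0][j].set_title(name)
        axes[0][j].set_ylabel("correlation with survey")
        finite = t[np.isfinite(t["fp_tp_ratio"])]
        axes[1][j].plot(finite["threshold"], finite["fp_tp_ratio"], marker=".", color="tab:red")
        axes[1][j].axvline(res.best_threshold, color="k", lw=0.8, ls="--")
        axes[1][j].set_ylabel("false:true positives")
        axes[1][j].set_xlabel("threshold")
        if name in ("single_recipient",):
            axes[0][j].set_xscale("log")
            axes[1][j].set_xscale("log")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_stability(curves: dict[str, pd.DataFrame], path) -> None:
    """Week-increment stability curves (weeks 1..N vs 1..N+1 correlation)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, df in curves.items():
        ax.plot(df["weeks"], df["correlation"], marker="o", label=name)
    ax.set_xlabel("weeks of email included (N vs N+1)")
    ax.set_ylabel("network correlation")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
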