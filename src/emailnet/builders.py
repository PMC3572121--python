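"""Constructing tie networks from the survey and from pair-level email summaries.

Three email-based constructions are implemented, each thresholding a
different statistic of the pair summaries:

* :func:`single_recipient_network` — undirected tie when the two-way
  single-recipient volume averages strictly more than a per-week threshold;
* :func:`logistic_network` — directed tie when a fitted logistic
  regression (on the feature set built by :func:`build_feature_table`)
  assigns a tie probability strictly above a threshold;
* :func:`ranked_partner_network` — directed tie from each ego to its
  top-ranked email partners by total single-recipient exchange.

Thresholds are strict (">") everywhere; rank thresholds are inclusive
("rank <= k") with min/competition ranking so equal volumes share the
better rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from collections import defaultdict

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ingest import SurveyTable
from .network import TieNetwork

__all__ = [
    "FEATURE_COLUMNS",
    "LogitModel",
    "build_survey_network",
    "single_recipient_network",
    "asymmetry_index",
    "sender_zscores",
    "contact_sets",
    "shared_contacts",
    "secondary_ties",
    "build_feature_table",
    "fit_tie_logit",
    "logistic_network",
    "ranked_partner_network",
]

FEATURE_COLUMNS = [
    "z_sent_single",
    "z_sent_multi",
    "log_single",
    "dummy_single_zero",
    "log_multi",
    "dummy_multi_zero",
    "log_size",
    "dummy_size_zero",
    "shared_contacts",
    "secondary_ties",
    "asym_single",
    "asym_multi",
]


def build_survey_network(survey: SurveyTable) -> TieNetwork:
    """Undirected name-generator network over respondents and named alters.

    Naming in any question creates the tie; duplicates and reciprocal
    namings collapse to a single undirected tie. Named non-respondents are
    nodes too.
    """
    g = nx.Graph()
    g.add_nodes_from(survey.people)
    for r, a in survey.ties.itertuples(index=False):
        g.add_edge(r, a)
    return TieNetwork(g, method="name_generator")


def _pair_nodes(pair_summaries: pd.DataFrame) -> list[str]:
    return sorted(set(pair_summaries["sender_id"]) | set(pair_summaries["recipient_id"]))


def _symmetric_counts(pair_summaries: pd.DataFrame, column: str) -> dict[tuple, int]:
    """Unordered-pair totals of an ordered-pair count column."""
    totals: dict[tuple, int] = defaultdict(int)
    for s, r, v in zip(pair_summaries["sender_id"], pair_summaries["recipient_id"],
                       pair_summaries[column]):
        key = (s, r) if s < r else (r, s)
        totals[key] += int(v)
    return totals


def single_recipient_network(
    pair_summaries: pd.DataFrame,
    threshold_per_week: float,
    window_weeks: float,
) -> TieNetwork:
    """Undirected network thresholding two-way single-recipient email volume.

    A tie exists when ``(n_single(A->B) + n_single(B->A)) / window_weeks``
    strictly exceeds ``threshold_per_week``. Multi-recipient email never
    counts. All people appearing in the summaries are nodes (possibly
    isolates).
    """
    if window_weeks <= 0:
        raise ValueError("window_weeks must be positive")
    if threshold_per_week <= 0:
        raise ValueError("threshold_per_week must be positive")
    g = nx.Graph()
    g.add_nodes_from(_pair_nodes(pair_summaries))
    for (a, b), total in _symmetric_counts(pair_summaries, "n_single").items():
        if total / window_weeks > threshold_per_week:
            g.add_edge(a, b)
    return TieNetwork(g, method="single_recipient", threshold=threshold_per_week)


def asymmetry_index(sent_ab: float, sent_ba: float) -> float:
    """Evenness of a pair's email exchange: |T/2 - s| / (T/2), T = total.

    0 means a perfectly even exchange; 1 means all mail flowed one way.
    Symmetric in argument order. Undefined (raises) for pairs with no email.
    """
    if sent_ab < 0 or sent_ba < 0:
        raise ValueError("counts must be nonnegative")
    total = sent_ab + sent_ba
    if total == 0:
        raise ValueError("asymmetry index undefined for a pair with zero email")
    half = total / 2.0
    return abs(half - sent_ab) / half


def sender_zscores(pair_summaries: pd.DataFrame, channel: str) -> dict[tuple, float]:
    """Within-sender z-scores of logged sent counts in one channel.

    For each sender, log counts over the partners with a positive count in
    the channel are standardized to mean 0 / sd 1 (sample sd, ddof=1).
    Senders with fewer than two positive-count partners, or zero variance,
    get z = 0 everywhere; (sender, partner) pairs with a zero count in the
    channel also get z = 0 (the channel's zero dummy carries that
    information instead).
    """
    col = {"single": "n_single", "multi": "n_multi"}.get(channel)
    if col is None:
        raise ValueError("channel must be 'single' or 'multi'")
    out: dict[tuple, float] = {}
    for sender, grp in pair_summaries.groupby("sender_id", sort=True):
        pos = grp[grp[col] > 0]
        if len(pos) < 2:
            continue
        logs = np.log(pos[col].to_numpy(float))
        sd = logs.std(ddof=1)
        if sd <= 0:
            continue
        z = (logs - logs.mean()) / sd
        for recipient, zi in zip(pos["recipient_id"], z):
            out[(sender, recipient)] = float(zi)
    return out


def contact_sets(pair_summaries: pd.DataFrame) -> dict[str, set]:
    """People each person has *sent* at least one email to (either channel)."""
    contacts: dict[str, set] = defaultdict(set)
    for s, r in zip(pair_summaries["sender_id"], pair_summaries["recipient_id"]):
        contacts[s].add(r)
    return dict(contacts)


def shared_contacts(pair: tuple, pair_summaries: pd.DataFrame | dict) -> int:
    """Number of third parties both members of the pair have emailed."""
    a, b = pair
    contacts = pair_summaries if isinstance(pair_summaries, dict) else contact_sets(pair_summaries)
    ca = contacts.get(a, set())
    cb = contacts.get(b, set())
    return len((ca & cb) - {a, b})


def secondary_ties(sender: str, pair_summaries: pd.DataFrame | dict) -> int:
    """Number of other people with whom the sender has more than one shared contact.

    Candidates are all other people in the summaries, whether or not the
    sender emailed them directly.
    """
    contacts = pair_summaries if isinstance(pair_summaries, dict) else contact_sets(pair_summaries)
    everyone = set(contacts)
    for cs in contacts.values():
        everyone |= cs
    count = 0
    for j in everyone:
        if j == sender:
            continue
        if shared_contacts((sender, j), contacts) > 1:
            count += 1
    return count


def _log_or_zero(x: float) -> float:
    return float(np.log(x)) if x > 0 else 0.0


def build_feature_table(
    pair_summaries: pd.DataFrame,
    survey_network: TieNetwork,
) -> pd.DataFrame:
    """One feature row per ordered pair that exchanged any email.

    Pair-level count variables (single, multi, file-size totals over both
    directions) are log-transformed; zeros map to 0 with the matching dummy
    set to 1. Sender z-scores and secondary-tie counts are sender-specific;
    asymmetry indices are pair-level per channel, set to 0 when the channel
    is silent (the dummy flags those rows). ``tie_label`` is 1 when the
    survey network holds the undirected tie.
    """
    single_tot = _symmetric_counts(pair_summaries, "n_single")
    multi_tot = _symmetric_counts(pair_summaries, "n_multi")
    size_tot = _symmetric_counts(pair_summaries, "size_sum")

    directed_single: dict[tuple, int] = {}
    directed_multi: dict[tuple, int] = {}
    for s, r, ns, nm in zip(pair_summaries["sender_id"], pair_summaries["recipient_id"],
                            pair_summaries["n_single"], pair_summaries["n_multi"]):
        directed_single[(s, r)] = directed_single.get((s, r), 0) + int(ns)
        directed_multi[(s, r)] = directed_multi.get((s, r), 0) + int(nm)

    z_single = sender_zscores(pair_summaries, "single")
    z_multi = sender_zscores(pair_summaries, "multi")
    contacts = contact_sets(pair_summaries)
    sg = survey_network.undirected_graph()

    pairs = sorted(k for k, v in {**single_tot, **multi_tot}.items())
    communicating = [p for p in pairs if single_tot.get(p, 0) + multi_tot.get(p, 0) > 0]
    sec_cache: dict[str, int] = {}

    rows = []
    for a, b in communicating:
        st = single_tot.get((a, b), 0)
        mt = multi_tot.get((a, b), 0)
        ft = size_tot.get((a, b), 0)
        sc = shared_contacts((a, b), contacts)
        label = int(sg.has_edge(a, b))
        if st > 0:
            asym_s = asymmetry_index(directed_single.get((a, b), 0), directed_single.get((b, a), 0))
        else:
            asym_s = 0.0
        if mt > 0:
            asym_m = asymmetry_index(directed_multi.get((a, b), 0), directed_multi.get((b, a), 0))
        else:
            asym_m = 0.0
        for sender, recipient in ((a, b), (b, a)):
            if sender not in sec_cache:
                sec_cache[sender] = secondary_ties(sender, contacts)
            rows.append(
                {
                    "sender_id": sender,
                    "recipient_id": recipient,
                    "z_sent_single": z_single.get((sender, recipient), 0.0),
                    "z_sent_multi": z_multi.get((sender, recipient), 0.0),
                    "log_single": _log_or_zero(st),
                    "dummy_single_zero": int(st == 0),
                    "log_multi": _log_or_zero(mt),
                    "dummy_multi_zero": int(mt == 0),
                    "log_size": _log_or_zero(ft),
                    "dummy_size_zero": int(ft == 0),
                    "shared_contacts": sc,
                    "secondary_ties": sec_cache[sender],
                    "asym_single": asym_s,
                    "asym_multi": asym_m,
                    "tie_label": label,
                }
            )
    return pd.DataFrame(rows, columns=["sender_id", "recipient_id", *FEATURE_COLUMNS, "tie_label"])


@dataclass
class LogitModel:
    """Fitted tie-prediction logistic regression."""

    params: pd.Series          # intercept ("const") + one coefficient per kept feature
    feature_names: list[str]   # features used (zero-variance columns dropped)
    converged: bool
    llf: float
    dropped: list[str]
    ridge: float = 0.0

    def predict(self, feature_table: pd.DataFrame) -> np.ndarray:
        """Fitted tie probabilities, strictly inside (0, 1)."""
        X = feature_table[self.feature_names].to_numpy(float)
        eta = self.params["const"] + X @ self.params[self.feature_names].to_numpy(float)
        p = 1.0 / (1.0 + np.exp(-eta))
        tiny = np.finfo(float).tiny
        return np.clip(p, tiny, 1 - 1e-16)


class PerfectSeparationError(RuntimeError):
    """The tie labels are perfectly separable from the email features."""


def _ridge_logit(y: np.ndarray, X: np.ndarray, alpha: float) -> tuple[np.ndarray, float]:
    """Penalized IRLS for L2-regularized logistic regression (intercept unpenalized)."""
    n, k = X.shape
    beta = np.zeros(k)
    pen = np.full(k, alpha)
    pen[0] = 0.0
    for _ in range(200):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1 - p), 1e-10, None)
        z = eta + (y - p) / w
        H = (X.T * w) @ X + np.diag(pen)
        beta_new = np.linalg.solve(H, (X.T * w) @ z)
        if np.max(np.abs(beta_new - beta)) < 1e-10:
            beta = beta_new
            break
        beta = beta_new
    eta = X @ beta
    ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    return beta, ll


def fit_tie_logit(
    feature_table: pd.DataFrame,
    features: list[str] | None = None,
    ridge: float = 0.0,
) -> LogitModel:
    """Maximum-likelihood logistic regression of survey ties on email features.

    Zero-variance features are dropped with a warning. Perfect separation
    raises :class:`PerfectSeparationError`; pass ``ridge > 0`` to fall back
    to an explicit L2-penalized fit instead.
    """
    features = list(features) if features is not None else list(FEATURE_COLUMNS)
    y = feature_table["tie_label"].to_numpy(float)
    if len(np.unique(y)) < 2:
        raise ValueError("need both tie and non-tie labels to fit the model")
    kept, dropped = [], []
    for f in features:
        if feature_table[f].nunique() > 1:
            kept.append(f)
        else:
            dropped.append(f)
    if dropped:
        warnings.warn(f"dropping zero-variance features: {dropped}", stacklevel=2)
    X = sm.add_constant(feature_table[kept].to_numpy(float), has_constant="add")

    if ridge > 0:
        beta, ll = _ridge_logit(y, X, ridge)
        params = pd.Series(beta, index=["const", *kept])
        return LogitModel(params, kept, True, ll, dropped, ridge=ridge)

    # IRLS via GLM-Binomial: same ML estimates as Logit, robust to the strong
    # collinearity among the volume features (pinv-based weighted least squares).
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    except Exception as exc:
        raise PerfectSeparationError(
            "logistic fit failed (likely perfect separation between tie labels "
            "and email features); refit with fit_tie_logit(..., ridge=<strength>) "
            f"to regularize explicitly. Original error: {exc}"
        ) from exc
    fitted = np.asarray(res.fittedvalues)
    saturated = np.all((fitted > 1 - 1e-8) == (y == 1)) and np.all(
        np.minimum(fitted, 1 - fitted) < 1e-8
    )
    if not res.converged or np.max(np.abs(res.params)) > 1e3 or saturated:
        raise PerfectSeparationError(
            "logistic MLE did not converge (perfect or near-perfect separation "
            "between tie labels and email features); refit with "
            "fit_tie_logit(..., ridge=<strength>) to regularize explicitly"
        )
    params = pd.Series(res.params, index=["const", *kept])
    return LogitModel(params, kept, True, float(res.llf), dropped)


def logistic_network(
    model: LogitModel,
    feature_table: pd.DataFrame,
    prob_threshold: float,
) -> TieNetwork:
    """Directed network: tie A->B when the fitted P(tie | A->B row) > threshold."""
    if not (0 < prob_threshold < 1):
        raise ValueError("prob_threshold must be in (0, 1)")
    p = model.predict(feature_table)
    g = nx.DiGraph()
    g.add_nodes_from(_pair_nodes(feature_table))
    mask = p > prob_threshold
    for s, r in zip(feature_table.loc[mask, "sender_id"], feature_table.loc[mask, "recipient_id"]):
        g.add_edge(s, r)
    return TieNetwork(g, method="logistic", threshold=prob_threshold)


def ranked_partner_network(pair_summaries: pd.DataFrame, rank_threshold: int) -> TieNetwork:
    """Directed network tying each ego to its top-k single-recipient partners.

    Partners are ordered by total single-recipient exchange (sent plus
    received) descending, with min/competition ranking so equal volumes
    share the better rank; a tie goes to every partner at rank <=
    ``rank_threshold``. Partners with zero single-recipient exchange never
    rank.
    """
    if rank_threshold < 1:
        raise ValueError("rank_threshold must be >= 1")
    totals = _symmetric_counts(pair_summaries, "n_single")
    per_ego: dict[str, dict[str, int]] = defaultdict(dict)
    for (a, b), tot in totals.items():
        if tot > 0:
            per_ego[a][b] = tot
            per_ego[b][a] = tot
    g = nx.DiGraph()
    g.add_nodes_from(_pair_nodes(pair_summaries))
    for ego, partners in per_ego.items():
        vols = pd.Series(partners)
        ranks = vols.rank(method="min", ascending=False)
        for alter, rank in ranks.items():
            if rank <= rank_threshold:
                g.add_edge(ego, alter)
    return TieNetwork(g, method="ranked_partner", threshold=float(rank_threshold))
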