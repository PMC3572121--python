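"""Synthetic coworker populations with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes about a mid-sized company:

* a sparse latent "offline" tie network with community structure
  (stochastic block model, so transitivity exceeds density);
* a name-generator survey answered by a fraction of the population, in
  which respondents name a subset of their true neighbours (capped at
  ``n_questions * max_names_per_question`` names);
* a multi-week email log in which tied pairs exchange mail at a much
  higher Poisson rate than untied pairs, modulated by a per-sender
  lognormal activity multiplier (producing the right-skewed per-person
  volume distribution seen in real corporate logs) and a Beta-distributed
  direction share (so email exchange is asymmetric within pairs);
* a trait (BMI) with known network autocorrelation ``rho_true``, simulated
  from the SAR-disturbance model on the *true* network.

Everything is driven by a single seeded RNG, so an identical config yields
a bit-identical population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .ingest import SurveyTable, write_email_log, write_survey, write_traits
from .network import TieNetwork
from .sar import row_standardize

__all__ = [
    "SyntheticConfig",
    "SyntheticPopulation",
    "person_ids",
    "generate_true_network",
    "generate_survey",
    "generate_email_log",
    "generate_trait",
    "generate_population",
    "write_population",
]

WINDOW_START = pd.Timestamp("2011-01-03")  # arbitrary fixed Monday


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic population.

    Defaults describe a desk-scale company: ~1000 people, a survey with
    ~47% response, a latent tie density of 0.004 (about 4 ties per person),
    and a 22-week email window in which tied pairs exchange ~2 single-
    recipient emails per week per direction against a faint background rate
    between untied coworkers.
    """

    n_people: int = 1000
    response_rate: float = 0.47
    n_questions: int = 4
    max_names_per_question: int = 5
    naming_prob: float = 0.9  # chance a respondent names any given true neighbour
    target_tie_density: float = 0.004
    base_email_rate_per_week: float = 0.002  # per ordered untied pair
    tied_email_rate_per_week: float = 2.0    # per ordered tied pair (expected)
    volume_skew: float = 1.0                 # sigma of the mean-1 lognormal sender multiplier
    asymmetry_beta_a: float = 2.0            # Beta(a, a) direction share within tied pairs
    n_weeks: int = 22
    multi_recipient_fraction: float = 0.59   # share of a pair's volume that is multi-recipient
    trait_mean: float = 27.6
    rho_true: float = 0.4
    noise_sd: float = 4.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tied_email_rate_per_week <= self.base_email_rate_per_week:
            raise ValueError("tied_email_rate_per_week must exceed base_email_rate_per_week")
        if not (0 <= self.rho_true < 1):
            raise ValueError("rho_true must be in [0, 1)")
        if not (0 < self.response_rate <= 1):
            raise ValueError("response_rate must be in (0, 1]")
        if not (0 < self.target_tie_density < 1):
            raise ValueError("target_tie_density must be in (0, 1)")
        if not (0 <= self.multi_recipient_fraction < 1):
            raise ValueError("multi_recipient_fraction must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_weeks < 1:
            raise ValueError("n_weeks must be >= 1")
        if not (0 <= self.naming_prob <= 1):
            raise ValueError("naming_prob must be in [0, 1]")
        if self.volume_skew < 0:
            raise ValueError("volume_skew must be nonnegative")

    @property
    def name_cap(self) -> int:
        """Per-respondent cap on distinct named contacts (20 at defaults)."""
        return self.n_questions * self.max_names_per_question


@dataclass
class SyntheticPopulation:
    """Ground truth plus the three observable tables derived from it."""

    config: SyntheticConfig
    true_network: TieNetwork
    survey: SurveyTable
    email_log: pd.DataFrame
    trait: pd.Series

    @property
    def people(self) -> list[str]:
        return sorted(self.true_network.nodes)


def person_ids(n: int) -> list[str]:
    return [f"P{i:04d}" for i in range(n)]


def _sbm_probabilities(n: int, sizes: list[int], density: float) -> tuple[float, float]:
    """Within/between block probabilities hitting the target density in expectation."""
    total_pairs = n * (n - 1) / 2
    within_pairs = sum(s * (s - 1) / 2 for s in sizes)
    f_w = within_pairs / total_pairs
    in_share = 0.7  # fraction of expected ties placed within blocks
    if f_w >= 1:  # single block
        return density, 0.0
    p_in = min(1.0, in_share * density / f_w) if f_w > 0 else 0.0
    p_out = (density - p_in * f_w) / (1 - f_w)
    return p_in, max(p_out, 0.0)


def generate_true_network(config: SyntheticConfig, rng: np.random.Generator | None = None) -> TieNetwork:
    """Sample the latent offline tie network from a stochastic block model.

    Blocks of ~25 people concentrate ties locally so the network is
    clustered (transitivity > density), as real coworker networks are.
    """
    n = config.n_people
    if n < 3:
        raise ValueError("need n_people >= 3")
    expected_ties = config.target_tie_density * n * (n - 1) / 2
    if expected_ties < 1:
        raise ValueError(
            f"infeasible density: n_people={n} at target_tie_density="
            f"{config.target_tie_density} expects {expected_ties:.3f} < 1 tie"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_blocks = max(1, int(round(n / 25)))
    sizes = [len(b) for b in np.array_split(np.arange(n), n_blocks)]
    p_in, p_out = _sbm_probabilities(n, sizes, config.target_tie_density)
    P = np.full((n_blocks, n_blocks), p_out)
    np.fill_diagonal(P, p_in)
    seed = int(rng.integers(0, 2**31 - 1))
    g = nx.stochastic_block_model(sizes, P.tolist(), seed=seed)
    g = nx.relabel_nodes(g, dict(zip(range(n), person_ids(n))))
    graph = nx.Graph()
    graph.add_nodes_from(person_ids(n))
    graph.add_edges_from(g.edges)
    return TieNetwork(graph, method="synthetic_truth", threshold=None)


def generate_survey(
    true_network: TieNetwork,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> SurveyTable:
    """Sample name-generator responses: respondents name true neighbours.

    A fraction ``response_rate`` of people respond; each respondent names
    each true neighbour independently with probability ``naming_prob``,
    truncated to the ``name_cap`` by sampling without replacement when the
    would-name set exceeds the cap. The naming process never invents ties.
    """
    people = sorted(true_network.nodes)
    if not people:
        raise ValueError("true network is empty")
    n_resp = max(1, int(round(config.response_rate * len(people))))
    respondents = sorted(rng.choice(people, size=n_resp, replace=False))
    graph = true_network.graph
    rows: list[tuple[str, str]] = []
    for r in respondents:
        neigh = sorted(graph.neighbors(r))
        if not neigh:
            continue
        mask = rng.random(len(neigh)) < config.naming_prob
        would_name = [v for v, m in zip(neigh, mask) if m]
        if len(would_name) > config.name_cap:
            would_name = sorted(rng.choice(would_name, size=config.name_cap, replace=False))
        rows.extend((r, v) for v in would_name)
    df = pd.DataFrame(rows, columns=["respondent_id", "named_id"]).astype("string")
    return SurveyTable(df)


def _expand_records(
    rng: np.random.Generator,
    sender_idx: np.ndarray,
    recipient_idx: np.ndarray,
    counts: np.ndarray,
    ids: list[str],
    n_weeks: int,
    multi: bool,
) -> pd.DataFrame:
    total = int(counts.sum())
    if total == 0:
        return pd.DataFrame(
            {"sender_id": [], "recipient_id": [], "timestamp": [], "n_recipients": [], "file_size": []}
        )
    s = np.repeat(sender_idx, counts)
    r = np.repeat(recipient_idx, counts)
    seconds = rng.random(total) * n_weeks * 7 * 86400
    ts = WINDOW_START + pd.to_timedelta(np.floor(seconds).astype(np.int64), unit="s")
    if multi:
        nrec = 2 + rng.poisson(2.0, size=total)
    else:
        nrec = np.ones(total, dtype=int)
    size = np.maximum(1, rng.lognormal(mean=8.5, sigma=1.2, size=total)).astype(np.int64)
    arr = np.asarray(ids, dtype=object)
    return pd.DataFrame(
        {
            "sender_id": arr[s],
            "recipient_id": arr[r],
            "timestamp": ts,
            "n_recipients": nrec,
            "file_size": size,
        }
    )


def generate_email_log(
    true_network: TieNetwork,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate the per-delivery email log over the study window.

    Single-recipient counts per ordered pair are Poisson with rate
    ``tied_rate`` (tied pairs, split across directions by a Beta(a, a)
    share) or ``base_rate`` (untied pairs), both multiplied by the sender's
    lognormal activity multiplier. Multi-recipient deliveries are an extra
    Poisson stream scaled so they form ``multi_recipient_fraction`` of each
    pair's expected volume. Timestamps are uniform over the window, which
    for a constant-rate Poisson process equals week-by-week generation.
    """
    ids = sorted(true_network.nodes)
    n = len(ids)
    idx = {v: i for i, v in enumerate(ids)}
    weeks = config.n_weeks
    skew = config.volume_skew
    if skew > 0:
        mult = np.exp(skew * rng.standard_normal(n) - skew**2 / 2)
    else:
        mult = np.ones(n)

    mf = config.multi_recipient_fraction
    mf_ratio = mf / (1 - mf)

    frames = []

    # tied pairs: total pair rate 2*tied_rate split by a Beta(a,a) share
    edges = sorted(tuple(sorted(e)) for e in true_network.graph.edges)
    if edges:
        u = np.array([idx[a] for a, _ in edges])
        v = np.array([idx[b] for _, b in edges])
        share = rng.beta(config.asymmetry_beta_a, config.asymmetry_beta_a, size=len(edges))
        rate_uv = 2 * config.tied_email_rate_per_week * share * mult[u]
        rate_vu = 2 * config.tied_email_rate_per_week * (1 - share) * mult[v]
        for s_idx, r_idx, rate in ((u, v, rate_uv), (v, u, rate_vu)):
            c_single = rng.poisson(rate * weeks)
            frames.append(_expand_records(rng, s_idx, r_idx, c_single, ids, weeks, multi=False))
            c_multi = rng.poisson(rate * weeks * mf_ratio)
            frames.append(_expand_records(rng, s_idx, r_idx, c_multi, ids, weeks, multi=True))

    # untied pairs: draw each sender's total at the all-partners rate, address
    # recipients uniformly among the other n-1 people, then discard deliveries
    # that landed on a true neighbour -- Poisson thinning leaves exactly
    # rate base*mult*weeks per ordered untied pair.
    if config.base_email_rate_per_week > 0 and n > 1:
        adj = {a: set(true_network.graph.neighbors(a)) for a in ids}
        for multi_flag, factor in ((False, 1.0), (True, mf_ratio)):
            totals = rng.poisson(config.base_email_rate_per_week * mult * weeks * (n - 1) * factor)
            senders = np.repeat(np.arange(n), totals)
            if len(senders):
                offsets = rng.integers(1, n, size=len(senders))
                recipients = (senders + offsets) % n
                keep = np.array(
                    [ids[r] not in adj[ids[s]] for s, r in zip(senders, recipients)]
                )
                senders, recipients = senders[keep], recipients[keep]
                counts = np.ones(len(senders), dtype=int)
                frames.append(
                    _expand_records(rng, senders, recipients, counts, ids, weeks, multi=multi_flag)
                )

    frames = [f for f in frames if len(f)]
    if frames:
        log = pd.concat(frames, ignore_index=True)
    else:
        log = pd.DataFrame(
            {
                "sender_id": pd.Series(dtype=object),
                "recipient_id": pd.Series(dtype=object),
                "timestamp": pd.Series(dtype="datetime64[ns]"),
                "n_recipients": pd.Series(dtype=int),
                "file_size": pd.Series(dtype=np.int64),
            }
        )
    log["sender_id"] = log["sender_id"].astype("string")
    log["recipient_id"] = log["recipient_id"].astype("string")
    log = log.sort_values(
        ["timestamp", "sender_id", "recipient_id", "n_recipients", "file_size"],
        kind="stable",
    ).reset_index(drop=True)
    return log


def generate_trait(
    true_network: TieNetwork,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> pd.Series:
    """Simulate the trait from the SAR-disturbance model on the true network.

    y = mu + eps with (I - rho W) eps = nu, W the row-standardized true
    adjacency and nu iid N(0, noise_sd^2). At rho_true = 0 the values are
    iid normal.
    """
    ids = sorted(true_network.nodes)
    n = len(ids)
    A01 = nx.to_numpy_array(true_network.undirected_graph(), nodelist=ids, dtype=float)
    W = row_standardize(A01, ids, name="true").W
    A = np.eye(n) - config.rho_true * W
    nu = rng.normal(0.0, config.noise_sd, size=n)
    try:
        eps = np.linalg.solve(A, nu)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"I - rho W singular at rho_true={config.rho_true}"
        ) from exc
    return pd.Series(config.trait_mean + eps, index=pd.Index(ids, name="person_id"), name="bmi")


def generate_population(config: SyntheticConfig) -> SyntheticPopulation:
    """Generate a full population from one RNG stream seeded by the config."""
    rng = np.random.default_rng(config.seed)
    net = generate_true_network(config, rng)
    survey = generate_survey(net, config, rng)
    log = generate_email_log(net, config, rng)
    trait = generate_trait(net, config, rng)
    return SyntheticPopulation(config, net, survey, log, trait)


def write_population(pop: SyntheticPopulation, outdir: str | Path) -> dict[str, Path]:
    """Write the three observable tables as the CSV dialects ingest reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return {
        "email_log": write_email_log(pop.email_log, outdir / "email_log.csv"),
        "survey": write_survey(pop.survey, outdir / "survey.csv"),
        "traits": write_traits(pop.trait, outdir / "traits.csv"),
    }
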