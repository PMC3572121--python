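"""End-to-end orchestration: data -> networks -> sweeps -> SAR -> metrics -> report.

A run starts either from a :class:`~emailnet.synthetic.SyntheticConfig`
(closed-loop simulation) or from user-supplied CSV paths, and produces a
report bundle mirroring the study's deliverables:

1. per-method threshold sweeps (all individuals and respondents-only);
2. BMI SAR comparison across the survey network and the three email
   networks at their optimized thresholds (rho, z, p, AIC);
3. metric-association table (five egocentric metrics x three methods);
4. threshold-diagnostic and week-increment stability plots;
5. a machine-readable ``report.json`` of everything, plus tidy CSVs.

All randomness flows from the single configured seed; a rerun with the same
config writes a byte-identical ``report.json``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import builders, ego, ingest, optimize, sar, synthetic
from .network import TieNetwork, write_network

__all__ = ["RunConfig", "ReportBundle", "run_full_analysis"]

log = logging.getLogger("emailnet")

EMAIL_METHODS = ("single_recipient", "logistic", "ranked_partner")


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    Exactly one of ``synthetic`` / ``inputs`` must be provided. ``inputs``
    maps the keys ``email_log``, ``survey``, ``traits`` to CSV paths.
    """

    synthetic: synthetic.SyntheticConfig | None = None
    inputs: dict[str, str] | None = None
    output_dir: str | Path = "emailnet_out"
    seed: int | None = None
    single_grid_steps: int = 40
    rank_min: int = 2
    rank_max: int = 25
    logit_ridge: float = 0.0
    window_weeks: float | None = None
    make_plots: bool = True
    stability: bool = True
    stability_methods: tuple[str, ...] = ("single_recipient", "ranked_partner")

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("provide exactly one of synthetic config or input paths")
        if self.inputs is not None:
            missing = {"email_log", "survey", "traits"} - set(self.inputs)
            if missing:
                raise ValueError(f"inputs missing paths: {sorted(missing)}")
        if self.synthetic is not None and self.seed is not None:
            self.synthetic = synthetic.SyntheticConfig(
                **{**asdict(self.synthetic), "seed": int(self.seed)}
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = synthetic.SyntheticConfig(**raw["synthetic"])
        if "stability_methods" in raw:
            raw["stability_methods"] = tuple(raw["stability_methods"])
        return cls(**raw)


@dataclass
class ReportBundle:
    """Everything a run produced, with paths to the written artifacts."""

    config: RunConfig
    sweeps: dict[str, optimize.SweepResult]
    sweeps_respondents: dict[str, optimize.SweepResult]
    networks: dict[str, TieNetwork]
    sar_fits: dict[str, sar.SARFit]
    sar_comparison: pd.DataFrame
    associations: dict[str, dict[str, ego.AssociationResult]]
    degree_table: pd.DataFrame
    stability: dict[str, pd.DataFrame]
    filter_counts: dict[str, int]
    report: dict
    paths: dict[str, Path] = field(default_factory=dict)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _load_tables(cfg: RunConfig):
    """Return (email_records, survey, trait, true_network_or_None)."""
    if cfg.synthetic is not None:
        pop = synthetic.generate_population(cfg.synthetic)
        return pop.email_log, pop.survey, pop.trait, pop.true_network
    records = ingest.read_email_log(cfg.inputs["email_log"])
    survey = ingest.read_survey(cfg.inputs["survey"])
    trait = ingest.read_traits(cfg.inputs["traits"])
    return records, survey, trait, None


def run_full_analysis(cfg: RunConfig) -> ReportBundle:
    """Run the full pipeline and write the report bundle to ``cfg.output_dir``."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    records, survey, trait, true_net = _load_tables(cfg)
    log.info("stage=load records=%d respondents=%d named=%d traits=%d",
             len(records), len(survey.respondents), len(survey.named), trait.notna().sum())

    n_total = len(records)
    internal = records[records["sender_id"].notna() & records["recipient_id"].notna()]
    filtered = ingest.filter_internal(records, survey.people)
    filter_counts = {
        "records_total": int(n_total),
        "records_external": int(n_total - len(internal)),
        "records_non_survey": int(len(internal) - len(filtered)),
        "records_kept": int(len(filtered)),
    }
    log.info("stage=filter %s", filter_counts)
    if not len(filtered):
        raise ValueError("no email records survive the exclusion filters")

    pairs = ingest.aggregate_pairs(filtered)
    span = filtered["timestamp"].max() - filtered["timestamp"].min()
    window_weeks = cfg.window_weeks or max(1.0, float(np.ceil(span / pd.Timedelta(weeks=1))))
    log.info("stage=aggregate pairs=%d window_weeks=%s", len(pairs), window_weeks)

    survey_net = builders.build_survey_network(survey)
    features = builders.build_feature_table(pairs, survey_net)
    model = builders.fit_tie_logit(features, ridge=cfg.logit_ridge)
    log.info("stage=logit rows=%d dropped=%s", len(features), model.dropped)

    email_people = set(pairs["sender_id"]) | set(pairs["recipient_id"])
    node_set = email_people & set(survey_net.nodes)
    log.info("stage=node_set email=%d survey=%d common=%d",
             len(email_people), len(survey_net.nodes), len(node_set))

    builder_fns = {
        "single_recipient": lambda thr: builders.single_recipient_network(pairs, thr, window_weeks),
        "logistic": lambda thr: builders.logistic_network(model, features, thr),
        "ranked_partner": lambda thr: builders.ranked_partner_network(pairs, int(thr)),
    }
    grids = {
        "single_recipient": optimize.default_single_recipient_grid(cfg.single_grid_steps),
        "logistic": optimize.default_logistic_grid(float(model.predict(features).max())),
        "ranked_partner": np.arange(cfg.rank_min, cfg.rank_max + 1),
    }
    sweeps = {
        name: optimize.sweep(builder_fns[name], grids[name], survey_net, node_set, method=name)
        for name in EMAIL_METHODS
    }
    for name, res in sweeps.items():
        log.info("stage=sweep method=%s best_threshold=%.4g correlation=%.3f",
                 name, res.best_threshold, res.best_row["correlation"])
    sweeps_resp = optimize.respondents_only_view(
        builder_fns, grids, survey_net, survey.respondents, email_people
    )

    networks: dict[str, TieNetwork] = {"name_generator": survey_net}
    for name in EMAIL_METHODS:
        networks[name] = builder_fns[name](sweeps[name].best_threshold)

    # --- BMI network autocorrelation on the three-way intersection ---
    with_trait = set(trait.dropna().index)
    sar_nodes = sorted(node_set & with_trait)
    sar_fits: dict[str, sar.SARFit] = {}
    for name, net in networks.items():
        wm = sar.weight_matrix_from_network(net, sar_nodes, keep_direction=True, name=name)
        sar.density_guard(wm)
        y = trait.loc[sar_nodes].to_numpy(float)
        sar_fits[name] = sar.fit_sar(y, None, [wm], w_names=[name],
                                     x_names=["intercept"], name=name)
        log.info("stage=sar network=%s rho=%.3f aic=%.1f n=%d",
                 name, sar_fits[name].rho[0], sar_fits[name].aic, sar_fits[name].n)
    sar_comparison = sar.compare_models(sar_fits)

    # --- egocentric metric associations (undirected ties only) ---
    survey_comp = ego.largest_component(survey_net)
    survey_metrics = ego.transform_metrics(ego.compute_metrics(survey_comp),
                                           skip_zero_variance=True)
    associations: dict[str, dict[str, ego.AssociationResult]] = {}
    for name in EMAIL_METHODS:
        email_comp = ego.largest_component(networks[name])
        email_metrics = ego.transform_metrics(ego.compute_metrics(email_comp),
                                              skip_zero_variance=True)
        common = sorted(set(survey_metrics.index) & set(email_metrics.index))
        associations[name] = {}
        for metric in ego.METRICS:
            if metric not in survey_metrics.columns or metric not in email_metrics.columns:
                log.warning("stage=association method=%s metric=%s skipped (zero variance)",
                            name, metric)
                continue
            ys = survey_metrics.loc[common, metric]
            xs = email_metrics.loc[common, metric]
            keep = [v for v in common if np.isfinite(ys[v]) and np.isfinite(xs[v])]
            if len(keep) < 10:
                log.warning("stage=association method=%s metric=%s skipped (n=%d)",
                            name, metric, len(keep))
                continue
            W_ng = sar.weight_matrix_from_network(survey_comp, keep, name="survey")
            W_em = sar.weight_matrix_from_network(email_comp, keep, name=name)
            associations[name][metric] = ego.metric_association(
                ys.loc[keep], xs.loc[keep], W_ng, W_em, metric=metric
            )
    degree_table = ego.degree_summary(networks)

    # --- week-increment stability ---
    stability: dict[str, pd.DataFrame] = {}
    if cfg.stability:
        for name in cfg.stability_methods:
            thr = sweeps[name].best_threshold
            if name == "single_recipient":
                def build(p, w, thr=thr):
                    return builders.single_recipient_network(p, thr, w)
            elif name == "ranked_partner":
                def build(p, w, thr=thr):
                    return builders.ranked_partner_network(p, int(thr))
            else:
                continue
            try:
                stability[name] = optimize.stability_curve(filtered, build)
            except ValueError as exc:
                log.warning("stage=stability method=%s skipped: %s", name, exc)

    report = {
        "filters": filter_counts,
        "window_weeks": window_weeks,
        "n_nodes": {
            "email": len(email_people),
            "survey": len(survey_net.nodes),
            "comparison": len(node_set),
            "sar": len(sar_nodes),
        },
        "logit": {
            "features": model.feature_names,
            "coefficients": {k: float(v) for k, v in model.params.items()},
            "dropped": model.dropped,
            "ridge": model.ridge,
        },
        "sweeps": {name: res.to_dict() for name, res in sweeps.items()},
        "sweeps_respondents_only": {name: res.to_dict() for name, res in sweeps_resp.items()},
        "sar_bmi": {name: fit.to_dict() for name, fit in sar_fits.items()},
        "sar_comparison": sar_comparison.to_dict(orient="records"),
        "associations": {
            name: {m: a.to_dict() for m, a in assoc.items()}
            for name, assoc in associations.items()
        },
        "degree_summary": degree_table.to_dict(orient="records"),
        "stability": {name: df.to_dict(orient="list") for name, df in stability.items()},
    }
    if cfg.synthetic is not None:
        report["synthetic_config"] = asdict(cfg.synthetic)

    paths: dict[str, Path] = {}
    report_path = outdir / "report.json"
    with open(report_path, "w", encoding="utf-8") as fh:
        json.dump(_jsonify(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["report"] = report_path
    for name, res in sweeps.items():
        p = outdir / f"sweep_{name}.csv"
        res.table.to_csv(p, index=False)
        paths[f"sweep_{name}"] = p
    assoc_rows = [
        {"method": name, **a.to_dict()}
        for name, assoc in associations.items()
        for a in assoc.values()
    ]
    p = outdir / "metric_associations.csv"
    pd.DataFrame(assoc_rows).to_csv(p, index=False)
    paths["associations"] = p
    p = outdir / "sar_comparison.csv"
    sar_comparison.to_csv(p, index=False)
    paths["sar_comparison"] = p
    for name, net in networks.items():
        paths[f"network_{name}"] = write_network(net, outdir / f"network_{name}")["edges"]
    if cfg.make_plots:
        optimize.plot_sweep(sweeps, outdir / "threshold_diagnostics.png")
        paths["plot_sweeps"] = outdir / "threshold_diagnostics.png"
        if stability:
            optimize.plot_stability(stability, outdir / "stability.png")
            paths["plot_stability"] = outdir / "stability.png"

    return ReportBundle(
        config=cfg,
        sweeps=sweeps,
        sweeps_respondents=sweeps_resp,
        networks=networks,
        sar_fits=sar_fits,
        sar_comparison=sar_comparison,
        associations=associations,
        degree_table=degree_table,
        stability=stability,
        filter_counts=filter_counts,
        report=report,
        paths=paths,
    )
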