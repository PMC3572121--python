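# emailnet

Infer coworker social networks from corporate email logs, validate them
against a name-generator survey, and quantify how a health trait (body
mass index) autocorrelates across the inferred ties.

Survey-based network mapping is the validated way to measure health-relevant
social ties, but surveys are slow and response rates are low, so survey
networks miss many ties. Email logs cover everyone. This package implements
and evaluates three ways of turning an email log into an unweighted social
network, using the survey network as the reference:

1. **Single-recipient threshold** — an undirected tie when a pair's two-way
   single-recipient email volume averages strictly more than a chosen number
   of emails per week.
2. **Logistic-regression probability** — a directed tie when a fitted
   logistic regression (nine email features per ordered pair: within-sender
   z-scores of logged sent volume, logged pair volumes with zero dummies,
   shared contacts, secondary ties, and per-channel asymmetry indices)
   assigns a tie probability strictly above a threshold.
3. **Ranked partners** — a directed tie from each person to their top-k
   email partners by total single-recipient exchange.

Each method's threshold is optimized by sweeping a grid and maximizing the
Pearson correlation between the candidate network's adjacency matrix and the
survey network's, vectorized over unordered pairs of a common node set.

Trait autocorrelation is estimated with a simultaneously autoregressive
(SAR) disturbance model,

```
y = Xβ + ε,   ε = ρWε + ν,   ν ~ N(0, σ²I)
```

with `W` a row-standardized adjacency matrix, fitted by maximum likelihood
(β and σ² profiled in closed form, ρ optimized on its spectral admissible
interval, standard errors from the numeric observed information). Models
are compared by AIC; `ρ` measures how strongly an individual's deviation
from the mean trait mirrors the average deviation of their network
neighbours.

Because real corporate email/survey/BMI data are proprietary, the package
ships a seeded synthetic-population generator
(`emailnet.synthetic`) that reproduces the statistical structure the
analysis assumes — a sparse clustered latent tie network, partial survey
response, Poisson pairwise email with lognormal sender activity and
asymmetric direction shares, and a trait with known autocorrelation — so
every stage is testable against ground truth.

## Worked example

Run the whole pipeline on a 300-person synthetic population:

```python
from emailnet.pipeline import RunConfig, run_full_analysis
from emailnet.synthetic import SyntheticConfig

cfg = RunConfig(
    synthetic=SyntheticConfig(n_people=300, target_tie_density=0.012, seed=7),
    output_dir="example_out", single_grid_steps=20,
)
bundle = run_full_analysis(cfg)
print(bundle.sar_comparison[["model", "aic", "rho", "n"]].round(3))
```

which prints (threshold sweeps first, then the BMI SAR comparison):

```
single_recipient: best_threshold=0.25 corr=0.869 density=0.0139 recovery=1.00 fp:tp=0.32
logistic:         best_threshold=0.08 corr=0.871 density=0.0139 recovery=1.00 fp:tp=0.31
ranked_partner:   best_threshold=2    corr=0.652 density=0.0138 recovery=0.75 fp:tp=0.74

           model      aic   rho   n
single_recipient 1519.981 0.362 259
        logistic 1520.218 0.360 259
  ranked_partner 1532.659 0.226 259
  name_generator 1535.301 0.202 259
```

Reading this: at their optimized thresholds the email networks recover
75–100% of the survey ties on this synthetic population, at roughly one
false-positive tie per three true ones. All four networks show positive BMI
autocorrelation (the generator planted ρ = 0.4 on the latent network); the
denser email constructions capture it better than the partially observed
survey network here, and AIC differences above 2 mark substantively
different fits. `example_out/` also receives the sweep tables, the
respondents-only robustness sweeps, the metric-association table (degree,
betweenness, closeness, eigenvector centrality, transitivity compared
across networks through two-weight-matrix autoregressive regressions),
edge lists/GraphML for every network, and threshold-diagnostic and
week-increment stability plots.

The same run is available from the shell:

```bash
emailnet report --synthetic --seed 7 --out example_out
emailnet simulate --seed 1 --out data/        # write synthetic CSVs
emailnet sweep --method ranked --grid 2:25 \
    --email-log data/email_log.csv --survey data/survey.csv
```

Runs on user data take three CSVs: an email log
(`sender_id,recipient_id,timestamp,n_recipients,file_size`, empty IDs =
external mail), a survey table (`respondent_id,named_id`) and a trait table
(`person_id,bmi`). `configs/default.yaml` holds a full default
configuration.

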