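# Methods

## Problem and design

The package addresses a measurement problem in workplace network
epidemiology: survey-based ("name generator") network maps are the
validated instrument for health-relevant social ties, but they are
incomplete — response rates near 50% are typical and named non-respondents
contribute only the ties their namers report. Email logs observe every
employee. The package therefore (i) constructs candidate social networks
from an email log under three distinct rules, (ii) calibrates each rule's
threshold against the survey network, and (iii) evaluates what each network
is good for: recovering survey ties, reproducing per-person structural
metrics, and carrying trait (BMI) autocorrelation.

## Network constructions

All three email constructions start from ordered-pair summaries of the
filtered log (external mail dropped; records kept only when at least one
endpoint responded to or was named in the survey; a multi-recipient message
to k people is k per-delivery records sharing one `n_recipients` value).

* **Single-recipient threshold.** Undirected tie when
  `(n_single(A→B)+n_single(B→A)) / window_weeks` is strictly greater than
  the threshold. Grid: 1 email/month (0.25/week) to 20/week, 40 log-spaced
  points.
* **Logistic probability.** A logistic regression predicts the survey tie
  label of every ordered pair that exchanged any email. Features follow the
  tie-prediction design: within-sender z-scores of logged sent volume per
  channel, logged pair totals (single, multiple, summed file size) each with
  a zero dummy, shared contacts, secondary ties, and per-channel asymmetry
  indices. Ties are fitted probability > threshold; grid 0.01 steps up to
  the fitted maximum. Directed, because features are asymmetric in the pair.
* **Ranked partners.** Each ego's partners are ranked by total two-way
  single-recipient exchange, descending, min/competition ranking; directed
  tie to every partner with rank ≤ k, grid k = 2..25.

Thresholds are strict (`>`) everywhere; rank inclusion is `≤ k`. Boundary
volumes therefore never create a tie, and equal volumes share the better
rank (deterministic and order-independent).

Sweeps are scored by the Pearson correlation of the two 0/1 pair vectors
over a common node set (individuals present in both the email data and the
survey network), with directed candidates union-symmetrized because the
reference network is undirected. Equal correlations break toward the
sparser network — conservative tie inference. The sweep table also records
tie density, the proportion of survey ties recovered, and false/true
positive diagnostics; a respondents-only view repeats everything on the
subset of survey respondents, where the reference ties are fully observed.

### Feature-engineering conventions

* `log(0)` is undefined; zero counts map to a transformed value of 0 with
  the matching dummy set to 1. The dummy absorbs the zero class, so any
  constant placeholder is equivalent up to the intercept.
* Sender z-scores use the sample (n−1) standard deviation over the sender's
  partners with positive counts in the channel; senders with fewer than two
  such partners, or zero variance, contribute z = 0. Zero-count partners are
  excluded from the sender's mean/sd and score z = 0 themselves (their
  information lives in the dummy).
* The asymmetry index `|T/2 − s| / (T/2)` is undefined when a channel is
  silent for the pair (T = 0); such rows carry 0 with the channel's zero
  dummy set — an interpretation, since the index's definition is silent here.
* "Emailed" for shared contacts means *sent* at least one email of either
  channel (active voice). "Secondary ties" counts all other individuals
  with more than one shared contact with the sender, whether or not the
  sender emailed them directly; the definition is ambiguous on that point
  and this reading is fixed and documented.
* A perfectly separable logit fails loudly rather than silently
  regularizing; an explicit L2-penalized IRLS fallback is available with a
  user-chosen strength (`logit_ridge`). The unpenalized fit itself goes
  through IRLS (GLM-Binomial), which tolerates the strong collinearity
  among the volume features.

## The SAR-disturbance model

Trait autocorrelation is modelled as

y = Xβ + ε, (I − Σ_k ρ_k W_k) ε = ν, ν ~ N(0, σ²I),

with each W a row-standardized adjacency: every ego distributes one unit of
influence over its out-ties, and isolates (zero rows) keep ε_i = ν_i — they
stay in the likelihood but contribute no autocorrelation, which is how
individuals with no ties are handled throughout. For the BMI analysis X is
an intercept only, so ρ expresses network-patterned deviation from the mean;
directed networks keep their direction there. Log-likelihood:

LL = −n/2·log(2πσ²) + log|det A| − ‖A(y − Xβ)‖² / (2σ²), A = I − Σ ρ_k W_k.

Estimation profiles β and σ² in closed form and maximizes the concentrated
likelihood over ρ:

* admissible ρ interval from the real spectrum of each W,
  (1/λ_min, 1/λ_max), intersected across matrices — this keeps A
  nonsingular throughout the search;
* single-W fits evaluate log|det A| as Σ log|1 − ρλ_i| from one
  eigendecomposition; multi-W fits use a dense `slogdet` per evaluation
  (exact, and desk-feasible at n ≈ 2000);
* single-ρ optimization is a 41-point coarse grid plus bounded scalar
  refinement; multi-ρ uses a coarse mesh with the best three points as
  Nelder–Mead starts, because the two-matrix likelihood can be flat or
  multimodal;
* standard errors come from a central-difference Hessian of the full
  likelihood at the optimum (observed information); z = ρ̂/se with normal
  p-values. Estimates landing on the admissibility boundary are flagged
  with a warning — this happens occasionally in the two-matrix metric
  regressions at small n, where one nuisance ρ is weakly identified; the
  slope of interest is unaffected.
* AIC = −2·LL + 2·(|β| + |ρ| + 1); differences ≤ 2 are flagged as
  equivalent model quality.

Row-standardized SAR ρ estimates are known to be biased downward at high
tie density; `density_guard` warns above density 0.15. All networks in the
default study conditions sit far below that.

Individuals missing the trait are dropped and W is re-standardized on the
survivors, mirroring the three-way intersection (email ∩ survey ∩ trait)
the BMI analysis uses.

## Egocentric metrics

Computed on the largest connected component of the undirected view of each
network (equal component sizes break toward the smallest node ID):

* degree; betweenness (fractional shortest-path counts, endpoints
  excluded); closeness as 1/(total shortest-path distance) — the standard
  computational convention, adopted deliberately even though closeness is
  often described verbally as an average distance, because the subsequent
  regressions are monotone-transform-sensitive and the inverse is what
  graph libraries compute; eigenvector centrality from a dense symmetric
  eigendecomposition (deterministic — no iterative-solver start vector),
  Perron vector scaled to max 1; transitivity as the local clustering
  coefficient, undefined (NaN) for degree ≤ 1.
* Degree, betweenness, eigenvector and transitivity are right-skewed and
  log-transformed as `log(x + ε)` with ε half the smallest positive value
  in the column (betweenness and eigenvector can be exactly 0 and no
  canonical offset exists; this choice is order-preserving and
  scale-aware). All five metrics are then z-scored.
* Cross-network agreement for a metric is the slope of a no-intercept
  regression of the survey metric on the email metric with SAR-disturbance
  errors adjusted by *both* row-standardized adjacencies (survey and that
  email network) — the two ρ's are nuisance parameters. The sample is the
  intersection of the two largest components (minus undefined-transitivity
  nodes for that metric only), and intervals are Wald ±1.96·se, labelled as
  such since the interval construction is otherwise unspecified.

## Synthetic populations

The generator produces the study conditions every test runs under:

* **Latent network**: stochastic block model, blocks of ~25, with 70% of
  expected ties within blocks, calibrated to the target density in
  expectation — clustered (transitivity > density) like real coworker
  networks. Default density 0.004 ≈ 4 ties/person at n = 1000, the sparse
  regime the survey reference network occupies.
* **Survey**: a fraction `response_rate` (default 0.47) respond; each
  respondent names each true neighbour independently with probability
  `naming_prob` (default 0.9), truncated at n_questions ×
  max_names_per_question = 20 names by sampling without replacement. The
  survey never invents ties; non-respondents appear only as named alters.
* **Email**: per ordered pair, single-recipient counts are Poisson over the
  window. Tied pairs share a total rate of 2 × `tied_email_rate_per_week`
  split across directions by a Beta(a, a) share (so the asymmetry features
  have nondegenerate support); untied pairs email at a faint base rate.
  Both are multiplied by a per-sender mean-1 lognormal activity multiplier
  with log-sd `volume_skew`, which produces the heavy right tail of
  per-person volume seen in real logs. Multi-recipient deliveries are an
  additional Poisson stream scaled so they form `multi_recipient_fraction`
  (default 0.59, the multi share of a realistic corporate log) of expected
  volume. Untied mail is drawn per sender and addressed uniformly, with
  deliveries landing on true neighbours discarded — Poisson thinning that
  leaves exactly the base rate per untied ordered pair. Timestamps are
  uniform over the window, which for a constant-rate Poisson process is
  distributionally identical to week-by-week generation.
* **Trait**: simulated from the SAR model on the *true* network
  (y = μ + (I − ρW)⁻¹ν), reflecting the premise that survey and email both
  partially observe one offline network. Defaults μ = 27.6, σ = 4.5 BMI
  units, ρ = 0.4.
* One `numpy` Generator seeded from the config drives everything, so equal
  configs give bit-identical populations and the pipeline report is
  byte-reproducible.

Defaults are desk-scale (n ≈ 1000, 22 weeks), not the multi-million-record
volumes of a real company-wide log. Rates were chosen once as realistic:
tied pairs exchanging ~4 single-recipient emails/week against a base rate
giving each person a few dozen incidental contacts over five months. The
generator models a single survey wave and stationary email rates; it does
not emulate vacation gaps, distribution lists, organizational hierarchy, or
reporting-line structure in who names whom. Passing tests therefore show
the estimators and the pipeline logic are correct under the assumed data
model, not that the thresholds found here transfer to any particular real
organization.

## Validation sizes

The heavier checks in the test suite run at sizes chosen to keep a
single-CPU run comfortable while leaving the assertions meaningful:
ρ-recovery uses 200 populations of n = 300 (tie density 0.015 so the mean
degree matches the n = 1000 default); the pipeline-level directional
properties use 8 full sweep replicates at n = 600 and 20 model-comparison
replicates at n = 600. Estimator-oracle equivalences run at n ≤ 12 (SAR),
200 rows (logit) and 200 random graphs of ≤ 8 nodes (metrics).

## Known limitations

* The tie-prediction logit is fitted and thresholded on the same survey it
  is later compared against; as in the original design, this is a
  calibration, not an out-of-sample validation.
* Multi-recipient counting is per delivered (sender, recipient) record; a
  k-recipient message contributes k pair deliveries.
* Weeks are consecutive 7-day bins from the first timestamp, not calendar
  weeks.
* The SAR implementation is dense; it targets populations up to a few
  thousand, not social-media-scale graphs.
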