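# Methods

## Setting and scope

The package analyses the quantitative side of a process evaluation run
alongside a stepped-wedge cluster randomised trial: a design in which
every cluster (here, a hospital catchment with one central and several
peripheral maternity facilities) starts under usual care and crosses
over to the intervention at one of a set of randomly allocated,
regularly spaced steps. The outcome scale throughout is a rare adverse
event count per delivery (order 10–300 per 10,000), recorded per
cluster-period cell. The implementation side is summarised by a small
set of per-cluster quantitative measures grouped into three domains —
fidelity (was the intervention delivered as intended, e.g. % staff
trained), reach (was the target population exposed, e.g. % women with a
blood-pressure measurement, equipment availability), adoption (routine
uptake, e.g. % clinical areas using the device at 6 months).

Qualitative process data, geography/referral-network structure and the
parent trial's full randomisation machinery are out of scope.

## Stepped-wedge simulation

`generate_design(n_clusters, n_steps, periods_per_step, seed)` allocates
clusters to steps by a seeded uniform permutation; when `n_clusters` is
not a multiple of `n_steps` the remainder is assigned round-robin
starting at the first step, so exactly the earliest steps carry an extra
cluster and the allocation of *which* cluster goes where stays uniform.
The grid spans `(n_steps + 1) * periods_per_step` periods: the first
block is all-control, and a cluster on step *s* is treated from period
`s * periods_per_step` on. The default footprint used in tests and the
acceptance experiments is 10 clusters crossing in 9 steps — one step
necessarily holds two clusters — over 10 or 20 periods.

`simulate_trial` draws deliveries per cell as Poisson around a
per-cluster mean (the real trial reports only monthly delivery means per
cluster, so Poisson is the minimal dispersion assumption; the mean is
configurable per cluster) and events as Binomial(deliveries, p) with

    logit p_ct = logit(base rate) + centre_effect_c + centre_trend_c * t
                 + log_OR * treated_ct.

Cells that draw zero deliveries are retained with zero events; they are
non-informative in the binomial likelihood rather than invalid.

Defaults: baseline event rate 0.01 (100 per 10,000 deliveries, mid-range
of the emulated trial's 39–324), 1,000 deliveries per cluster-period
(a scale at which the logistic asymptotics are comfortably valid while a
500-replicate experiment runs in seconds), zero centre effects and
trends unless set.

`simulate_implementation` gives each cluster a latent implementation
strength `s_c = -coupling * log_OR_c + N(0, noise_sd²)` (protective
effects map to high strength when `coupling > 0`) and emits six
proportion-scale measures across the three domains as logistic
transforms of the latent strength plus measure noise, one of them
declared `lower_is_better` to exercise direction handling. The adoption
measure is marked unavailable for the latest-crossing clusters, emulating
the right-censoring of 6-month reviews that a stepped-wedge rollout
produces. With `coupling = 0` the measures carry no effectiveness
signal — the null condition for meta-regression calibration. With all
noise at zero each measure is strictly monotone in the latent strength,
so the composite-score ordering equals the ordering by effect magnitude.

One integer seed drives everything, split into independent design /
trial / implementation streams via `numpy.random.SeedSequence.spawn`.

What the generator does *not* emulate: seasonality and other
non-linear secular trends, overdispersion of events beyond binomial
(no cluster-period random effects), referral-network structure, and
measurement error in the implementation measures' denominators. Passing
recovery tests therefore shows the estimators are correct under the
model they assume, not that the model captures every feature of real
trial data — in particular the real trial's own analysts noted
within-site variation and seasonal patterns beyond a linear trend.

## Effect measures

Odds ratios use the Woolf log standard error
`sqrt(1/a + 1/b + 1/c + 1/d)` and a 95% Wald interval on the log scale.
When any cell is zero the OR is undefined; with `continuity=True` the
Haldane–Anscombe correction adds 0.5 to *every* cell of such a table
(and only such a table). This matters in practice because
post-implementation coverage can reach 100%, where an OR does not exist
but a post/pre proportion ratio does. Proportion ratios are
scale-invariant in their inputs; when the underlying counts are supplied
the CI is the Katz log method, `se = sqrt(1/x1 - 1/n1 + 1/x0 - 1/n0)`.
Published per-site "OR" columns for coverage comparisons are in some
sources in fact post/pre proportion ratios (reproducible with Katz
intervals); the package implements both and labels each estimate by
`measure_kind` rather than guessing what a given source meant.

All computation is full precision; `round_half_up` exists only for
display, matching the half-up one-decimal convention of the source
tables, and is never fed back into a computation.

## Implementation-strength composite

Ranking is `scipy.stats.rankdata` (mid-rank ties) applied after sign
adjustment for each measure's declared direction of benefit, so rank 1
is always "best". Ranks rescale linearly to [0, 1] by
`(n − rank)/(n − 1)` — the minimal map onto the stated 0–1 range, with
ties landing on equal scores, the untied best at 1 and the untied worst
at 0. Domain scores are unweighted means over the cluster's available
measures in that domain; the composite is the unweighted mean over
available domains, with `n_domains_used` recorded. Missing measures and
missing domains are simply excluded from their means (a cluster must
have at least one available domain). Because every step is rank-based,
the composite is invariant to strictly monotone transformations of any
raw measure, and permuting cluster labels permutes scores identically.

Spearman correlation is computed as the Pearson correlation of
tie-averaged ranks; a constant vector is an explicit error, not NaN.

## Meta-analysis and meta-regression

Pooling uses the DerSimonian–Laird moment estimator:
`tau² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw))` with fixed-effect weights
`w_i = 1/se_i²`, then random-effects weights `1/(se_i² + tau²)`. When
`Q ≤ k−1`, tau² truncates at zero and the pool reduces exactly to
inverse-variance fixed-effect pooling. `I² = max(0, 100 (Q−(k−1))/Q)`.

Meta-regression estimates residual heterogeneity by the analogous moment
equation on the regression Q-statistic: with `W = diag(1/v_i)` and hat
matrix from the fixed-effect WLS fit,
`tau²_resid = max(0, (Q_E − (k − p)) / tr(P))`, `P = W − WX(X'WX)⁻¹X'W`,
followed by WLS with weights `1/(v_i + tau²_resid)`. Implementation was
cross-checked against R metafor (`rma(..., method="DL")`) and agrees to
10+ decimal places on a frozen fixture, including the Knapp–Hartung
variant (off by default: k is small in this setting and the plain Wald
interval is what moment-method meta-regression conventionally reports;
the flag is available where the extra small-sample conservatism is
wanted). The covariate is used on whatever scale it is supplied —
composite scores in [0, 1] give a slope per full unit of score.

The DL estimator was chosen over REML-type alternatives because it is
deterministic and closed-form, which makes the whole chain exactly
reproducible and unit-testable without an iterative inner loop.

## Cluster-period logistic fit

The site-level effect estimator is a binomial logistic regression on
cluster-period cells. Per-site fits use intercept + centred linear
period trend + treatment; the all-sites fit uses centre indicator
blocks with either centre-specific trends (`"pooled"`) or a shared trend
(`"pooled_common_trend"`) — both exposed because the appropriate trend
structure is a substantive choice. The trend covariate is centred at its
mean so trend and treatment coefficients are invariant to period
relabelling (only the intercept shifts), and the design is better
conditioned.

Optimisation is Newton–Raphson IRLS: score `X'(y − n·p)`, Hessian
`−X' diag(n p (1−p)) X`, step-halving whenever a full step would
decrease the likelihood, convergence at max |score| < 1e-8, hard cap 100
iterations. Coefficients beyond |15| in absolute value flag
(quasi-)separation — the likelihood flattens while coefficients diverge,
so the gradient criterion alone can be met spuriously; such fits are
returned with `converged=False` and `site_effect` refuses to package
them. Zero-event and zero-delivery cells are retained; no ad-hoc
dropping.

Multi-site marginal inference replaces an exchangeable-correlation GEE
with the independence working model plus cluster-robust sandwich
covariance `A⁻¹ (Σ_g s_g s_g') A⁻¹ · G/(G−1)`, where `s_g` sums score
contributions within cluster g. The point-estimate family is identical
to independence-working GEE and the sandwich is valid under arbitrary
within-cluster correlation; this avoids mirroring any particular GEE
implementation's defaults while keeping population-averaged
interpretation. With one group per cell the estimator reduces to the
heteroscedasticity-robust (HC-type) form.

Type-I-error calibration in the test suite uses the model-based Wald
test: under the generator, cells are independent binomials given the
centre effects, so the model-based variance is the correctly specified
one for that check. Cluster-robust standard errors with G = 10 and
normal critical values are known to be anti-conservative in small-G
settings; their behaviour is covered instead by the scaling-law and
well-specified-agreement tests.

## Descriptive summaries and pipeline

Context summaries are unweighted means per column over the clusters with
non-missing values, with the contributing-cluster count always emitted
(source tables do not always state which clusters feed which column).
Training coverage reports per-site percentages where workforce totals
are known, the total trained as a pure sum, and an overall percentage
over known totals only. Missing values in CSVs are empty fields;
sentinel strings are rejected by pandas parsing conventions.

`run_pipeline` chains simulate → score → per-site effects → pooled fit →
DL pool → meta-regression, writes every table as CSV, and emits a
manifest with the seed and SHA-256 hash of each file; identical
config+seed reproduces byte-identical outputs, and partial outputs are
removed on failure.

## Problem sizes in the standard experiments

The parameter-recovery experiment uses 200 replicates of a 10-cluster ×
20-period trial with 1,000 deliveries per cell, treatment log-OR
ln(0.7), centre effects in ±0.5 and trends in ±0.02 per period; the
null meta-regression calibration uses 500 replicates at 500 deliveries
per cell with baseline rate 0.02; the type-I error experiment uses 500
replicates of the 10-period design at 1,000 deliveries per cell. These
sizes give Monte-Carlo standard errors small enough to detect biases of
a few percent of the effect size while keeping a full run under a
minute on one CPU.

## Known limitations

- The per-site estimator conditions on a *linear* trend; strong
  seasonality aliases into the treatment contrast in a per-site fit and
  is not modelled.
- DL tau² is noisy at k = 10 sites; meta-regression CIs at that k are
  approximate (coverage in the null experiment is nominal under
  homogeneity, but genuinely heterogeneous effects with very unequal
  variances will degrade it). Knapp–Hartung is available but not default.
- The composite score has no weighting scheme and no latent-variable
  structure; domains with more measures are not up-weighted.
- Published per-site summary tables are bundled only to the precision
  they were printed at; percentages back-derived from them inherit that
  rounding.
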