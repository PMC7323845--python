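# Methods

## The estimation problem

A study table holds one row per invited parent–child dyad: identifiers,
site, child age and gender, parent gender, group-composition flags, seven
observational measurements coded before consent was requested (durations of
dyadic, supervised and unsupervised activity within a 300 s observation
window, in seconds; counts of pedagogical questions, information-seeking
questions, statements and commands), a participation status
(`not_invited | refused | consented_untested | tested`), and — for tested
dyads only — seven test measurements (total play time in seconds; for the
whole play period and the first minute each: target-function activation
(0/1), number of unique actions, number of non-target functions activated
out of 4).

The *participating* group comprises tested dyads; the *not-participating*
group defaults to refusers only, with consented-but-untested dyads excluded
from both (they can be pooled into not-participating by a config switch).
The quantity of interest is the bias of participant-only means and SDs
relative to the combined pre-consent population.

## Identifying assumption

Imputation of the non-participants' outcomes is licensed by missing at
random: conditional on the observational measurements, consent is assumed
uninformative about the would-be outcome. This is plausible when parental
practices, not the consent act itself, drive both consent and child
behaviour, but it is untestable from the observed data alone; the
false-missingness cross-validation checks only the machinery, not MAR
itself. The method additionally needs overlap: matched subsamples and
within-support interpolation require the two groups' covariate
distributions to overlap substantially.

## Consent model and propensity scores

Participation (tested = 1 vs refused = 0) is modelled by maximum-likelihood
logistic regression on the seven observational measurements (preset
`observational`; preset `extended` adds age, both genders, the composition
flags and a site code). Continuous predictors enter on their raw scale so
coefficients read as log-odds per unit; a config switch standardizes.
Convergence: relative log-likelihood tolerance 1e-10, 100 iterations.
On detected separation or non-convergence the fit is repeated with an L2
penalty λ = 1e-4 on slopes (never the intercept) and flagged; separation is
a realistic hazard at n ≈ 78 with seven predictors. Model fit is summarized
by Nagelkerke's R² = [1 − exp(2(ℓ₀ − ℓ₁)/n)] / [1 − exp(2ℓ₀/n)].
Propensity scores are the fitted probabilities; dyads missing a predictor
get a flagged NaN rather than failing the batch.

## Proper multiple imputation

Per test measurement, a predictive model is fitted on the participating
group with the seven observational measurements as predictors: OLS with the
unbiased residual variance (df = n − p − 1) for continuous and count
measurements, logistic regression for the binary ones. A constant binary
training outcome is imputed as that constant with a warning.

Each of the m = 100 runs draws, per gaussian measurement,
σ²\* = σ̂²·df/χ²(df), then β\* ~ N(β̂, σ²\*(XᵀX)⁻¹), then outcomes from
N(xᵀβ\*, σ²\*); binary measurements draw β\* ~ N(β̂, Σ̂) and then Bernoulli
outcomes. A plug-in variant (point estimates, residual noise only) is
exposed for tests and degenerate fixtures; a zero-residual model imputes
deterministically in both modes. Run k draws from the stream seeded by
`SeedSequence((master_seed, k))`, so run counts and memberships are
reproducible across implementations even though bit-streams are not.

Group statistics are computed on the raw model-scale draws. Clipping or
rounding draws before averaging would bias group means (for counts near
zero, by up to several hundredths of an SD), so out-of-range draws are only
*counted* (`n_clipped`), and `ImputedRun.postprocessed()` materializes valid
outcome records (counts ≥ 0, non-target ≤ 4, integers rounded, first-minute
counts capped at their whole-period values) for export and display.

## Reference ensembles

*Bootstrap groups*: uniform random subsets of the participating group,
without replacement (a subsample should be a committee of distinct
children), size-matched to the not-participating group, m runs.

*PSM groups*: greedy 1:1 nearest-neighbour matching on the logit of the
propensity score, without replacement; not-participating dyads are processed
in random order and distance ties are broken randomly, so the ensemble of m
runs varies in order and tie-breaks. No caliper by default; with a caliper
(in SD units of the logit scores) an exhausted match is an error, never a
silently smaller group — the design requires exact size match.

## Tests and pooling

Two inferential routes are reported side by side, deliberately labelled:

* **Ensemble tests** mirror the usual presentation of run ensembles with
  SE-across-runs error bars: a one-sample t of the m imputed run means
  against the empirical mean (and two-sample t's for PSM-vs-bootstrap and
  PSM-vs-imputed run means). Because the SE shrinks with 1/√m while the
  model-estimation error in the grand mean does not, this route is
  anti-conservative — under a zero-coupling generator its "significantly
  lower" flag fires at roughly 2–3× the nominal α.
* **Rubin's-rules tests** pool the per-run difference (imputed run mean −
  empirical mean) with total variance T = W̄ + (1 + 1/m)B and Barnard–Rubin
  small-sample df. In this design the imputation models are trained on the
  same participating group the difference is tested against, which makes
  even this route conservative (the dependence is ignored by T); under the
  zero-coupling generator its flag rate is near 0. Neither route is exactly
  α-calibrated; the Rubin route is the principled, non-anticonservative one
  and is the flag to act on.

Cohen's d between the empirical and imputed groups uses member-level values
with imputed members pooled across runs and the pooled (n−1-weighted)
within-group SD. No multiplicity correction is applied across the seven
measurements by default; a Holm flag is available.

Population estimates pool, per run, the n_p empirical with that run's n_np
imputed member values; the mean and SD of the combined n_p + n_np values are
averaged across runs and reported with both the run-to-run SD and the
SD/√m, plus a Rubin's-rules SE. Bias is the participant-only statistic minus
the population estimate, so positive mean bias is overestimation of
performance and negative SD bias is underestimation of individual
differences.

## False-missingness cross-validation

`round(fraction × level count)` participating dyads at a factor level
(default: half of the participating boys, mirroring a factor chosen to be
uncorrelated with outcomes) have their outcomes deleted; the masked view
structurally lacks them, so no fitting step can touch them. Imputation
models are refitted on the remaining participants, the masked outcomes
recovered over m runs, and (optionally) a pseudo-participation PSM run
against the masked group. The 95% interval of the simulated group mean is
the 2.5–97.5 percentile band of run means using the Weibull k/(n+1)
quantile convention — at m = 100 the default linear convention targets
roughly the 3rd/98th order statistics, whose prediction coverage is ~94%
rather than 95% — with a normal-approximation band reported alongside. SD
recovery is reported at both the run level (mean of per-run SDs) and the
member level (pooled draws), since either convention is defensible.

## Synthetic-data generator

The generator emulates the study table's statistical structure with
everything observable: covariates, a consent model, and latent outcomes for
every dyad.

* Durations: a 4-part Dirichlet composition (α = 2.0, 2.5, 1.5, 0.7) of the
  300 s window — dyadic, supervised, unsupervised, plus an *uncoded* share.
  The uncoded share keeps the three coded durations from summing exactly to
  the window; three shares summing to a constant would be perfectly
  collinear with the intercept of every downstream model, and live coding
  leaves gaps in any case.
* Communication counts: negative-binomial (gamma–Poisson) with means
  0.9 (pedagogical questions), 3.5 (information-seeking), 16 (statements),
  6 (commands) per 5 minutes and dispersions 1–4; configurable to Poisson.
* Consent: Bernoulli(inverse-logit), slopes 1.49 per pedagogical question
  and 1.47 for boys, the intercept solved analytically so the linear
  predictor at the covariate means equals logit(0.756); among consenters
  the test completes with probability 47/59. Consent uses only covariates
  and noise independent of the outcome noise, so MAR holds by construction.
* Outcomes: gaussian linear models in pedagogical questions (and dyadic
  time) with residual SDs of 60 s (total play time), 3 (unique actions) and
  1 (non-target functions, rounded and clipped to 0–4); target activation
  logistic in pedagogical questions. First-minute counts are binomial
  thinnings of whole-period counts (p = 0.55/0.6), which enforces
  first ≤ whole by construction; first-minute activation is whole-period
  activation thinned through a second logistic. The implied
  consenter–refuser gaps span d ≈ 0.1–0.25.
* Bookkeeping: each dyad carries its true consent probability and true
  conditional outcome means (pre-discretization for rounded/thinned
  measurements); `true_bias` reports ground-truth gaps and population
  moments from the latent outcomes.

What the generator does *not* emulate: within-dyad correlation between the
seven outcomes beyond their shared covariates, coder disagreement,
site-level effects, non-linear covariate effects, and any violation of MAR
(non-ignorable refusal). Passing calibration tests on this generator
therefore validates the machinery under MAR with correctly-specified-ish
models — it cannot certify MAR in real data.

## Numerical and reproducibility choices

Degenerate scales (zero SDs) raise errors naming the offending measurement;
Cohen's d of two identical constant groups is defined as 0. Rank-deficient
designs raise a collinearity error naming the aliased predictors. Every
stochastic stage derives child seeds from the master seed via fixed stage
tags (`SeedSequence((master_seed, tag, k))`), so the full pipeline, the
stage subcommands, and reruns are byte-identical given the seed; output
tables carry a version/seed header comment and the manifest holds the only
timestamp.

The test suite runs the statistical calibration studies at moderated sizes
chosen as its study conditions: 100 replicate populations of n = 500 with
m = 100 for null calibration and for sign/population recovery, 200
replicate cross-validation pipelines at n = 200, and paper-scale (n = 78)
fixtures elsewhere.

## Known limitations

* Univariate imputation ignores residual dependence among the seven
  measurements, so imputed runs can order first-minute and whole-period
  draws inconsistently (resolved only in the post-processed view);
  chained-equations or joint-model imputation would be the upgrade path.
* The Rubin-pooled comparison is conservative here because the imputation
  models are estimated from the comparison group itself; an honest exact
  test would need to model that dependence.
* Covariate missingness is handled by per-analysis complete-case exclusion;
  no covariate imputation is attempted.
* Sensitivity analysis for non-ignorable refusal (outcomes depending on
  consent given covariates) is out of scope.
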