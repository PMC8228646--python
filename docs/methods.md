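# Methods

This note documents the statistical model, the default settings and the
numerical choices behind `pneumolag`, and what the synthetic validation
does and does not establish.

## Record handling

Suspected-pneumonia admissions are identified from free-text reasons
for admission by case-insensitive substring screening: a record is kept
if it contains any of `monia`, `brpn`, `bpn`, `pcp` and none of `chem`,
`pneumothorax`, `asp` (exclusion wins, which is what removes aspiration
pneumonia despite its `monia` match). Matching is raw substring with no
tokenization — the screening terms are wildcarded fragments, and
whole-word matching would miss compounds like "bronchopneumonia".
Screening is idempotent and order-preserving.

A record missing its admission date but carrying a discharge date and a
length of stay (LOS, whole days) is recovered as
`admission = discharge − LOS` (LOS 0 ⇒ same-day). Records with a
discharge date but no LOS go to imputation; records with neither date
cannot be placed in the time series and are excluded. Resolved records
are aggregated to a contiguous daily series; days with no records count
zero admissions, and a gap in the meteorology inside the study window
is an error (never silently interpolated).

## Imputation

Missing LOS is multiply imputed by *proper* predictive mean matching:
each of `m` imputations draws regression parameters from their
approximate posterior (normal draw for the coefficients around the
complete-case least-squares fit, scaled inverse-χ² draw for the
residual variance), computes predictive means, and copies the observed
LOS of one of the `k = 5` nearest complete cases (type-1 matching:
drawn parameters for the targets, fitted parameters for the donors).
Five donors is the conventional default; matching on predictive means
keeps imputations in the observed support (non-negative integers) and
is robust to the collinearity among the calendar/weather predictors
(the posterior draw uses an eigen square root of the pseudo-inverted
normal matrix, so exactly collinear predictors are tolerated).
Defaults: `m = 20`, predictors = day of year, day of week, week, month,
year, season, and daily min/mean/max temperature and humidity. The
ambiguous predictor phrase "week month" in the source protocol is read
as the two predictors week and month. Each imputation has its own RNG
stream spawned from (master seed, imputation index), so enlarging `m`
never reshuffles earlier imputations.

Downstream estimates are pooled by Rubin's rules on the model's linear
predictor (log) scale, where approximate normality is most plausible:
pooled point = mean, pooled covariance = mean within-imputation
covariance + (1 + 1/m) × between-imputation covariance, with the
large-sample degrees of freedom (infinite when imputations agree
exactly). Pooling at the coefficient level — rather than pooling
predictions — is the standard reading and lets every downstream
quantity (RR surfaces, attributable fractions) be computed once from
the pooled fit.

## Splines and the crossbasis

The natural cubic spline basis is built from the clamped cubic B-spline
basis projected onto the null space of the second-derivative
constraints at the two boundary knots — dimension
`#internal knots + 1 (+1 with intercept)`, zero curvature at the
boundaries, and *linear* extrapolation beyond them (implemented as a
first-order Taylor expansion at the boundary, exact for a natural
spline). Linear extrapolation matters: exposure-shift scenarios push
the series beyond the observed range.

The crossbasis entry for day `t` and column `(i, j)` is
`Σ_{ℓ=0..L} B_x,i(x_{t−ℓ}) B_ℓ,j(ℓ)` with `L = 21` days. Defaults:
exposure knots at the 25th/50th/75th percentiles of the observed series
with boundaries at the min/max (the established convention when knots
are otherwise unspecified); lag basis a natural spline *with*
intercept and two internal knots equally spaced on the `log(1+lag)`
scale, reflecting richer structure at short lags. Both are
configurable, and all knot metadata is serialized with the matrix so a
prediction is reproducible bit-exactly. An unlagged exposure (DTR) is
the `L = 0` degenerate case with an intercept-only lag basis, so one
code path serves both. Rows with incomplete lag history are excluded
from the likelihood rather than zero-padded; padding would bias
early-period estimates.

## Likelihood and fitting

The ZINB likelihood uses the NB2 parameterization
(variance `μ + αμ²`) mixed with a logistic point mass at zero:
`log[π + (1−π)·NB(0)]` for zero days, `log(1−π) + log NB(y)`
otherwise. Zero-count terms are computed with `logaddexp`/`log1p`
throughout; a non-finite contribution raises naming the offending row.

Maximization is BFGS on `[θ, γ, log α]` with the analytic gradient
(digamma terms for the dispersion), initialized from a Poisson GLM for
`θ`, zeros for `γ`, and `α = 0.5` — a robust, reproducible start. If
the scaled gradient criterion (max |gradient|/n < 1e−4) is not met an
L-BFGS-B polishing pass runs; a still-unconverged fit is returned with
`converged=False` and a warning rather than raised. The covariance is
the inverse observed information, obtained by centered numerical
differentiation of the analytic gradient and inverted by truncated
eigendecomposition (relative threshold 1e−9). The truncation matters in
practice: the zero component can hit a boundary — e.g. a day-of-week
category whose inflation probability collapses to zero, its coefficient
diverging to −∞ — leaving the information singular along those
directions. The pseudo-inverse reports zero variance there instead of
letting the near-singularity contaminate the whole matrix; variances
for such collapsed directions are understated, but the rate-component
contrasts used for RR and AF are unaffected.

Separating structural zeros from negative-binomial zeros is weakly
identified when the mean count is ~1 and overdispersion is present;
this is intrinsic to zero-inflated models at this scale, not an
artifact of the optimizer, and it is why the zero component carries
only the low-dimensional terms (day of week, previous three days'
counts, optionally the Fourier pair). The Fourier pair defaults to
*both* components: the rate component on structural grounds, the zero
component because seasonality in the odds of any admission is plausible
and costs two parameters.

## Prediction and attribution

RR surfaces are pure contrast algebra (see README) with delta-method
intervals on the log scale and normal 95 % quantiles. Centering is a
group action: re-centering at `c₂` divides all RRs by the RR of `c₂`
under the old centre, which the tests verify to 1e−10. Default
exposure grid: 50 equally spaced points over the boundary range plus
the centre; lag-specific curves are reported at integer lags only
(daily data).

The backward attributable fraction for day `t` is
`1 − exp(−Σ_ℓ η(x_{t−ℓ}, ℓ))`, count-weighted into a total. Only the
rate-component coefficients enter: AF is defined on the relative-rate
scale, and the zero component is held fixed. Subrange AFs zero the
contributions of source days whose exposure falls outside the subrange
*on the day it occurred* — consistent with the backward formula's
attribution of risk to past exposures. Note the per-day AF is a
nonlinear (exponential) function of the summed contributions, so
subrange AFs add up to the total exactly only when no day's lag window
mixes subranges. Default subranges: below 14 °C / above 26 °C for mean
temperature, below 40 % / above 80 % for RH, above 20 °C for DTR; DTR
has no "low" component because its reference is the dataset minimum.
Scenario AFs displace the whole exposure series by a fixed shift
(defaults ±2 °C for temperature and DTR, ±5 % for RH) and recompute
under the unchanged coefficients, with the natural spline's linear
extrapolation covering values beyond the observed range. Empirical
95 % intervals are percentile intervals (not bias-corrected) over 1000
multivariate-normal draws of the term's coefficient subvector,
deterministic given the seed; a percentile interval need not contain
the point estimate, though it typically does.

## Synthetic ground truth

The generator emulates the study setting: a southern-hemisphere
station's daily weather (annual temperature sinusoid peaking in
mid-January with AR(1) noise, humidity seasonally in phase but
negatively coupled to temperature residuals and clipped to [5, 100] %,
diurnal range widest in the dry winter), pushed through a known
exposure-lag-response model to counts averaging ≈1.3/day with ≈40 %
zero days over an eight-year span (≈4000 admissions), then exploded
into raw records with decoy diagnoses and the two missingness
mechanisms (34.3 % of records lose their admission date, tilted by
temperature so the mechanism is missing-at-random; half of those also
lose LOS; 4.5 % lose both dates).

Truth surfaces are rank-1 (exposure curve × decaying lag kernel) with
the directions reported for this setting — cold harmful with a lag,
heat protective, low humidity harmful, wide DTR harmful same-day — and
evaluate to zero at the centering values so true RR(centre) = 1 in
closed form. By default both factors are *projections onto the same
natural-spline spaces the model fits* (fixed knots, exported as
`TRUTH_SPECS`), so recovery tests are free of approximation bias; a
`misspecified` flag swaps in a rich-spline projection of a raw
quadratic × exponential-decay surface outside the fitted span for
robustness experiments.

What passing tests therefore show: the estimator recovers a truth of
the assumed form at the study's scale and noise level, with correctly
calibrated Wald intervals, and every algebraic identity of the
prediction/attribution layer holds exactly. What they do not show:
robustness to real-data features the generator omits — epidemic
outbreaks beyond the 3-day autoregressive device, measurement error in
the weather station, reporting artifacts (holiday backlogs), secular
changes in admission practice, or confounding by unmeasured covariates.

## Problem sizes and tolerances in the test suite

Structural oracles (crossbasis double loop, per-observation likelihood)
are exact to 1e−10. Parameter recovery uses one 3100-day study
(cumulative log-RR at probe exposures within 3 standard errors of
truth) and 200 replicates of 822 days with a compact crossbasis for
Wald coverage (95 % ± 5 points); imputation coverage uses 100
replicates of 400 records at 30 % MAR missingness with `m = 20`. These
sizes keep the full suite around a quarter of a minute while leaving
the Monte-Carlo error well inside the asserted bands. The pipeline
smoke tests run ~300-day studies with `m = 2` and 50 Monte-Carlo draws.

## Known limitations

* Age/sex are deliberately not modelled or imputed: in this setting
  their missingness is not plausibly at random.
* No penalized splines, B-spline/threshold exposure alternatives, or
  automatic knot selection; knots are configuration.
* Forward-perspective per-day AF series are not produced; scenario
  analysis is the shifted-distribution recomputation.
* The ZINB zero component is weakly identified at ~1 admission/day;
  interpret its coefficients (and their truncated variances) with care.
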