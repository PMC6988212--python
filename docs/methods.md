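# Methods

## Model

Aggregated counts are arranged as cells on the Lexis plane: one row per
(age, period) combination with the number of cases and the number surveyed.
Age and period are treated as **cell midpoints in continuous years** — a
5-year age band 45–49 enters as 47.5, a 2014–15 survey as 2014.5 — and
birth cohort is always derived as `cohort = period − age`, never stored
independently, so the three scales cannot drift apart. All year arithmetic
is floating point; nothing is truncated to integers.

Counts are modelled as Poisson with a log link and an offset equal to the
log of the number surveyed, so the linear predictor is a log rate and
exponentiated contrasts are rate ratios. The likelihood includes the
`log(y!)` constant; reported log-likelihoods are therefore absolute.
Zero-case cells are ordinary observations. The Poisson-for-prevalence
approximation is standard in this setting and matches the models this
package is meant to reproduce; a binomial variant is deliberately out of
scope.

The model assumes independent cells. For longitudinal designs in which the
same people are re-surveyed, this is wrong in a known direction
(variability is underestimated); `fit(..., scale="pearson")` optionally
inflates the covariance by the Pearson dispersion as a labelled extension,
but no correlation structure is modelled.

## Spline basis

Each time-scale effect is a restricted (natural) cubic spline built from
the truncated-power basis: the linear function plus, for each knot
`t_j (j ≤ K−2)`, a combination of `(x−t)₊³` terms normalised by
`(t_K−t_1)²`. The span is cubic between knots, C² everywhere and linear
beyond both boundary knots, which keeps tail behaviour and extrapolation
tame. Any basis spanning the same space gives the identical fit, so tests
assert fit-level invariants rather than coefficient values.

Knots default to **equal spacing over the observed range**, boundary knots
at the observed min/max; quantile placement is available
(`place_knots_quantile`) for heavily skewed layouts. Defaults are 5
internal knots for age and 4 each for period and cohort — few enough to
avoid overfitting aggregated tables, equal for the two temporal scales so
their curvature budgets are comparable.

## Identifiability constraints

Because `cohort = period − age` exactly, constants and a linear drift can
be traded freely among the three functions. Three constraints pin the
decomposition down:

1. the age block carries the intercept (absolute rates);
2. the drift-bearing temporal basis (period under APC, cohort under ACP)
   is centered at a reference year, column by column, so any fitted
   combination is exactly zero there;
3. the residual temporal basis is detrended: `B* = B − X(XᵀWX)⁻¹XᵀWB` with
   `X = [1, t]`, which annihilates the linear column exactly (it is then
   dropped) and leaves columns with zero weighted mean and zero weighted
   least-squares slope over the observed records.

The exact collinearity is broken only because the residual block retains
nothing linear; the assembler verifies full column rank and aborts naming
the offending block rather than silently dropping columns.

**Detrending weights.** The projection weights default to the per-cell
number surveyed, mirroring the offset's role as exposure; `none` and
`cases` are provided. This is the largest genuinely open choice in the
construction — the zero-mean/zero-slope statement is always relative to a
weighting — and it is surfaced in the API and the CLI
(`--detrend-weights`). Detrending is computed over records, which equals
value-level detrending under frequency weights.

**References** default to survey-size-weighted medians of period and birth
year (the conventional anchor choice), overridable everywhere.

Both schemes span the same 16-dimensional column space (with default
knots: 1 intercept + 6 age + 5 centered temporal + 4 detrended temporal),
so APC and ACP fits agree in likelihood and fitted values to numerical
precision; this is asserted at 1e−6 in the tests. Reduced models (A+C,
A+P) keep the single temporal function centered at its reference — it
necessarily carries the drift. Their design-column deficit relative to the
full model (4 with default knots) is what the deviance tests use for
degrees of freedom; df is always computed from the assembled designs, not
hard-coded.

Drift is not reported as a named coefficient; it lives in the linear
component of the centered drift-bearing basis.

## Fitting

IRLS with the working response of the canonical log link, each weighted
least-squares step solved by QR of the weighted design (no normal
equations). Start values: intercept = log(total cases / total surveyed),
all else zero — robust for these well-conditioned aggregated problems.
Convergence: relative deviance change below 1e−8 (cap 100 iterations),
followed by one extra polishing step so the reported optimum has a
numerically vanishing score; non-convergence is flagged on the model, not
raised. The covariance `(XᵀWX)⁻¹` is formed once at convergence from the
final R factor. With an intercept, total fitted equals total observed
cases (canonical-link property); the tests check this at 1e−6 relative.

## Effect curves and intervals

Curves are evaluated by replaying each block's transformation on the
requested grid: raw basis plus intercept for age, reference-centered basis
for the drift-bearing function, stored projection matrix for the residual
function. Consequently, at the observed cells,
`age-rate × drift-bearing RR × residual RR × denom` reproduces every
fitted count exactly (asserted at 1e−6 relative), and the product is
scheme-invariant even though the factors are not.

Confidence bands are pointwise Wald intervals on the log scale with
z = 1.959964; the age band uses the full intercept+age covariance
sub-block. Simultaneous bands are out of scope. Default grids are 200
equally spaced points per observed range with the reference inserted
exactly (the anchor point then shows rate ratio 1 with a degenerate
interval, as it must). Grid points beyond the boundary knots are linear
extrapolations; they are emitted with an `extrapolated` flag rather than
suppressed.

## Lexis reshaping and exploratory panels

`lexis_reshape` pools cells into synthetic birth cohorts:
bin = `floor((cohort − origin)/width)` with origin at the earliest birth
year, counts summed within (bin, age), the pooled cell's cohort set to the
survey-size-weighted mean birth year of its members and its period
recovered as cohort + age so the Lexis identity survives pooling. The
operation conserves totals and is idempotent when the bin width matches
the data's native cohort granularity.

The four exploratory tables (prevalence by age per period, by period per
age band, by age per cohort, by cohort per age band) carry group keys,
prevalence and cell denominators. Cohort quartiles use inverted-CDF
weighted quantiles, weighting each cell by its number surveyed by default
(unweighted available). Duplicate (age, period) rows in input are pooled
by summing, with a warning, so stratified tables can be merged.

## Synthetic-data generator

The generator exists to validate the estimator, with truth known by
construction. The documented default scenario is shaped like the adult
obesity epidemiology that motivates the package, with smooth closed-form
effects:

- age: quadratic on the log scale peaking at 60, `−(a−60)²/1500`;
- cohort: `0.010·(c−1951) + 0.12·softplus((c−1962)/10)` — steady rise with
  a smooth acceleration for birth years after the early 1960s;
- period: gentle linear drift `0.004·(p−2007)`;
- baseline log rate `log 0.13`; implied rates stay within ≈0.03–0.33.

Layouts: cross-sectional (40 ages spanning 20–79 at eight 3-yearly surveys
1996–2017, emulating a national survey series) or longitudinal (four fixed
birth-year bands observed at successive surveys, ages derived as
period − cohort). Per-cell Poisson draws use substreams keyed by
(seed, age, period), so enlarging a grid never reshuffles existing cells;
draws exceeding the denominator are truncated with a warning. Scenarios
whose rates exceed 1 are rejected before sampling; rates above 0.5 warn as
implausible prevalences. Binomial sampling is available to exercise mild
misspecification of the Poisson likelihood.

What the generator does **not** emulate: within-person correlation across
surveys, attrition, self-report measurement error, survey weighting, and
sampling-frame drift. Passing recovery tests therefore demonstrate the
estimator's correctness under its own assumptions, not robustness to those
real-data features.

**Recovery metric.** Truth is only identified up to the constraints, so
before comparison the true functions are pushed through the model's own
transformation: the true residual-variable function is split by weighted
least squares (same weights, same records) into constant + slope +
residual, the slope is reallocated via the Lexis identity to the
drift-bearing and age functions, the drift-bearing function is re-anchored
at the model's reference, and constants are absorbed into the age
function. Errors are max/mean absolute differences on the log scale at the
distinct observed values (never extrapolated). At 100 000 per cell on the
default grid the max log-scale error per curve is ≈0.005 — the acceptance
tests assert < 0.05.

## Problem sizes and numerical choices

Tests and the acceptance script run the default 320-cell grid (12×6 for
quick checks) with denominators of 10³–10⁵; IRLS converges in 4–6
iterations and a full three-model fit takes milliseconds, so the entire
validation is a few seconds of compute. Tolerances: deviance convergence
1e−8; constraint identities asserted at 1e−8 (log scale) and fit
invariance at 1e−6; the chi-squared tail is computed via the regularized
upper incomplete gamma and cross-checked in the tests against an
independent series/continued-fraction implementation at 1e−10.

## Known limitations

- First-order (linear) temporal information is irreducibly
  convention-dependent; only curvature is constraint-free. Interpretation
  of the drift-bearing curve must always reference its scheme.
- Independence of cells is assumed; see the dispersion note above.
- AIC/BIC conventions differ across software (total vs per-observation);
  both are emitted, and comparisons across packages should match
  conventions before comparing numbers.
- No covariates, interactions, projections, smoothing-spline penalties, or
  hierarchical APC variants.
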