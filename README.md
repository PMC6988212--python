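# apcspline

Flexible age–period–cohort (APC) modelling of aggregated prevalence data
with restricted cubic splines.

## The problem

Temporal change in a population health outcome — the running example is the
prevalence of obesity (BMI ≥ 30 kg/m²) among adult women — can be driven by
**age** at observation, by calendar time of observation (**period**, e.g. a
tax or a change in the food supply affecting everyone at once), or by
generation (**cohort**, e.g. lifestyles formed early in life travelling with
a birth year). Separating the three matters for prevention and forecasting,
but they are exactly collinear:

```
cohort = period − age
```

so any linear trend ("drift") can be attributed to period or to cohort at
will. Categorical APC models spend many parameters and give unstable,
convention-dependent answers. `apcspline` instead treats all three time
scales as continuous and models each with a restricted (natural) cubic
spline inside a Poisson rate model, making the second-order (non-linear)
effects identifiable and the whole decomposition interpretable through
explicit, documented constraints.

## The model

For aggregated cells with `cases` of `denom` people at continuous age *a*
and survey year *p* (birth year *c = p − a*), the number of cases is
Poisson with

```
log E[cases] = f_A(a) + f_T(t) + f_R(r) + log(denom)
```

where each `f` is a linear combination of restricted-cubic-spline basis
functions (cubic between knots, twice continuously differentiable, linear
beyond the boundary knots; by default 5 equally spaced internal knots for
age and 4 each for period and cohort so the temporal effects are treated
symmetrically). Three constraints make the decomposition unique:

1. **age** carries the intercept, so `exp(f_A)` is an absolute
   age-specific rate;
2. the **drift-bearing** temporal function (period under the *APC*
   parameterization, cohort under *ACP*) is anchored to 0 at a reference
   year, so `exp(f_T)` is a rate ratio relative to that year and absorbs
   the drift;
3. the **residual** temporal function (cohort under APC, period under ACP)
   is detrended — projected, weighted by the numbers surveyed, orthogonal
   to constant and linear functions of its variable — so `exp(f_R)` is a
   residual rate ratio with zero weighted mean and slope.

The scheme changes the displayed curves, never the fit: APC shows
cross-sectional age-specific rates at the reference year; ACP shows the
longitudinal ("biological") age effect for the reference cohort. References
default to survey-size-weighted medians. Period-vs-cohort evidence is
weighed by fitting the full model and the two reduced models (A+C, A+P) and
referring the deviance, −2Δlog-likelihood, to a chi-squared distribution.

The package also ships Lexis reshaping of repeated cross-sectional surveys
into synthetic birth cohorts, the four conventional exploratory prevalence
panels, delta-method 95% confidence bands on every curve, and a
synthetic-data generator with known truth for validation.

## Worked example

Simulate an obesity-like truth (age effect peaking near 60, accelerating
cohort effect, nearly flat period effect) on a 40-age × 8-survey grid with
10 000 women per cell, then fit and compare the three models:

```python
import numpy as np
import apcspline as aps
from apcspline.modelcmp import comparison_table

scn = aps.default_scenario(denom_per_cell=10_000, seed=42)
ds = aps.simulate(scn)
knots = aps.default_knots(ds)               # age: 5 internal knots; period/cohort: 4
scheme = aps.default_scheme(ds, "APC")      # refs: weighted medians 2005.0, 1956.3

full = aps.fit(aps.assemble_design(ds, knots, scheme))
ac = aps.fit(aps.assemble_two_term_design(ds, knots, scheme, "cohort"))
ap = aps.fit(aps.assemble_two_term_design(ds, knots, scheme, "period"))
print(comparison_table({"A+P+C": full, "A+C": ac, "A+P": ap}, "A+P+C").round(4))
```

```
model  aic_per_obs       aic       bic     loglik  n_params  n_obs  deviance   df  p_value
A+P+C       9.9930 3197.7655 3258.0587 -1582.8828        16    320       NaN <NA>      NaN
  A+C       9.9823 3194.3452 3239.5651 -1585.1726        12    320    4.5797    4   0.3332
  A+P      10.6062 3393.9927 3439.2125 -1684.9963        12    320  204.2271    4   0.0000
```

Read: dropping the cohort term (A+P row) costs deviance 204.2 on 4 df —
overwhelming evidence of a cohort effect — while dropping the period
residual (A+C row) costs only 4.6 (p = 0.33), exactly the structure the
generator put in. Effect curves with 95% bands:

```python
curves = aps.effect_curves(full)
age = curves["age_rates"]
i = np.argmin(np.abs(age.grid - 60))
print(f"rate at age 60: {age.estimate[i]:.4f} [{age.lower[i]:.4f}, {age.upper[i]:.4f}]")
# rate at age 60: 0.1259 [0.1244, 0.1274]

rep = aps.recovery_report(scn, full)        # truth vs fit, on the log scale,
print(rep.to_dict())                        # after the constraint transformation
# max abs log errors ~ 0.007 (age), 0.007 (period), 0.010 (cohort)
```

Every fitted curve is within about 1% on the log scale of the
constraint-transformed truth at this sample size.

The same pipeline from a shell:

```sh
apcspline simulate --seed 42 --out data.csv
apcspline fit --input data.csv --scheme both --out results/
apcspline panels --input data.csv --cohort-quartiles --out panels/
```

`fit` writes per-curve CSVs, a four-panel figure (APC and ACP displays),
the model-comparison table and a JSON manifest; every output echoes the
resolved knots, references and scheme in its header.

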