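"""Fit statistics and nested-model comparison.

Provides the likelihood machinery used to weigh period against cohort
effects: the deviance of a reduced model against the full age+period+cohort
model, -2 x (difference in maximized log-likelihood), referred to a
chi-squared distribution on the difference in parameter count, plus AIC and
BIC in both the textbook and the per-observation conventions (some software
reports AIC/n, which is why both are always emitted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaincc

from .exceptions import ValidationError
from .poisson_glm import FittedAPCModel


def chi2_sf(x: float, k: int) -> float:
    """Upper-tail probability of the chi-squared distribution.

    Computed as Q(k/2, x/2), the regularized upper incomplete gamma
    function; monotone decreasing in x, exactly 1 at x = 0.
    """
    if x < 0:
        raise ValidationError(f"chi-squared statistic must be >= 0, got {x}")
    if k < 1:
        raise ValidationError(f"degrees of freedom must be >= 1, got {k}")
    return float(gammaincc(k / 2.0, x / 2.0))


def compare_nested(loglik_full: float, loglik_reduced: float,
                   df_diff: int) -> tuple[float, float]:
    """Deviance and p-value of a reduced model against a nesting full model.

    deviance = -2 (loglik_reduced - loglik_full); the p-value is the
    chi-squared upper tail at ``df_diff`` degrees of freedom.  A reduced
    log-likelihood that exceeds the full one by more than numerical noise
    triggers a warning (the models are then not nested, or one fit failed);
    tiny violations are clipped to deviance zero.
    """
    if df_diff < 1:
        raise ValidationError(f"df_diff must be >= 1, got {df_diff}")
    if loglik_reduced > loglik_full + 1e-9:
        warnings.warn(
            f"reduced model log-likelihood ({loglik_reduced:.6f}) exceeds "
            f"the full model's ({loglik_full:.6f}); check nesting",
            stacklevel=2)
    deviance = -2.0 * (loglik_reduced - loglik_full)
    p_value = chi2_sf(max(deviance, 0.0), df_diff)
    return deviance, p_value


@dataclass
class FitStats:
    """Information criteria for one fitted model.

    ``aic``/``bic`` follow the textbook definitions 2k - 2l and
    k ln(n) - 2l; the ``*_per_obs`` variants divide by the number of
    aggregated cells.  ``deviance_vs`` is filled when the model has been
    compared against a nesting reference.
    """

    label: str
    loglik: float
    n_params: int
    n_obs: int
    aic: float
    aic_per_obs: float
    bic: float
    bic_per_obs: float
    overparameterised: bool = False
    deviance_vs: dict | None = None

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("label", "loglik", "n_params", "n_obs", "aic", "aic_per_obs",
              "bic", "bic_per_obs", "overparameterised")}
        if self.deviance_vs is not None:
            d["deviance_vs"] = dict(self.deviance_vs)
        return d


def fit_stats(model: FittedAPCModel, label: str = "",
              reference: FittedAPCModel | None = None,
              reference_label: str = "") -> FitStats:
    """Information criteria for a fit, optionally compared to a full model."""
    if not model.converged:
        raise ValidationError("fit statistics require a converged model")
    ll, k, n = model.loglik, model.n_params, model.n_obs
    aic = 2.0 * k - 2.0 * ll
    bic = k * np.log(n) - 2.0 * ll
    stats = FitStats(label=label, loglik=ll, n_params=k, n_obs=n,
                     aic=aic, aic_per_obs=aic / n,
                     bic=bic, bic_per_obs=bic / n,
                     overparameterised=n <= k)
    if stats.overparameterised:
        warnings.warn(f"model {label!r} has n_obs <= n_params", stacklevel=2)
    if reference is not None:
        df_diff = reference.n_params - model.n_params
        deviance, p = compare_nested(reference.loglik, ll, df_diff)
        stats.deviance_vs = {"reference": reference_label,
                             "deviance": deviance, "df": df_diff,
                             "p_value": p}
    return stats


def comparison_table(models: dict[str, FittedAPCModel],
                     full_label: str) -> pd.DataFrame:
    """Side-by-side fit statistics with deviances against the full model.

    ``models`` maps display labels (e.g. "A+P+C", "A+C", "A+P") to fits of
    the same data; every model other than ``full_label`` is compared to the
    full one.  p-values are carried at full precision; round for display.
    """
    if full_label not in models:
        raise ValidationError(f"full model {full_label!r} not among "
                              f"{sorted(models)}")
    full = models[full_label]
    rows = []
    for label, model in models.items():
        ref = full if label != full_label else None
        s = fit_stats(model, label=label, reference=ref,
                      reference_label=full_label)
        row = {"model": label, "aic_per_obs": s.aic_per_obs, "aic": s.aic,
               "bic": s.bic, "loglik": s.loglik, "n_params": s.n_params,
               "n_obs": s.n_obs,
               "deviance": np.nan, "df": pd.NA, "p_value": np.nan}
        if s.deviance_vs is not None:
            row["deviance"] = s.deviance_vs["deviance"]
            row["df"] = s.deviance_vs["df"]
            row["p_value"] = s.deviance_vs["p_value"]
        rows.append(row)
    return pd.DataFrame(rows)
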