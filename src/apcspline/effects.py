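"""Effect curves with 95% confidence bands from a fitted model.

Under either constraint scheme the fitted log rate decomposes additively
into three displayed functions:

- the **age curve**, exp(intercept + age-spline), read as absolute
  age-specific rates at the reference year (APC) or for the reference
  cohort (ACP), with the intercept's uncertainty and its covariance with
  the age coefficients folded into the band;
- the **drift-bearing curve**, a rate ratio relative to the reference year
  of the period (APC) or cohort (ACP) function, exactly 1 at the reference;
- the **residual curve**, the detrended rate ratio of the other temporal
  variable, whose log has weighted mean and slope zero over the data.

Their product times the number surveyed reconstructs every fitted count
exactly, so the curves are a faithful multiplicative decomposition, not a
post-hoc smoothing.  Confidence bands are pointwise Wald intervals on the
log scale (z = 1.959964); grid points beyond the boundary knots are linear
extrapolations and are flagged, not suppressed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .poisson_glm import FittedAPCModel, predict_linear
from .rcs import rcs_basis

Z95 = 1.959964
DEFAULT_GRID_POINTS = 200


@dataclass
class EffectCurve:
    """One displayed effect: grid, point estimate and 95% band.

    ``estimate`` is a rate per person for the age curve and a rate ratio
    for the temporal curves.
    """

    variable: str                 # age | period | cohort
    role: str                     # age_rates | drift_bearing | residual
    grid: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    extrapolated: np.ndarray
    scheme: "ConstraintScheme"
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "grid": self.grid,
            "estimate": self.estimate,
            "lower": self.lower,
            "upper": self.upper,
            "extrapolated": self.extrapolated.astype(int),
        })


def _default_grid(values: np.ndarray, n: int, include=None) -> np.ndarray:
    grid = np.linspace(float(values.min()), float(values.max()), n)
    if include is not None and not np.any(grid == include):
        grid = np.sort(np.append(grid, include))
    return grid


def effect_curves(model: FittedAPCModel, grids: dict | None = None,
                  n_grid: int = DEFAULT_GRID_POINTS) -> dict[str, EffectCurve]:
    """Compute the displayed curves for a fitted model.

    ``grids`` optionally maps variable names to evaluation grids; defaults
    are ``n_grid`` equally spaced points over each observed range, with the
    drift-bearing reference inserted so the anchor point is always shown.
    Returns a dict keyed by role (``age_rates``, ``drift_bearing`` and,
    for the full three-effect model, ``residual``).
    """
    if not model.converged:
        raise ValidationError("model did not converge; curves would be "
                              "unreliable")
    design = model.design
    scheme = design.scheme
    data = design.data
    grids = dict(grids or {})
    out: dict[str, EffectCurve] = {}

    # -- age: absolute rates, intercept included ------------------------------
    age_knots = design.knots["age"]
    agrid = np.asarray(grids.get("age", _default_grid(data.ages, n_grid)),
                       dtype=float)
    if agrid.size == 0:
        raise ValidationError("age grid is empty")
    rows = np.column_stack([np.ones_like(agrid),
                            rcs_basis(agrid, age_knots).values])
    est, se = predict_linear(model, rows, blocks=("intercept", "age"))
    out["age_rates"] = _curve("age", "age_rates", agrid, est, se,
                              age_knots, scheme, data.label)

    # -- drift-bearing temporal curve -----------------------------------------
    dvar = scheme.drift_variable
    dknots = design.knots[dvar]
    dvals = data.frame[dvar].to_numpy()
    dgrid = np.asarray(grids.get(dvar, _default_grid(
        dvals, n_grid, include=scheme.drift_reference)), dtype=float)
    if dgrid.size == 0:
        raise ValidationError(f"{dvar} grid is empty")
    ref_row = rcs_basis([scheme.drift_reference], dknots).values[0]
    rows = rcs_basis(dgrid, dknots).values - ref_row
    est, se = predict_linear(model, rows, blocks="drift_bearing")
    out["drift_bearing"] = _curve(dvar, "drift_bearing", dgrid, est, se,
                                  dknots, scheme, data.label)

    # -- residual temporal curve (three-effect designs only) ------------------
    if design.detrended is not None:
        rvar = scheme.residual_variable
        rknots = design.knots[rvar]
        rvals = data.frame[rvar].to_numpy()
        rgrid = np.asarray(grids.get(rvar, _default_grid(rvals, n_grid)),
                           dtype=float)
        if rgrid.size == 0:
            raise ValidationError(f"{rvar} grid is empty")
        rows = design.detrended.evaluate(rgrid)
        est, se = predict_linear(model, rows, blocks="residual")
        out["residual"] = _curve(rvar, "residual", rgrid, est, se,
                                 rknots, scheme, data.label)
    return out


def _curve(variable, role, grid, est, se, knots, scheme, label) -> EffectCurve:
    lo, hi = knots.boundary
    return EffectCurve(
        variable=variable, role=role, grid=grid,
        estimate=np.exp(est),
        lower=np.exp(est - Z95 * se),
        upper=np.exp(est + Z95 * se),
        extrapolated=(grid < lo) | (grid > hi),
        scheme=scheme, label=label,
    )


def _csv_header(curve: EffectCurve, multiplier: float) -> str:
    s = curve.scheme
    return ("# apcspline effect curve\n"
            f"# label={curve.label}\n"
            f"# role={curve.role} variable={curve.variable}\n"
            f"# scheme={s.scheme} ref_period={s.ref_period} "
            f"ref_cohort={s.ref_cohort}\n"
            f"# display_multiplier={multiplier}\n")


def write_curve_csv(curve: EffectCurve, path, multiplier: float = 1.0) -> None:
    """One curve to CSV (grid, estimate, lower, upper, extrapolated).

    The header comment block echoes scheme and references so every file is
    self-describing; ``multiplier`` rescales rate-type curves for display
    (e.g. per 100 people) and is recorded in the header.
    """
    frame = curve.to_frame().sort_values("grid")
    if curve.role == "age_rates" and multiplier != 1.0:
        for col in ("estimate", "lower", "upper"):
            frame[col] = frame[col] * multiplier
    with open(path, "w") as fh:
        fh.write(_csv_header(curve, multiplier))
        frame.to_csv(fh, index=False)


def read_curve_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def panel_export(curves: list[EffectCurve], outdir,
                 multiplier: float = 1.0, stem: str = "effects",
                 figure: bool = True) -> dict[str, str]:
    """Write CSVs per curve and the combined four-panel display figure.

    The canonical layout pairs, per scheme, the absolute age-rate panel with
    a panel overlaying the drift-bearing and residual temporal curves:
    top row APC (age rates at the reference year; period-with-drift beside
    the detrended cohort), bottom row ACP (age rates for the reference
    cohort; cohort-with-drift beside the detrended period).  All curves must
    come from fits of the same dataset.
    """
    if not curves:
        raise ValidationError("no curves to export")
    labels = {c.label for c in curves}
    if len(labels) > 1:
        raise ValidationError(
            f"curves come from different datasets: {sorted(labels)}")
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    for c in curves:
        name = f"{stem}_{c.scheme.scheme}_{c.role}.csv"
        path = os.path.join(outdir, name)
        write_curve_csv(c, path, multiplier=multiplier)
        paths[f"{c.scheme.scheme}:{c.role}"] = path

    if figure:
        paths["figure"] = _panel_figure(curves, outdir, stem, multiplier)
    return paths


def _panel_figure(curves, outdir, stem, multiplier) -> str:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    by = {(c.scheme.scheme, c.role): c for c in curves}
    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    for row, sch in enumerate(("APC", "ACP")):
        ax = axes[row, 0]
        c = by.get((sch, "age_rates"))
        if c is not None:
            _plot_band(ax, c, multiplier if c.role == "age_rates" else 1.0)
            ref = (c.scheme.ref_period if sch == "APC" else c.scheme.ref_cohort)
            what = "year" if sch == "APC" else "cohort"
            ax.set_title(f"{sch}: age-specific rates (reference {what} {ref:g})")
            ax.set_xlabel("age (years)")
            ax.set_ylabel("rate" + ("" if multiplier == 1.0
                                    else f" x {multiplier:g}"))
        ax = axes[row, 1]
        any_curve = False
        for role in ("drift_bearing", "residual"):
            c = by.get((sch, role))
            if c is not None:
                _plot_band(ax, c, 1.0,
                           label=f"{c.variable} ({role.replace('_', ' ')})")
                any_curve = True
        if any_curve:
            ax.axhline(1.0, color="grey", lw=0.8, ls=":")
            ax.set_title(f"{sch}: temporal rate ratios")
            ax.set_xlabel("calendar year")
            ax.set_ylabel("rate ratio")
            ax.legend(fontsize=8)
    fig.tight_layout()
    path = os.path.join(outdir, f"{stem}_panels.png")
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def _plot_band(ax, curve, multiplier, label=None):
    order = np.argsort(curve.grid)
    g = curve.grid[order]
    ax.plot(g, curve.estimate[order] * multiplier, lw=1.5, label=label)
    ax.fill_between(g, curve.lower[order] * multiplier,
                    curve.upper[order] * multiplier, alpha=0.25)
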