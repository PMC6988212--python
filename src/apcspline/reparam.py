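"""Identifiability constraints and design-matrix assembly.

Because cohort = period - age exactly, a model with unconstrained smooth
functions of all three time scales is over-parameterised: a linear trend
("drift") can be traded freely between the temporal functions, and constants
between all of them.  Three constraints make the decomposition unique:

1. the age function carries the intercept, so it reads as absolute
   age-specific rates;
2. the drift-bearing temporal function (period under the APC scheme, cohort
   under ACP) is anchored to zero at a reference year, so it reads as a rate
   ratio relative to that year and absorbs the drift;
3. the remaining temporal function is detrended - projected, under weights,
   orthogonal to the constant and linear functions of its variable - so it
   has zero weighted mean and zero weighted slope and reads as a residual
   rate ratio.

The choice of scheme changes the displayed curves but not the fitted model:
both designs span the same column space.

Detrending weights default to the number surveyed per cell, mirroring the
offset's role as exposure; unweighted and cases-weighted variants are
available through the ``weights`` argument of :func:`assemble_design`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .apc_data import APCDataset, weighted_quantile
from .exceptions import FittingError, ValidationError
from .rcs import KnotSpec, SplineBasis, place_knots, place_knots_quantile, \
    rcs_basis

SCHEMES = ("APC", "ACP")


@dataclass(frozen=True)
class ConstraintScheme:
    """Which temporal function carries the drift, and the anchor years.

    ``APC`` puts the drift in the period function (anchored at
    ``ref_period``) and detrends the cohort function; ``ACP`` puts it in the
    cohort function (anchored at ``ref_cohort``) and detrends period.
    """

    scheme: str
    ref_period: float
    ref_cohort: float

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValidationError(f"scheme must be one of {SCHEMES}, "
                                  f"got {self.scheme!r}")

    @property
    def drift_variable(self) -> str:
        return "period" if self.scheme == "APC" else "cohort"

    @property
    def residual_variable(self) -> str:
        return "cohort" if self.scheme == "APC" else "period"

    @property
    def drift_reference(self) -> float:
        return self.ref_period if self.scheme == "APC" else self.ref_cohort

    def to_dict(self) -> dict:
        return {"scheme": self.scheme, "ref_period": self.ref_period,
                "ref_cohort": self.ref_cohort}

    @classmethod
    def from_dict(cls, d: dict) -> "ConstraintScheme":
        return cls(d["scheme"], float(d["ref_period"]), float(d["ref_cohort"]))


def default_scheme(dataset: APCDataset, scheme: str = "APC",
                   ref_period: float | None = None,
                   ref_cohort: float | None = None) -> ConstraintScheme:
    """Scheme with references defaulting to survey-size-weighted medians."""
    if ref_period is None:
        ref_period = float(weighted_quantile(dataset.periods, 0.5,
                                             dataset.denom)[0])
    if ref_cohort is None:
        ref_cohort = float(weighted_quantile(dataset.cohorts, 0.5,
                                             dataset.denom)[0])
    return ConstraintScheme(scheme, ref_period, ref_cohort)


def center_at_reference(basis: SplineBasis, ref: float) -> SplineBasis:
    """Shift every column so it evaluates to exactly zero at ``ref``.

    Any linear combination of the centered columns then vanishes at the
    reference; the operation is idempotent.
    """
    ref_val = rcs_basis([ref], basis.knots).values[0] - basis.offset
    return SplineBasis(values=basis.values - ref_val, knots=basis.knots,
                       column_labels=[f"{c}_c" for c in basis.column_labels],
                       offset=basis.offset + ref_val)


@dataclass
class DetrendedBasis:
    """Spline basis projected orthogonal (under weights) to {1, t}.

    ``projection`` holds the 2 x n_cols matrix A with rows (constant, slope)
    such that the detrended columns are B - [1, t] A; it is what allows the
    same transformation to be replayed on a new evaluation grid.  The linear
    column of the input, annihilated exactly by the projection, is dropped.
    """

    values: np.ndarray
    knots: KnotSpec
    column_labels: list[str]
    projection: np.ndarray  # 2 x (n_basis of the parent, pre-drop)

    @property
    def n_basis(self) -> int:
        return self.values.shape[1]

    def evaluate(self, x) -> np.ndarray:
        """Replay the detrending transformation at new points."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        B = rcs_basis(x, self.knots).values
        Xg = np.column_stack([np.ones_like(x), x])
        return (B - Xg @ self.projection)[:, 1:]


def detrend(basis: SplineBasis, t, w) -> DetrendedBasis:
    """Remove the weighted mean and weighted linear trend from each column.

    Computes B* = B - X (X'WX)^{-1} X'W B with X = [1, t] and W = diag(w),
    then drops the (exactly annihilated) linear column.  Every remaining
    column j satisfies sum_i w_i B*_ij = 0 and sum_i w_i t_i B*_ij = 0, so
    any fitted combination has weighted mean zero and weighted
    least-squares slope zero over the data.
    """
    t = np.asarray(t, dtype=float)
    w = np.asarray(w, dtype=float)
    B = basis.values
    if not (len(t) == B.shape[0] == len(w)):
        raise ValidationError("basis rows, t and w must have equal length")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValidationError("weights must be nonnegative with positive sum")
    if np.ptp(t) == 0:
        raise ValidationError("t is constant: the trend projection is "
                              "rank-deficient")
    X = np.column_stack([np.ones_like(t), t])
    XtW = X.T * w
    A = np.linalg.solve(XtW @ X, XtW @ B)
    resid = B - X @ A
    lin_norm = np.max(np.abs(resid[:, 0]))
    scale = max(np.max(np.abs(t)), 1.0)
    if lin_norm > 1e-6 * scale:
        raise FittingError(
            f"linear column not annihilated by detrending (max abs "
            f"{lin_norm:.3g}); check the basis convention")
    return DetrendedBasis(values=resid[:, 1:], knots=basis.knots,
                          column_labels=[f"{c}_d"
                                         for c in basis.column_labels[1:]],
                          projection=A)


@dataclass
class DesignMatrix:
    """Assembled model matrix with named column blocks.

    ``blocks`` maps {intercept, age, drift_bearing, residual} to column
    slices (``residual`` absent in the two-term age+time designs).  The
    metadata needed to re-evaluate each block on an arbitrary grid - knot
    layouts, anchor references, the detrending projection - travels with
    the matrix, as do the data columns, so a fitted model is
    self-contained for effect estimation.
    """

    values: np.ndarray
    blocks: dict[str, slice]
    scheme: ConstraintScheme
    knots: dict[str, KnotSpec]
    detrended: DetrendedBasis | None
    data: "APCDataset"

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def block_indices(self, names) -> np.ndarray:
        if isinstance(names, str):
            names = (names,)
        idx: list[int] = []
        for name in names:
            if name not in self.blocks:
                raise ValidationError(
                    f"unknown design block {name!r}; have "
                    f"{sorted(self.blocks)}")
            sl = self.blocks[name]
            idx.extend(range(sl.start, sl.stop))
        return np.asarray(idx, dtype=int)


def default_knots(dataset: APCDataset, n_age: int = 5, n_period: int = 4,
                  n_cohort: int = 4, quantile: bool = False) -> dict[str, KnotSpec]:
    """Per-variable knot layouts over the observed ranges.

    Defaults follow the parsimony convention of five internal knots for age
    and four each for period and cohort, the latter equal so the two
    temporal effects are treated symmetrically.
    """
    out = {}
    for var, n in (("age", n_age), ("period", n_period), ("cohort", n_cohort)):
        x = dataset.frame[var].to_numpy()
        if quantile:
            out[var] = place_knots_quantile(x, n, variable=var)
        else:
            out[var] = place_knots(float(x.min()), float(x.max()), n,
                                   variable=var)
    return out


def _resolve_weights(dataset: APCDataset, weights: str) -> np.ndarray:
    if weights == "denom":
        return dataset.denom
    if weights == "cases":
        return dataset.cases
    if weights == "none":
        return np.ones(len(dataset))
    raise ValidationError(
        f"weights must be 'denom', 'cases' or 'none', got {weights!r}")


def assemble_design(dataset: APCDataset, knots: dict[str, KnotSpec],
                    scheme: ConstraintScheme,
                    weights: str = "denom") -> DesignMatrix:
    """Full three-effect design: intercept | age | drift-bearing | residual.

    The age block is the uncentered spline basis (the intercept rides with
    it); the drift-bearing block is the full basis of period (APC) or cohort
    (ACP) centered at its reference; the residual block is the detrended
    basis of the other temporal variable, weighted by ``weights``.
    """
    if len(dataset) == 0:
        raise ValidationError("dataset is empty")
    n = len(dataset)
    age_b = rcs_basis(dataset.ages, knots["age"])

    db_var = scheme.drift_variable
    res_var = scheme.residual_variable
    db_vals = dataset.frame[db_var].to_numpy()
    res_vals = dataset.frame[res_var].to_numpy()

    db_b = center_at_reference(rcs_basis(db_vals, knots[db_var]),
                               scheme.drift_reference)
    w = _resolve_weights(dataset, weights)
    res_b = detrend(rcs_basis(res_vals, knots[res_var]), res_vals, w)

    parts = [np.ones((n, 1)), age_b.values, db_b.values, res_b.values]
    values = np.hstack(parts)
    stops = [int(s) for s in np.cumsum([p.shape[1] for p in parts])]
    blocks = {"intercept": slice(0, stops[0]),
              "age": slice(stops[0], stops[1]),
              "drift_bearing": slice(stops[1], stops[2]),
              "residual": slice(stops[2], stops[3])}
    design = DesignMatrix(values=values, blocks=blocks, scheme=scheme,
                          knots=dict(knots), detrended=res_b, data=dataset)
    _check_rank(design)
    return design


def assemble_two_term_design(dataset: APCDataset, knots: dict[str, KnotSpec],
                             scheme: ConstraintScheme,
                             time_variable: str) -> DesignMatrix:
    """Reduced age + one-temporal-term design (A+P or A+C).

    The single temporal function necessarily carries the drift and is
    anchored at its reference; no residual block exists.
    """
    if time_variable not in ("period", "cohort"):
        raise ValidationError("time_variable must be 'period' or 'cohort'")
    if len(dataset) == 0:
        raise ValidationError("dataset is empty")
    n = len(dataset)
    age_b = rcs_basis(dataset.ages, knots["age"])
    ref = (scheme.ref_period if time_variable == "period"
           else scheme.ref_cohort)
    tb = center_at_reference(
        rcs_basis(dataset.frame[time_variable].to_numpy(),
                  knots[time_variable]), ref)
    parts = [np.ones((n, 1)), age_b.values, tb.values]
    values = np.hstack(parts)
    stops = [int(s) for s in np.cumsum([p.shape[1] for p in parts])]
    blocks = {"intercept": slice(0, stops[0]),
              "age": slice(stops[0], stops[1]),
              "drift_bearing": slice(stops[1], stops[2])}
    sub_scheme = ConstraintScheme(
        "APC" if time_variable == "period" else "ACP",
        scheme.ref_period, scheme.ref_cohort)
    design = DesignMatrix(values=values, blocks=blocks, scheme=sub_scheme,
                          knots=dict(knots), detrended=None, data=dataset)
    _check_rank(design)
    return design


def _check_rank(design: DesignMatrix) -> None:
    """Abort with a named block rather than silently dropping columns."""
    V = design.values
    if np.linalg.matrix_rank(V) == V.shape[1]:
        return
    # walk the blocks to name the first one that breaks full rank
    cols: list[int] = []
    for name, sl in design.blocks.items():
        new = cols + list(range(sl.start, sl.stop))
        if np.linalg.matrix_rank(V[:, new]) < len(new):
            raise FittingError(
                f"design is rank-deficient once the {name!r} block is "
                f"added; too many knots for the observed "
                f"{design.scheme.scheme} layout?")
        cols = new
    raise FittingError("design is rank-deficient")
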