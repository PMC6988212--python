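"""Aggregated prevalence data on the age x period (Lexis) plane.

The central object is a table of cells, one per (age, period) combination,
holding the number of cases (e.g. women with BMI >= 30 kg/m^2) and the
number surveyed.  Birth cohort is always derived from the exact identity

    cohort = period - age

so the three time scales stay consistent by construction.  Ages and periods
are cell midpoints in continuous years (a 5-year age group 45-49 enters as
47.5, a 2014-15 survey as 2014.5); no integer truncation is applied anywhere.

Besides ingestion, the module rearranges repeated cross-sectional surveys
into synthetic birth cohorts (the Lexis-diagram view of the same counts) and
prepares the four exploratory prevalence panels that are conventionally
inspected before fitting age-period-cohort models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError

REQUIRED_COLUMNS = ("age", "period", "cases", "denom")
DESIGNS = ("cross_sectional", "longitudinal", "unknown")

_COHORT_TOL = 1e-9


def derive_cohort(period, age):
    """Year of birth implied by age at observation: ``period - age``.

    Works element-wise on scalars or arrays; the result is exact
    floating-point subtraction, never rounded.
    """
    return np.asarray(period, dtype=float) - np.asarray(age, dtype=float) \
        if np.ndim(period) or np.ndim(age) else float(period) - float(age)


@dataclass(frozen=True)
class APCRecord:
    """One aggregated cell: ``cases`` of ``denom`` people at (age, period)."""

    age: float
    period: float
    cases: int
    denom: int
    cohort: float | None = None

    def __post_init__(self):
        if self.cohort is None:
            object.__setattr__(self, "cohort", self.period - self.age)
        if self.denom <= 0:
            raise ValidationError(
                f"denom must be positive, got {self.denom} at "
                f"(age={self.age}, period={self.period})"
            )
        if not 0 <= self.cases <= self.denom:
            raise ValidationError(
                f"cases={self.cases} outside [0, denom={self.denom}] at "
                f"(age={self.age}, period={self.period})"
            )
        if abs(self.cohort - (self.period - self.age)) > _COHORT_TOL:
            raise ValidationError(
                f"cohort={self.cohort} != period - age = "
                f"{self.period - self.age}"
            )

    @property
    def prevalence(self) -> float:
        return self.cases / self.denom


class APCDataset:
    """Ordered collection of aggregated (age, period) cells.

    Parameters
    ----------
    frame
        DataFrame with columns ``age, period, cases, denom`` (``cohort``
        is derived if absent).  Duplicate (age, period) cells are pooled by
        summing counts, with a warning, so stratified inputs can be merged.
    label
        Free-text identifier echoed into outputs.
    design
        ``cross_sectional``, ``longitudinal`` or ``unknown``; purely
        descriptive metadata.
    """

    def __init__(self, frame: pd.DataFrame, label: str = "",
                 design: str = "unknown"):
        if design not in DESIGNS:
            raise ValidationError(f"design must be one of {DESIGNS}, got {design!r}")
        missing = [c for c in ("age", "period", "cases", "denom")
                   if c not in frame.columns]
        if missing:
            raise ConfigurationError(f"missing required columns: {missing}")
        frame = frame.copy()
        for col in ("age", "period"):
            frame[col] = pd.to_numeric(frame[col], errors="raise").astype(float)
        for col in ("cases", "denom"):
            frame[col] = pd.to_numeric(frame[col], errors="raise")

        bad_denom = frame.index[frame["denom"] <= 0].tolist()
        if bad_denom:
            raise ValidationError(f"denom must be positive; offending rows: {bad_denom}")
        bad_cases = frame.index[(frame["cases"] < 0)
                                | (frame["cases"] > frame["denom"])].tolist()
        if bad_cases:
            raise ValidationError(
                f"cases must lie in [0, denom]; offending rows: {bad_cases}")

        if frame.duplicated(subset=["age", "period"]).any():
            n_dup = int(frame.duplicated(subset=["age", "period"]).sum())
            warnings.warn(
                f"{n_dup} duplicate (age, period) cells pooled by summing counts",
                stacklevel=2,
            )
            frame = (frame.groupby(["age", "period"], as_index=False)
                     [["cases", "denom"]].sum())
        frame["cohort"] = frame["period"] - frame["age"]
        self.frame = frame[["age", "period", "cohort", "cases", "denom"]] \
            .reset_index(drop=True)
        self.label = label
        self.design = design

    # -- construction helpers -------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[APCRecord], label: str = "",
                     design: str = "unknown") -> "APCDataset":
        rows = [(r.age, r.period, r.cases, r.denom) for r in records]
        frame = pd.DataFrame(rows, columns=["age", "period", "cases", "denom"])
        return cls(frame, label=label, design=design)

    # -- array accessors ------------------------------------------------------
    @property
    def ages(self) -> np.ndarray:
        return self.frame["age"].to_numpy()

    @property
    def periods(self) -> np.ndarray:
        return self.frame["period"].to_numpy()

    @property
    def cohorts(self) -> np.ndarray:
        return self.frame["cohort"].to_numpy()

    @property
    def cases(self) -> np.ndarray:
        return self.frame["cases"].to_numpy(dtype=float)

    @property
    def denom(self) -> np.ndarray:
        return self.frame["denom"].to_numpy(dtype=float)

    @property
    def prevalence(self) -> np.ndarray:
        return self.cases / self.denom

    @property
    def total_cases(self) -> float:
        return float(self.frame["cases"].sum())

    @property
    def total_denom(self) -> float:
        return float(self.frame["denom"].sum())

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[APCRecord]:
        for row in self.frame.itertuples(index=False):
            yield APCRecord(age=row.age, period=row.period,
                            cases=int(row.cases), denom=int(row.denom),
                            cohort=row.cohort)

    def __repr__(self) -> str:
        return (f"APCDataset(label={self.label!r}, design={self.design!r}, "
                f"n_cells={len(self)}, cases={self.total_cases:.0f}/"
                f"{self.total_denom:.0f})")


def load_counts(source, delimiter: str | None = None, label: str = "",
                design: str = "unknown") -> APCDataset:
    """Read an aggregated count table from delimited text.

    ``source`` is a path or file-like object with header columns
    ``age, period, cases, denom`` (an optional ``label`` column, if constant,
    names the dataset).  The delimiter is sniffed unless given.  Comment
    lines starting with ``#`` are ignored so the package's own CSV outputs
    round-trip.
    """
    try:
        if delimiter is None:
            frame = pd.read_csv(source, sep=None, engine="python", comment="#")
        else:
            frame = pd.read_csv(source, sep=delimiter, comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ConfigurationError(f"could not parse count table: {exc}") from exc

    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ConfigurationError(
            f"count table lacks required columns {missing}; found "
            f"{list(frame.columns)}")

    if not label and "label" in frame.columns:
        uniq = frame["label"].dropna().unique()
        if len(uniq) == 1:
            label = str(uniq[0])

    try:
        for col in REQUIRED_COLUMNS:
            frame[col] = pd.to_numeric(frame[col], errors="raise")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric value in column {col!r}: {exc}") from exc

    return APCDataset(frame[list(REQUIRED_COLUMNS)], label=label, design=design)


def lexis_reshape(dataset: APCDataset, bin_width: float,
                  origin: float | None = None) -> APCDataset:
    """Pool cells into synthetic birth cohorts of width ``bin_width`` years.

    Cells are grouped by (cohort bin, age), where the bin index is
    ``floor((cohort - origin) / bin_width)`` with ``origin`` defaulting to
    the earliest observed birth year.  Counts are summed within each group;
    the group's cohort is the denom-weighted mean birth year of its members
    and its period is recovered as ``cohort + age``, so the Lexis identity
    is preserved exactly.  The result carries ``n_synthetic_cohorts``, the
    number of distinct cohort bins.
    """
    if bin_width <= 0:
        raise ValidationError(f"bin_width must be positive, got {bin_width}")
    if dataset.frame["period"].nunique() < 2:
        raise ValidationError(
            "lexis_reshape needs at least 2 distinct survey periods")
    if origin is None:
        origin = float(dataset.frame["cohort"].min())

    df = dataset.frame.copy()
    df["cohort_bin"] = np.floor((df["cohort"] - origin) / bin_width).astype(int)
    df["_wc"] = df["cohort"] * df["denom"]
    grouped = (df.groupby(["cohort_bin", "age"], as_index=False)
               .agg(cases=("cases", "sum"), denom=("denom", "sum"),
                    _wc=("_wc", "sum")))
    grouped["cohort"] = grouped["_wc"] / grouped["denom"]
    grouped["period"] = grouped["cohort"] + grouped["age"]
    out = APCDataset(grouped[["age", "period", "cases", "denom"]],
                     label=dataset.label, design=dataset.design)
    out.frame["cohort_bin"] = grouped["cohort_bin"].to_numpy()
    out.n_synthetic_cohorts = int(grouped["cohort_bin"].nunique())
    out.bin_width = float(bin_width)
    out.bin_origin = float(origin)
    return out


def weighted_quantile(values, q, weights=None) -> np.ndarray:
    """Inverted-CDF weighted quantiles: smallest v with F_w(v) >= q."""
    values = np.asarray(values, dtype=float)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if weights is None:
        weights = np.ones_like(values)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValidationError("weights must be nonnegative with positive sum")
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cdf = np.cumsum(w) / w.sum()
    idx = np.searchsorted(cdf, q - 1e-12, side="left")
    idx = np.clip(idx, 0, len(v) - 1)
    return v[idx]


def _assign_age_group(ages: np.ndarray,
                      age_groups: Sequence[tuple[float, float]]) -> np.ndarray:
    labels = np.full(len(ages), None, dtype=object)
    for lo, hi in age_groups:
        inside = (ages >= lo) & (ages < hi)
        labels[inside] = f"[{lo:g}, {hi:g})"
    # top edge of the last interval is inclusive so the max age is kept
    lo, hi = max(age_groups, key=lambda g: g[1])
    labels[ages == hi] = f"[{lo:g}, {hi:g})"
    return labels


def _default_age_groups(ages: np.ndarray, n_groups: int = 4):
    uniq = np.unique(ages)
    if len(uniq) <= n_groups:
        eps = 1e-9
        return [(a, a + eps) for a in uniq]
    edges = np.quantile(uniq, np.linspace(0, 1, n_groups + 1))
    edges[-1] = edges[-1] + 1e-9
    return [(edges[i], edges[i + 1]) for i in range(n_groups)]


def exploratory_panels(dataset: APCDataset,
                       age_groups: Sequence[tuple[float, float]] | None = None,
                       cohort_quartiles: bool = False,
                       weighted: bool = True) -> dict[str, pd.DataFrame]:
    """The four conventional exploratory prevalence tables.

    Returns a dict of DataFrames keyed

    - ``age_by_period``      prevalence by age, one series per survey period;
    - ``period_by_age_group`` prevalence by period within age bands;
    - ``age_by_cohort``      prevalence by age, one series per birth cohort
      (or per birth-year quartile when ``cohort_quartiles``);
    - ``cohort_by_age_group`` prevalence by birth year within age bands.

    Roughly parallel series in the first pair point to age-period structure,
    in the second pair to age-cohort structure.  Quartile grouping weights
    each cell by its survey size unless ``weighted`` is False.
    """
    if len(dataset) == 0:
        raise ValidationError("dataset is empty")
    if age_groups is not None and len(age_groups) == 0:
        raise ValidationError("age_groups must be a nonempty list of intervals")
    if age_groups is None:
        age_groups = _default_age_groups(dataset.ages)

    df = dataset.frame.copy()
    df["prevalence"] = df["cases"] / df["denom"]

    panels: dict[str, pd.DataFrame] = {}
    panels["age_by_period"] = (
        df[["period", "age", "prevalence", "cases", "denom"]]
        .sort_values(["period", "age"]).reset_index(drop=True))

    df["age_group"] = _assign_age_group(df["age"].to_numpy(), age_groups)
    uncovered = df["age_group"].isna()
    if uncovered.any():
        warnings.warn(
            f"{int(uncovered.sum())} cells fall outside the supplied "
            "age_groups and are omitted from age-grouped panels",
            stacklevel=2)

    grouped = (df[~uncovered]
               .groupby(["age_group", "period"], as_index=False)
               [["cases", "denom"]].sum())
    grouped["prevalence"] = grouped["cases"] / grouped["denom"]
    panels["period_by_age_group"] = grouped[
        ["age_group", "period", "prevalence", "cases", "denom"]]

    if cohort_quartiles:
        w = df["denom"].to_numpy() if weighted else None
        breaks = weighted_quantile(df["cohort"].to_numpy(),
                                   [0.25, 0.5, 0.75], w)
        df["cohort_group"] = np.searchsorted(breaks, df["cohort"].to_numpy(),
                                             side="left")
        df["cohort_group"] = "Q" + (df["cohort_group"] + 1).astype(str)
        key = "cohort_group"
    else:
        key = "cohort"
    byc = df.groupby([key, "age"], as_index=False)[["cases", "denom"]].sum()
    byc["prevalence"] = byc["cases"] / byc["denom"]
    panels["age_by_cohort"] = byc[[key, "age", "prevalence", "cases", "denom"]]

    byag = (df[~uncovered]
            .groupby(["age_group", "cohort"], as_index=False)
            [["cases", "denom"]].sum())
    byag["prevalence"] = byag["cases"] / byag["denom"]
    panels["cohort_by_age_group"] = byag[
        ["age_group", "cohort", "prevalence", "cases", "denom"]]
    return panels
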