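"""Restricted (natural) cubic spline bases for continuous time-scale effects.

The basis is the truncated-power construction: with ordered knots
t_1 < ... < t_K the columns are

    s_1(x) = x
    s_{j+1}(x) = [ (x - t_j)_+^3
                   - (x - t_{K-1})_+^3 (t_K - t_j)/(t_K - t_{K-1})
                   + (x - t_K)_+^3   (t_{K-1} - t_j)/(t_K - t_{K-1})
                 ] / (t_K - t_1)^2            for j = 1 .. K-2,

where (u)_+ = max(u, 0).  Every linear combination is cubic between knots,
twice continuously differentiable everywhere, and exactly linear beyond both
boundary knots, so extrapolation degrades gracefully.  The (t_K - t_1)^2
normalisation keeps the nonlinear columns on roughly the scale of x itself.

Knots are by default equally spaced over the observed range of the variable;
quantile-based placement is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError


@dataclass(frozen=True)
class KnotSpec:
    """Knot layout for one variable: boundary pair plus interior knots."""

    variable: str
    boundary: tuple[float, float]
    internal: tuple[float, ...] = ()

    def __post_init__(self):
        lo, hi = self.boundary
        if not lo < hi:
            raise ValidationError(
                f"boundary min must be < max, got ({lo}, {hi})")
        internal = tuple(float(t) for t in self.internal)
        object.__setattr__(self, "internal", internal)
        object.__setattr__(self, "boundary", (float(lo), float(hi)))
        if any(b <= a for a, b in zip(internal, internal[1:])):
            raise ValidationError("internal knots must be strictly increasing")
        if internal and not (lo < internal[0] and internal[-1] < hi):
            raise ValidationError(
                "internal knots must lie strictly inside the boundary")

    @property
    def all_knots(self) -> np.ndarray:
        lo, hi = self.boundary
        return np.array([lo, *self.internal, hi], dtype=float)

    @property
    def n_total(self) -> int:
        return len(self.internal) + 2

    @property
    def n_basis(self) -> int:
        """Columns spanned: one linear plus K-2 restricted cubics."""
        return self.n_total - 1

    def to_dict(self) -> dict:
        return {"variable": self.variable,
                "boundary": list(self.boundary),
                "internal": list(self.internal)}

    @classmethod
    def from_dict(cls, d: dict) -> "KnotSpec":
        return cls(variable=d["variable"], boundary=tuple(d["boundary"]),
                   internal=tuple(d.get("internal", ())))


@dataclass
class SplineBasis:
    """Evaluated basis matrix: rows = evaluation points, columns = functions.

    ``offset`` records the constant row already subtracted from the raw
    basis (zero for a freshly evaluated basis); reference-centering updates
    it so the operation can be replayed on new grids and is idempotent.
    """

    values: np.ndarray
    knots: KnotSpec
    column_labels: list[str]
    offset: np.ndarray | None = None

    def __post_init__(self):
        if self.offset is None:
            self.offset = np.zeros(self.values.shape[1])

    @property
    def n_basis(self) -> int:
        return self.values.shape[1]


def place_knots(xmin: float, xmax: float, n_internal: int,
                variable: str = "x") -> KnotSpec:
    """Equally spaced internal knots on (xmin, xmax), boundaries at the ends.

    Internal knot i (1-based) sits at ``xmin + i (xmax - xmin)/(n + 1)``.
    """
    if n_internal < 0:
        raise ValidationError(f"n_internal must be >= 0, got {n_internal}")
    if not xmin < xmax:
        raise ValidationError(f"need xmin < xmax, got ({xmin}, {xmax})")
    step = (xmax - xmin) / (n_internal + 1)
    internal = tuple(xmin + i * step for i in range(1, n_internal + 1))
    return KnotSpec(variable=variable, boundary=(xmin, xmax), internal=internal)


def place_knots_quantile(x, n_internal: int, variable: str = "x") -> KnotSpec:
    """Internal knots at equally spaced quantiles of the observed values."""
    if n_internal < 0:
        raise ValidationError(f"n_internal must be >= 0, got {n_internal}")
    x = np.asarray(x, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    qs = np.linspace(0, 1, n_internal + 2)[1:-1]
    internal = np.quantile(x, qs)
    # nudge any quantile that collides with a boundary or a neighbour
    internal = tuple(t for t in np.unique(internal) if lo < t < hi)
    return KnotSpec(variable=variable, boundary=(lo, hi), internal=internal)


def rcs_basis(x, knots: KnotSpec) -> SplineBasis:
    """Evaluate the restricted cubic spline basis at the points ``x``.

    Points may lie outside the boundary knots; there every column continues
    linearly by construction.
    """
    t = knots.all_knots
    K = len(t)
    if K < 2:
        raise ValidationError("need at least 2 knots (the boundary pair)")
    x = np.atleast_1d(np.asarray(x, dtype=float))

    cols = [x]
    labels = [f"{knots.variable}_lin"]
    norm = (t[-1] - t[0]) ** 2
    ratio_den = t[-1] - t[-2]
    for j in range(K - 2):
        tj = t[j]
        term = (_pos3(x - tj)
                - _pos3(x - t[-2]) * (t[-1] - tj) / ratio_den
                + _pos3(x - t[-1]) * (t[-2] - tj) / ratio_den)
        cols.append(term / norm)
        labels.append(f"{knots.variable}_rcs{j + 1}")
    return SplineBasis(values=np.column_stack(cols), knots=knots,
                       column_labels=labels)


def _pos3(u: np.ndarray) -> np.ndarray:
    return np.maximum(u, 0.0) ** 3
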