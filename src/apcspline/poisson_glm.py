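"""Poisson log-link GLM with exposure offset, fitted by IRLS.

Counts y_i are modelled as Poisson with mean

    mu_i = exp(x_i' beta + log(denom_i)),

so exp(x_i' beta) is the rate (prevalence) and coefficients exponentiate to
rate ratios.  The log-likelihood includes the log(y!) constant, so reported
values are absolute, not kernel-only, and comparable across software.

Fitting is iteratively reweighted least squares with each weighted solve
done through a QR decomposition of the weighted design rather than the
normal equations; the coefficient covariance (X'WX)^{-1} is formed once at
convergence from the final R factor.  Cells with zero cases are legitimate
observations and are retained.

No overdispersion scale is applied by default.  When the independence
assumption is doubtful - repeated observations of the same individuals, as
in long-running longitudinal cohorts - ``fit(..., scale="pearson")``
inflates the covariance by the Pearson chi-square over residual df.  This
is an extension flag, not part of the core model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import gammaln

from .exceptions import FittingError, ValidationError
from .reparam import DesignMatrix

DEVIANCE_TOL = 1e-8
MAX_ITER = 100


def poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    """Full Poisson log-likelihood sum(y log mu - mu - log y!)."""
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


def poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """2 sum[ y log(y/mu) - (y - mu) ], zero-case cells contributing mu."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


@dataclass
class FittedAPCModel:
    """A converged (or flagged) Poisson fit plus its design metadata."""

    coefficients: np.ndarray
    covariance: np.ndarray
    loglik: float
    n_params: int
    n_obs: int
    deviance_resid_total: float
    fitted_counts: np.ndarray
    design: DesignMatrix
    converged: bool
    iterations: int
    score_norm: float
    scale: float = 1.0

    def coef_block(self, names) -> np.ndarray:
        return self.coefficients[self.design.block_indices(names)]

    def cov_block(self, names) -> np.ndarray:
        idx = self.design.block_indices(names)
        return self.covariance[np.ix_(idx, idx)]

    def to_dict(self) -> dict:
        """JSON-serializable snapshot sufficient to recompute effect curves."""
        d = self.design
        return {
            "coefficients": self.coefficients.tolist(),
            "covariance": self.covariance.tolist(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "deviance_resid_total": self.deviance_resid_total,
            "converged": self.converged,
            "iterations": self.iterations,
            "scale": self.scale,
            "blocks": {k: [v.start, v.stop] for k, v in d.blocks.items()},
            "scheme": d.scheme.to_dict(),
            "knots": {k: v.to_dict() for k, v in d.knots.items()},
            "detrend_projection": (d.detrended.projection.tolist()
                                   if d.detrended is not None else None),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def fit(design: DesignMatrix, cases=None, denom=None,
        tol: float = DEVIANCE_TOL, max_iter: int = MAX_ITER,
        scale: str | None = None) -> FittedAPCModel:
    """Maximum-likelihood Poisson fit of ``cases`` with offset log(denom).

    ``cases``/``denom`` default to the columns of the dataset the design was
    assembled from.  Iterates IRLS until the relative deviance change drops
    below ``tol`` or ``max_iter`` is hit; non-convergence is flagged on the
    returned model rather than raised, so diagnostics stay accessible.
    """
    X = design.values
    if cases is None:
        cases = design.data.cases
    if denom is None:
        denom = design.data.denom
    y = np.asarray(cases, dtype=float)
    denom = np.asarray(denom, dtype=float)
    if not (len(y) == X.shape[0] == len(denom)):
        raise ValidationError("rows of design, cases and denom must match")
    if np.any(denom <= 0):
        raise ValidationError("denom must be strictly positive")
    offset = np.log(denom)
    n, p = X.shape

    beta = np.zeros(p)
    total_rate = y.sum() / denom.sum()
    beta[0] = np.log(total_rate) if total_rate > 0 else -10.0

    eta = X @ beta + offset
    mu = np.exp(eta)
    dev = poisson_deviance(y, mu)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        z = (eta - offset) + (y - mu) / mu
        sw = np.sqrt(mu)
        Q, R = np.linalg.qr(sw[:, None] * X)
        diag = np.abs(np.diag(R))
        if np.min(diag) < 1e-10 * np.max(diag):
            raise FittingError(
                "weighted normal equations are singular; the design has "
                "(numerically) collinear columns")
        beta = solve_triangular(R, Q.T @ (sw * z))
        eta = X @ beta + offset
        mu = np.exp(eta)
        dev_new = poisson_deviance(y, mu)
        if converged:
            dev = dev_new
            break
        if abs(dev_new - dev) < tol * (abs(dev_new) + 0.1):
            # one polishing step: quadratic convergence drives the score
            # norm to the stationary point before covariance is formed
            converged = True
        dev = dev_new
    if not converged:
        warnings.warn(f"IRLS did not converge in {max_iter} iterations "
                      f"(deviance {dev:.6g})", stacklevel=2)

    # covariance from the final weighted QR: (X'WX)^{-1} = R^{-1} R^{-T}
    sw = np.sqrt(mu)
    Q, R = np.linalg.qr(sw[:, None] * X)
    Rinv = solve_triangular(R, np.eye(p))
    cov = Rinv @ Rinv.T
    cov = 0.5 * (cov + cov.T)

    scale_val = 1.0
    if scale == "pearson":
        pearson = float(np.sum((y - mu) ** 2 / mu))
        scale_val = pearson / max(n - p, 1)
        cov = cov * scale_val
    elif scale is not None:
        raise ValidationError(f"scale must be None or 'pearson', got {scale!r}")

    score = X.T @ (y - mu)
    return FittedAPCModel(
        coefficients=beta,
        covariance=cov,
        loglik=poisson_loglik(y, mu),
        n_params=p,
        n_obs=n,
        deviance_resid_total=poisson_deviance(y, mu),
        fitted_counts=mu,
        design=design,
        converged=converged,
        iterations=it,
        score_norm=float(np.max(np.abs(score))),
        scale=scale_val,
    )


def predict_linear(model: FittedAPCModel, rows: np.ndarray,
                   blocks=None) -> tuple[np.ndarray, np.ndarray]:
    """Linear-predictor estimates and delta-method standard errors.

    ``rows`` is a matrix whose columns correspond to the coefficient
    sub-vector selected by ``blocks`` (a block name or sequence of names;
    ``None`` means the full design).  Returns ``(estimate, se)`` with
    estimate = r' beta and se = sqrt(r' Cov r) per row.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if blocks is None:
        beta = model.coefficients
        cov = model.covariance
    else:
        beta = model.coef_block(blocks)
        cov = model.cov_block(blocks)
    if rows.shape[1] != len(beta):
        raise ValidationError(
            f"rows have {rows.shape[1]} columns but the selected coefficient "
            f"block has {len(beta)}")
    est = rows @ beta
    var = np.einsum("ij,jk,ik->i", rows, cov, rows)
    return est, np.sqrt(np.maximum(var, 0.0))
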