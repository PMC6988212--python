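import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.special import gammaln

import apcspline as aps
from apcspline.exceptions import ValidationError
from apcspline.poisson_glm import fit as glm_fit
from apcspline.poisson_glm import poisson_loglik, predict_linear
from apcspline.reparam import ConstraintScheme, DesignMatrix


def _bare_design(X, cases, denom):
    """Wrap a raw matrix (first column = intercept) as a DesignMatrix."""
    frame = pd.DataFrame({"age": np.arange(len(cases), dtype=float) + 20.0,
                          "period": 2000.0, "cases": cases, "denom": denom})
    data = aps.APCDataset(frame)
    return DesignMatrix(values=X,
                        blocks={"intercept": slice(0, 1),
                                "rest": slice(1, X.shape[1])},
                        scheme=ConstraintScheme("APC", 2000.0, 1950.0),
                        knots={}, detrended=None, data=data)


def _brute_force_mle(X, y, denom, p):
    """Generic numeric maximizer of the same Poisson log-likelihood."""
    off = np.log(denom)

    def negll(beta):
        eta = X @ beta + off
        mu = np.exp(eta)
        return -np.sum(y * eta - mu - gammaln(y + 1.0))

    def grad(beta):
        mu = np.exp(X @ beta + off)
        return -X.T @ (y - mu)

    def hess(beta):
        mu = np.exp(X @ beta + off)
        return (X * mu[:, None]).T @ X

    res = minimize(negll, np.zeros(p), jac=grad, hess=hess,
                   method="Newton-CG", options={"xtol": 1e-12})
    return res.x


class TestFit:
    def test_intercept_only_single_cell_closed_form(self):
        X = np.ones((1, 1))
        model = glm_fit(_bare_design(X, [5], [100]))
        assert model.coefficients[0] == pytest.approx(np.log(0.05), abs=1e-10)
        assert model.fitted_counts[0] == pytest.approx(5.0, abs=1e-8)

    def test_intercept_only_common_rate(self):
        X = np.ones((2, 1))
        model = glm_fit(_bare_design(X, [5, 10], [100, 200]))
        assert model.coefficients[0] == pytest.approx(np.log(0.05), abs=1e-10)

    def test_total_fitted_matches_total_observed(self, fitted_pair):
        for model in fitted_pair.values():
            total = model.design.data.total_cases
            assert model.fitted_counts.sum() == pytest.approx(
                total, rel=1e-6)

    def test_score_vanishes_at_reported_optimum(self, fitted_pair):
        for model in fitted_pair.values():
            # scale-free: score relative to the magnitude of the counts
            assert model.score_norm < 1e-6 * model.design.data.total_cases

    def test_covariance_symmetric_positive_semidefinite(self, fitted_pair):
        for model in fitted_pair.values():
            cov = model.covariance
            assert np.allclose(cov, cov.T)
            assert np.min(np.linalg.eigvalsh(cov)) > -1e-12

    def test_zero_count_cells_are_retained(self):
        X = np.column_stack([np.ones(4), [0.0, 1.0, 2.0, 3.0]])
        model = glm_fit(_bare_design(X, [0, 2, 5, 9], [100] * 4))
        assert model.converged
        assert model.n_obs == 4

    def test_mismatched_rows_rejected(self):
        X = np.ones((3, 1))
        design = _bare_design(X, [1, 2, 3], [10, 10, 10])
        with pytest.raises(ValidationError):
            glm_fit(design, cases=[1, 2], denom=[10, 10])

    def test_pearson_scale_inflates_covariance(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        y = rng.poisson(5.0, size=30)
        design = _bare_design(X, y, [100] * 30)
        plain = glm_fit(design)
        inflated = glm_fit(design, scale="pearson")
        assert np.allclose(inflated.covariance,
                           plain.covariance * inflated.scale)


class TestBruteForceAgreement:
    """IRLS must land on the same optimum as a generic numeric maximizer."""

    @pytest.mark.parametrize("seed", range(25))
    def test_random_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 20, 4
        X = np.column_stack([np.ones(n), rng.normal(scale=0.5,
                                                    size=(n, p - 1))])
        beta_true = rng.normal(scale=0.3, size=p)
        beta_true[0] = np.log(0.05)
        denom = rng.integers(50, 500, size=n).astype(float)
        mu = denom * np.exp(X @ beta_true)
        y = rng.poisson(mu)
        model = glm_fit(_bare_design(X, y, denom))
        beta_oracle = _brute_force_mle(X, y.astype(float), denom, p)
        assert np.max(np.abs(model.coefficients - beta_oracle)) < 1e-6


def test_agreement_with_statsmodels_glm(small_dataset, small_knots,
                                        fitted_pair):
    import statsmodels.api as sm

    model = fitted_pair["APC"]
    X = model.design.values
    sm_fit = sm.GLM(small_dataset.cases, X, family=sm.families.Poisson(),
                    offset=np.log(small_dataset.denom)).fit()
    assert np.max(np.abs(model.coefficients - sm_fit.params)) < 1e-6
    assert model.loglik == pytest.approx(sm_fit.llf, abs=1e-6)


def test_deviance_of_nested_submodel_is_larger(fitted_pair, reduced_models):
    full = fitted_pair["APC"]
    for reduced in reduced_models.values():
        assert reduced.deviance_resid_total >= full.deviance_resid_total


class TestPredictLinear:
    def test_all_zero_row(self, fitted_pair):
        model = fitted_pair["APC"]
        est, se = predict_linear(model, np.zeros((1, 4)), blocks="residual")
        assert est[0] == 0.0 and se[0] == 0.0

    def test_se_invariant_to_sign_flip(self, fitted_pair):
        model = fitted_pair["APC"]
        row = np.arange(1.0, 6.0)[None, :]
        _, se_pos = predict_linear(model, row, blocks="drift_bearing")
        _, se_neg = predict_linear(model, -row, blocks="drift_bearing")
        assert se_pos[0] == pytest.approx(se_neg[0])

    def test_two_coefficient_quadratic_form_by_hand(self):
        X = np.column_stack([np.ones(10), np.linspace(-1, 1, 10)])
        rng = np.random.default_rng(11)
        y = rng.poisson(8.0, size=10)
        model = glm_fit(_bare_design(X, y, [100] * 10))
        cov = model.covariance
        row = np.array([1.0, 0.5])
        est, se = predict_linear(model, row[None, :])
        hand_var = (cov[0, 0] + 2 * 0.5 * cov[0, 1] + 0.25 * cov[1, 1])
        assert se[0] == pytest.approx(np.sqrt(hand_var), rel=1e-12)
        assert est[0] == pytest.approx(row @ model.coefficients)

    def test_unknown_block_rejected(self, fitted_pair):
        with pytest.raises(ValidationError):
            predict_linear(fitted_pair["APC"], np.zeros((1, 2)),
                           blocks="seasonal")

    def test_row_width_mismatch_rejected(self, fitted_pair):
        with pytest.raises(ValidationError):
            predict_linear(fitted_pair["APC"], np.zeros((1, 3)),
                           blocks="residual")
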