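import numpy as np
import pandas as pd
import pytest

import apcspline as aps
from apcspline.exceptions import ValidationError
from apcspline.synthgen import (SyntheticScenario, default_scenario,
                                effect_from_spec, scenario_from_dict,
                                transformed_truth)


class TestSimulate:
    def test_same_seed_gives_identical_datasets(self):
        scn = default_scenario(denom_per_cell=1000, seed=42, n_ages=6,
                               n_periods=4)
        a = aps.simulate(scn)
        b = aps.simulate(scn)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_different_seed_changes_counts(self):
        base = dict(denom_per_cell=1000, n_ages=6, n_periods=4)
        a = aps.simulate(default_scenario(seed=1, **base))
        b = aps.simulate(default_scenario(seed=2, **base))
        assert not a.frame["cases"].equals(b.frame["cases"])

    def test_grid_extension_preserves_existing_cells(self):
        # per-cell substreams: adding surveys must not reshuffle old ones
        a = aps.simulate(default_scenario(seed=3, denom_per_cell=1000,
                                          n_ages=6, n_periods=4))
        b = aps.simulate(default_scenario(seed=3, denom_per_cell=1000,
                                          n_ages=6, n_periods=6))
        merged = a.frame.merge(b.frame, on=["age", "period"],
                               suffixes=("_a", "_b"))
        assert len(merged) == len(a.frame)
        assert merged["cases_a"].equals(merged["cases_b"])

    def test_zero_effects_grand_prevalence(self):
        # flat truth at rate 0.2: the pooled estimate should land within
        # 3 binomial standard errors of the truth
        scn = SyntheticScenario(baseline_log_rate=np.log(0.2),
                                ages=np.linspace(20, 70, 10),
                                periods=np.linspace(2000, 2016, 5),
                                denom_per_cell=1000, seed=9)
        ds = aps.simulate(scn)
        n_total = ds.total_denom
        p_hat = ds.total_cases / n_total
        assert abs(p_hat - 0.2) < 3 * np.sqrt(0.2 * 0.8 / n_total)

    def test_longitudinal_age_spans(self):
        scn = SyntheticScenario(baseline_log_rate=np.log(0.1),
                                design="longitudinal",
                                cohorts=np.array([1950.0, 1975.0]),
                                periods=np.arange(1996.0, 2017.0, 4.0),
                                denom_per_cell=100, seed=0)
        ds = aps.simulate(scn)
        by_cohort = ds.frame.groupby("cohort")["age"]
        assert by_cohort.min()[1950.0] == 46 and by_cohort.max()[1950.0] == 66
        assert by_cohort.min()[1975.0] == 21 and by_cohort.max()[1975.0] == 41

    def test_rate_above_one_rejected_before_sampling(self):
        scn = SyntheticScenario(baseline_log_rate=np.log(0.9),
                                f_period=lambda p: np.full_like(p, 0.5),
                                ages=np.array([30.0]),
                                periods=np.array([2000.0]),
                                denom_per_cell=100)
        with pytest.raises(ValidationError, match="rate > 1"):
            aps.simulate(scn)

    def test_implausible_prevalence_warns(self):
        scn = SyntheticScenario(baseline_log_rate=np.log(0.7),
                                ages=np.array([30.0]),
                                periods=np.array([2000.0]),
                                denom_per_cell=100, seed=0)
        with pytest.warns(UserWarning, match="prevalence"):
            aps.simulate(scn)

    def test_binomial_sampling_never_exceeds_denom(self):
        scn = SyntheticScenario(baseline_log_rate=np.log(0.45),
                                ages=np.linspace(20, 70, 8),
                                periods=np.linspace(2000, 2010, 4),
                                denom_per_cell=30, seed=4,
                                sampling="binomial")
        ds = aps.simulate(scn)
        assert np.all(ds.cases <= ds.denom)

    def test_simulated_csv_round_trips_through_loader(self, tmp_path):
        ds = aps.simulate(default_scenario(denom_per_cell=500, seed=5,
                                           n_ages=5, n_periods=3))
        path = tmp_path / "sim.csv"
        ds.frame[["age", "period", "cases", "denom"]].to_csv(path,
                                                             index=False)
        back = aps.load_counts(path)
        assert len(back) == len(ds)
        assert back.total_cases == ds.total_cases


class TestScenarioConfig:
    def test_round_trip_through_dict(self):
        cfg = {"design": "cross_sectional",
               "ages": {"min": 20, "max": 60, "n": 5},
               "periods": [2000, 2005, 2010],
               "denom_per_cell": 200, "seed": 8,
               "baseline_log_rate": float(np.log(0.15)),
               "effects": {"age": {"shape": "quadratic_peak", "peak": 55,
                                   "curvature": 2000}}}
        scn = scenario_from_dict(cfg)
        assert len(scn.cells()) == 15
        ds = aps.simulate(scn)
        assert len(ds) == 15

    def test_unknown_shape_rejected(self):
        with pytest.raises(ValidationError):
            effect_from_spec({"shape": "fourier"})


class TestRecovery:
    def test_truth_against_itself_is_exact(self, small_scenario,
                                           fitted_pair):
        # zero-noise limit: feed the transformed truth back through the
        # same transformation and the discrepancy must vanish
        model = fitted_pair["APC"]
        g = transformed_truth(small_scenario, model)
        data = model.design.data
        sch = model.design.scheme
        a = np.unique(data.ages)
        p = np.unique(data.periods)
        c = np.unique(data.cohorts)
        total_truth = small_scenario.log_rate(
            data.ages, data.periods)
        total_transformed = (g["age"](data.ages)
                             + g["drift_bearing"](
                                 data.frame[sch.drift_variable].to_numpy())
                             + g["residual"](
                                 data.frame[sch.residual_variable]
                                 .to_numpy()))
        assert np.max(np.abs(total_truth - total_transformed)) < 1e-9
        # constraint checks on the transformed pieces themselves
        w = data.denom
        rvals = data.frame[sch.residual_variable].to_numpy()
        r = g["residual"](rvals)
        assert abs(np.sum(w * r)) < 1e-6 * w.sum()
        assert abs(g["drift_bearing"](sch.drift_reference)) < 1e-12

    def test_scheme_mismatch_rejected(self, small_scenario, fitted_pair):
        with pytest.raises(ValidationError, match="mismatch"):
            aps.recovery_report(small_scenario, fitted_pair["APC"],
                                scheme="ACP")

    def test_zero_effect_truth_gives_near_unit_temporal_curves(self):
        scn = SyntheticScenario(baseline_log_rate=np.log(0.15),
                                f_age=lambda a: -((a - 60.0) ** 2) / 1500.0,
                                ages=np.linspace(20, 79, 40),
                                periods=np.linspace(1996, 2017, 8),
                                denom_per_cell=100_000, seed=13)
        ds = aps.simulate(scn)
        knots = aps.default_knots(ds)
        model = aps.fit(aps.assemble_design(
            ds, knots, aps.default_scheme(ds, "APC")))
        curves = aps.effect_curves(model)
        for role in ("drift_bearing", "residual"):
            c = curves[role]
            inside = ~c.extrapolated
            assert np.max(np.abs(np.log(c.estimate[inside]))) < 0.05

    def test_errors_shrink_with_denominator(self):
        # median over replicates of the max log error must drop from
        # denom 1e3 to 1e5
        errs = {denom: [] for denom in (1_000, 100_000)}
        for denom, seeds in ((1_000, range(10)), (100_000, range(10))):
            for seed in seeds:
                scn = default_scenario(denom_per_cell=denom, seed=100 + seed,
                                       n_ages=12, n_periods=6)
                ds = aps.simulate(scn)
                knots = aps.default_knots(ds)
                model = aps.fit(aps.assemble_design(
                    ds, knots, aps.default_scheme(ds, "APC")))
                rep = aps.recovery_report(scn, model)
                errs[denom].append(max(rep.age.max_abs_log,
                                       rep.drift_bearing.max_abs_log,
                                       rep.residual.max_abs_log))
        assert np.median(errs[100_000]) < np.median(errs[1_000])


def test_cohort_signal_detected_period_not(small_knots):
    """Power/level of the nested deviance tests on known truth.

    A clearly non-linear cohort effect with a flat period effect should
    make dropping the cohort term significant (p < 0.01) and dropping the
    period term unremarkable (p > 0.05) in at least 8 of 10 replicates.
    """
    hits_cohort, hits_period = 0, 0
    for seed in range(10):
        scn = default_scenario(denom_per_cell=10_000, seed=200 + seed,
                               n_ages=12, n_periods=6,
                               effect_specs={
                                   "age": {"shape": "quadratic_peak",
                                           "peak": 60, "curvature": 1500},
                                   "period": {"shape": "zero"},
                                   "cohort": {"shape": "linear_softplus",
                                              "slope": 0.010,
                                              "center": 1951, "knee": 1962,
                                              "scale": 10, "gain": 0.12}})
        ds = aps.simulate(scn)
        knots = aps.default_knots(ds)
        scheme = aps.default_scheme(ds, "APC")
        full = aps.fit(aps.assemble_design(ds, knots, scheme))
        ac = aps.fit(aps.assemble_two_term_design(ds, knots, scheme,
                                                  "cohort"))
        ap = aps.fit(aps.assemble_two_term_design(ds, knots, scheme,
                                                  "period"))
        _, p_drop_cohort = aps.compare_nested(
            full.loglik, ap.loglik, full.n_params - ap.n_params)
        _, p_drop_period = aps.compare_nested(
            full.loglik, ac.loglik, full.n_params - ac.n_params)
        hits_cohort += p_drop_cohort < 0.01
        hits_period += p_drop_period > 0.05
    assert hits_cohort >= 8
    assert hits_period >= 8
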