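import numpy as np
import pandas as pd
import pytest
import scipy.integrate
import scipy.linalg

from panelmsm import (
    FitResult,
    IntensityModel,
    build_generator,
    calibrated_model,
    hazard_ratio_table,
    hazard_ratios,
    occupancy_curves,
    prevalence_gof,
    sojourn_times,
    statetable,
    total_length_of_stay,
    transition_probability,
)
from panelmsm.cohort import simulate_dataset

from conftest import make_plain4, make_two_state, plain4_config


def _fake_fit(model, estimates, vcov):
    lay = model.layout
    return FitResult(
        model=model.with_vector(np.asarray(estimates, dtype=float)),
        estimates=np.asarray(estimates, dtype=float),
        param_names=lay.names,
        loglik=0.0,
        converged=True,
        vcov=vcov,
        n_subjects=0,
        n_observations=0,
        statetable=np.zeros((model.structure.n_states,) * 2, dtype=int),
    )


class TestHazardRatios:
    def test_zero_beta_with_se(self):
        m = make_two_state(q=0.3, beta=0.0)
        fit = _fake_fit(m, [np.log(0.3), 0.0], np.diag([0.0, 0.01]))
        row = hazard_ratios(fit).iloc[0]
        assert row.hr == pytest.approx(1.0)
        assert row.lo95 == pytest.approx(np.exp(-1.959964 * 0.1), abs=1e-6)
        assert row.hi95 == pytest.approx(np.exp(1.959964 * 0.1), abs=1e-6)
        assert round(row.lo95, 2) == 0.82 and round(row.hi95, 2) == 1.22

    def test_degenerate_zero_se(self):
        m = make_two_state(q=0.3, beta=np.log(2.0))
        fit = _fake_fit(m, [np.log(0.3), np.log(2.0)], np.zeros((2, 2)))
        row = hazard_ratios(fit).iloc[0]
        assert (row.hr, row.lo95, row.hi95) == pytest.approx((2.0, 2.0, 2.0))

    def test_missing_vcov_marks_ci_unavailable(self):
        m = make_two_state(q=0.3, beta=0.5)
        fit = _fake_fit(m, [np.log(0.3), 0.5], None)
        row = hazard_ratios(fit).iloc[0]
        assert row.hr == pytest.approx(np.exp(0.5))
        assert np.isnan(row.lo95) and np.isnan(row.hi95)

    def test_cells_are_exactly_exp_beta(self):
        m = calibrated_model()
        x = m.to_vector()
        rng = np.random.default_rng(0)
        x += rng.normal(0, 0.1, len(x))
        fit = _fake_fit(m, x, np.eye(len(x)) * 1e-4)
        tab = hazard_ratios(fit)
        lay = m.layout
        for row in tab.itertuples():
            r, s = row.transition.split("->")
            i = lay.names.index(f"beta[{r}->{s}].{row.covariate}:{row.level}")
            assert row.hr == np.exp(x[i])

    def test_wide_table_has_transition_columns(self):
        m = calibrated_model()
        fit = _fake_fit(m, m.to_vector(), np.eye(m.layout.n_params) * 1e-4)
        wide = hazard_ratio_table(fit)
        for col in ("1->2", "2->1", "2->3", "1->3", "3->4"):
            assert col in wide.columns
        assert ("wealth", "high") in wide.index


class TestOccupancy:
    def test_t_zero_unit_mass(self):
        m = calibrated_model()
        pat = {"education": "low", "occupation": "manual", "wealth": "low"}
        occ = occupancy_curves(m, pat, 60.0, 2, [0.0])
        probs = occ.set_index("state")["probability"]
        assert probs[2] == 1.0 and probs[1] == 0.0

    def test_zero_rate_model_constant(self):
        m = calibrated_model()
        frozen = IntensityModel(
            structure=m.structure,
            spec=m.spec,
            log_q0={},
            zero_rates=frozenset(m.structure.transitions),
        )
        pat = {"education": "low", "occupation": "manual", "wealth": "low"}
        occ = occupancy_curves(frozen, pat, 60.0, 1, [0.0, 5.0, 10.0])
        s1 = occ[occ.state == 1]["probability"]
        assert (s1 == 1.0).all()

    def test_rows_sum_to_one(self):
        m = calibrated_model()
        pat = {"education": "high", "occupation": "professional", "wealth": "high"}
        occ = occupancy_curves(m, pat, 58.0, 1, np.linspace(0, 10, 11))
        sums = occ.groupby("time")["probability"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-8)

    def test_absorption_higher_at_age_80_than_60(self):
        m = calibrated_model()
        pat = {"education": "middle", "occupation": "manual", "wealth": "middle"}
        occ60 = occupancy_curves(m, pat, 60.0, 1, [10.0])
        occ80 = occupancy_curves(m, pat, 80.0, 1, [10.0])
        p4_60 = occ60[occ60.state == 4]["probability"].iloc[0]
        p4_80 = occ80[occ80.state == 4]["probability"].iloc[0]
        assert p4_80 > p4_60

    def test_unknown_level_rejected(self):
        m = calibrated_model()
        with pytest.raises(ValueError, match="unknown level"):
            occupancy_curves(
                m,
                {"education": "none", "occupation": "manual", "wealth": "low"},
                60.0, 1, [0.0, 1.0],
            )


class TestTotalLengthOfStay:
    def test_horizon_zero(self):
        m = calibrated_model()
        pat = {"education": "low", "occupation": "manual", "wealth": "low"}
        np.testing.assert_array_equal(
            total_length_of_stay(m, pat, 60.0, 1, 0.0), np.zeros(4)
        )

    def test_negative_horizon_rejected(self):
        m = calibrated_model()
        pat = {"education": "low", "occupation": "manual", "wealth": "low"}
        with pytest.raises(ValueError):
            total_length_of_stay(m, pat, 60.0, 1, -1.0)

    def test_two_state_closed_form(self):
        m = make_two_state(q=0.5)
        tl = total_length_of_stay(m, {"x": "a"}, 60.0, 1, 10.0)
        assert tl[0] == pytest.approx((1 - np.exp(-5.0)) / 0.5, abs=1e-6)

    def test_conservation(self):
        m = calibrated_model()
        pat = {"education": "high", "occupation": "intermediate", "wealth": "middle"}
        for age in (58.0, 75.0):
            tl = total_length_of_stay(m, pat, age, 1, 10.0)
            assert tl.sum() == pytest.approx(10.0, abs=1e-6)

    def test_nondecreasing_in_horizon(self):
        m = calibrated_model()
        pat = {"education": "low", "occupation": "manual", "wealth": "low"}
        prev = np.zeros(4)
        for T in (1.0, 3.0, 5.0, 10.0):
            tl = total_length_of_stay(m, pat, 63.0, 1, T)
            assert (tl >= prev - 1e-9).all()
            prev = tl

    def test_agrees_with_simpson_rule(self):
        m = calibrated_model()
        pat = {"education": "middle", "occupation": "manual", "wealth": "low"}
        age, T = 58.0, 10.0  # crosses two band boundaries
        grid = np.arange(0.0, T + 1e-12, 0.01)
        rows = np.array(
            [transition_probability(m, pat, age, float(u))[0] for u in grid]
        )
        simpson = scipy.integrate.simpson(rows, x=grid, axis=0)
        tl = total_length_of_stay(m, pat, age, 1, T)
        np.testing.assert_allclose(tl, simpson, atol=1e-6)


class TestTotlosBootstrapCI:
    def test_bootstrap_brackets_point_estimate(self):
        from panelmsm import total_length_of_stay_ci

        m = make_two_state(q=0.5)
        fit = _fake_fit(m, [np.log(0.5), 0.0], np.diag([0.01, 0.01]))
        ci = total_length_of_stay_ci(
            fit, {"x": "a"}, 60.0, 1, 10.0, draws=60, seed=5
        )
        row = ci[ci.state == 1].iloc[0]
        assert row.lo95 < row.expected_years < row.hi95
        assert row.expected_years == pytest.approx((1 - np.exp(-5.0)) / 0.5, abs=1e-6)

    def test_requires_vcov(self):
        from panelmsm import total_length_of_stay_ci

        m = make_two_state(q=0.5)
        fit = _fake_fit(m, [np.log(0.5), 0.0], None)
        with pytest.raises(ValueError, match="covariance"):
            total_length_of_stay_ci(fit, {"x": "a"}, 60.0, 1, 5.0, draws=10)


class TestSojourn:
    def test_reciprocal_rule(self):
        m = make_two_state(q=0.5)
        soj = sojourn_times(m, {"x": "a"}, 60.0)
        assert soj.iloc[0].sojourn_years == pytest.approx(2.0)

    def test_absorbing_state_excluded(self):
        m = calibrated_model()
        pat = {"education": "low", "occupation": "manual", "wealth": "low"}
        soj = sojourn_times(m, pat, 60.0)
        assert set(soj.state) == {1, 2, 3}

    def test_halving_outflow_doubles_sojourn(self):
        m = make_plain4()
        m2 = make_plain4(q0={t: 0.5 * np.exp(v) for t, v in m.log_q0.items()})
        s1 = sojourn_times(m, {}, 60.0).set_index("state")["sojourn_years"]
        s2 = sojourn_times(m2, {}, 60.0).set_index("state")["sojourn_years"]
        np.testing.assert_allclose(s2, 2 * s1, rtol=1e-12)

    def test_ci_present_with_vcov(self):
        m = make_two_state(q=0.5)
        from test_derived import _fake_fit

        fit = _fake_fit(m, [np.log(0.5), 0.0], np.diag([0.04, 0.01]))
        soj = sojourn_times(fit.model, {"x": "a"}, 60.0, fit=fit)
        row = soj.iloc[0]
        assert row.lo95 < row.sojourn_years < row.hi95
        # log-scale delta method: CI = s * exp(+-1.96 * se(log q))
        assert row.hi95 == pytest.approx(2.0 * np.exp(1.959964 * 0.2), rel=1e-3)


class TestPrevalenceGof:
    def test_baseline_expected_equals_observed(self):
        m = make_plain4()
        ds, _, _ = simulate_dataset(m, plain4_config(400, waves=(0, 2, 4), seed=31))
        tab = prevalence_gof(m, ds, [0.0])
        for row in tab.itertuples():
            assert row.observed == pytest.approx(row.expected, abs=1e-12)

    def test_self_consistency_on_simulated_data(self):
        m = make_plain4()
        n = 4000
        ds, _, _ = simulate_dataset(
            m, plain4_config(n, waves=(0, 2, 4, 6, 8, 10), seed=8)
        )
        tab = prevalence_gof(m, ds, [2.0, 4.0, 6.0, 8.0, 10.0])
        for row in tab.itertuples():
            sd = np.sqrt(max(row.expected * (1 - row.expected), 1e-6) / n)
            assert abs(row.observed - row.expected) < 3 * sd + 0.01

    def test_misspecified_dementia_rate_detected(self):
        m = make_plain4()
        ds, _, _ = simulate_dataset(
            m, plain4_config(3000, waves=(0, 2, 4, 6, 8, 10), seed=12)
        )
        q0_bad = {t: np.exp(v) for t, v in m.log_q0.items()}
        q0_bad[(2, 3)] *= 4.0
        q0_bad[(1, 3)] *= 4.0
        bad = make_plain4(q0=q0_bad)
        tab = prevalence_gof(bad, ds, [10.0])
        dem = tab[tab.state == 3].iloc[0]
        assert dem.expected > dem.observed

    def test_rows_sum_to_one(self):
        m = make_plain4()
        ds, _, _ = simulate_dataset(m, plain4_config(300, waves=(0, 2, 4), seed=2))
        tab = prevalence_gof(m, ds, [0.0, 2.0, 4.0])
        for t, grp in tab.groupby("time"):
            assert grp["observed"].sum() == pytest.approx(1.0, abs=1e-9)
            assert grp["expected"].sum() == pytest.approx(1.0, abs=1e-8)
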