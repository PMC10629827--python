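"""Uptake kinetics: model evaluation, lag time, fitting, model comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rohflux.uptake import (
    ModelComparison,
    Timecourse,
    UptakeError,
    UptakeParams1,
    UptakeParams2,
    compare_models,
    fit_uptake,
    free_contribution_fraction,
    lag_time,
    model1_predict,
    model2_predict,
)

P2 = UptakeParams2(Kp=90.0, k1=0.05, Kp_star=90.0, k1_star=0.02, c_star=36.0)


class TestModelEvaluation:
    def test_single_phase_scalar_value(self):
        # plain-arithmetic oracle: 0.1 * 90 * (1 - e^-0.9)
        expected = 0.1 * 90.0 * (1.0 - math.exp(-0.03 * 30))
        assert model1_predict(30.0, 0.1, UptakeParams1(90.0, 0.03)) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(5.3409, abs=1e-4)

    def test_starts_at_zero_saturates_at_partition_limit(self):
        p = UptakeParams1(90.0, 0.05)
        assert model1_predict(0.0, 2.0, p) == 0.0
        assert model1_predict(1e6, 2.0, p) == pytest.approx(180.0, rel=1e-9)

    def test_lag_time_closed_form(self):
        expected = -math.log(1.0 - 36.0 / (90.0 * 2.0)) / 0.05
        assert lag_time(36.0, 90.0, 2.0, 0.05) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(4.4629, abs=1e-4)

    def test_lag_time_boundaries(self):
        assert lag_time(0.0, 90.0, 2.0, 0.05) == 0.0
        assert lag_time(180.0, 90.0, 2.0, 0.05) == math.inf
        assert lag_time(200.0, 90.0, 2.0, 0.05) == math.inf
        with pytest.raises(UptakeError):
            lag_time(-1.0, 90.0, 2.0, 0.05)

    def test_biphasic_scalar_value(self):
        # independent scalar arithmetic of both phases at t = 120 min
        tlag = -math.log(1.0 - 36.0 / 180.0) / 0.05
        first = 2.0 * 90.0 * (1.0 - math.exp(-0.05 * 120.0))
        second = 2.0 * 90.0 * (1.0 - math.exp(-0.02 * (120.0 - tlag)))
        assert model2_predict(120.0, 2.0, P2) == pytest.approx(first + second, rel=1e-12)
        assert first + second == pytest.approx(341.70, abs=0.01)

    def test_reduces_to_single_phase_when_second_amplitude_zero(self):
        p = UptakeParams2(90.0, 0.05, 0.0, 0.02, 36.0)
        t = np.linspace(0.0, 120.0, 50)
        np.testing.assert_allclose(
            model2_predict(t, 2.0, p), model1_predict(t, 2.0, UptakeParams1(90.0, 0.05))
        )

    def test_continuous_at_lag_time(self):
        tlag = P2.t_lag(2.0)
        eps = 1e-9
        below = model2_predict(tlag - eps, 2.0, P2)
        at = model2_predict(tlag, 2.0, P2)
        above = model2_predict(tlag + eps, 2.0, P2)
        assert at == pytest.approx(below, abs=1e-6)
        assert at == pytest.approx(above, abs=1e-6)

    def test_inactive_second_phase_below_threshold(self):
        # at 0.1 µM fluid the plateau (9 µM) never reaches c* = 36 µM
        t = np.linspace(0.0, 500.0, 100)
        np.testing.assert_allclose(
            model2_predict(t, 0.1, P2),
            model1_predict(t, 0.1, UptakeParams1(90.0, 0.05)),
        )

    @given(
        cf=st.floats(0.05, 5.0),
        kp=st.floats(0.1, 200.0),
        k1=st.floats(1e-3, 0.5),
        kps=st.floats(0.0, 200.0),
        k1s=st.floats(1e-3, 0.5),
        cs=st.floats(0.0, 300.0),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_nonnegative_and_monotone(self, cf, kp, k1, kps, k1s, cs):
        p = UptakeParams2(kp, k1, kps, k1s, cs)
        t = np.linspace(0.0, 240.0, 97)
        y = model2_predict(t, cf, p)
        assert np.all(y >= 0.0)
        assert np.all(np.diff(y) >= -1e-9)

    @given(cf=st.floats(0.05, 5.0), kp=st.floats(0.1, 200.0), k1=st.floats(1e-3, 0.5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_single_phase_is_homogeneous_in_fluid_concentration(self, cf, kp, k1):
        # normalized model-1 curves are concentration-independent; the
        # threshold model deliberately breaks this, which is what makes
        # the normalized curves fan out at higher concentrations
        p = UptakeParams1(kp, k1)
        t = np.linspace(0.0, 240.0, 49)
        np.testing.assert_allclose(
            model1_predict(t, 2 * cf, p), 2 * model1_predict(t, cf, p), rtol=1e-9
        )


class TestFitting:
    def _noise_free(self, truth, c_fluids=(0.1, 0.4, 2.0)):
        t = np.arange(0.0, 121.0, 5.0)
        predict = model2_predict if isinstance(truth, UptakeParams2) else model1_predict
        return [
            Timecourse(f"{cf:g}", cf, t, predict(t, cf, truth)[None, :])
            for cf in c_fluids
        ]

    def test_noise_free_single_phase_recovered_exactly(self):
        truth = UptakeParams1(90.0, 0.05)
        fit = fit_uptake(self._noise_free(truth), model=1, seed=0)
        assert fit.params["Kp"] == pytest.approx(90.0, rel=1e-6)
        assert fit.params["k1"] == pytest.approx(0.05, rel=1e-6)
        assert fit.ssr < 1e-12

    def test_noise_free_biphasic_recovered(self):
        fit = fit_uptake(self._noise_free(P2), model=2, seed=0)
        assert fit.params["c_star"] == pytest.approx(36.0, rel=1e-3)
        assert fit.params["Kp"] == pytest.approx(90.0, rel=1e-4)
        assert fit.t_lag["2"] == pytest.approx(P2.t_lag(2.0), rel=1e-3)
        assert math.isinf(fit.t_lag["0.1"])

    def test_single_phase_fit_never_beats_biphasic_on_biphasic_data(self):
        tcs = self._noise_free(P2)
        f1 = fit_uptake(tcs, model=1, seed=0)
        f2 = fit_uptake(tcs, model=2, seed=0)
        assert f1.ssr > f2.ssr

    def test_per_condition_fitting_returns_dict(self):
        truth = UptakeParams1(90.0, 0.05)
        fits = fit_uptake(self._noise_free(truth), model=1, shared=False, seed=0)
        assert set(fits) == {"0.1", "0.4", "2"}
        for f in fits.values():
            assert f.params["Kp"] == pytest.approx(90.0, rel=1e-4)

    def test_too_few_time_points_rejected(self):
        tc = Timecourse("x", 1.0, [0.0, 5.0, 10.0], [[0.0, 1.0, 2.0]])
        with pytest.raises(UptakeError, match="fewer than 4"):
            fit_uptake([tc], model=1)


class TestModelComparison:
    def test_identical_fits_give_f_zero_p_one(self):
        tcs = [
            Timecourse("a", 1.0, np.arange(0, 60, 5.0),
                       model1_predict(np.arange(0, 60, 5.0), 1.0, UptakeParams1(50, 0.05))[None, :]
                       + 0.01)
        ]
        f1 = fit_uptake(tcs, model=1, seed=0)
        f2 = fit_uptake(tcs, model=2, seed=0)
        cmp_ = compare_models(f1, f2)
        if f1.ssr == pytest.approx(f2.ssr, rel=1e-6):
            assert cmp_.p_value > 0.5

    def test_non_nested_inputs_rejected(self):
        tcs = [
            Timecourse("a", 1.0, np.arange(0, 60, 5.0),
                       np.arange(12.0)[None, :])
        ]
        f1 = fit_uptake(tcs, model=1, seed=0)
        with pytest.raises(UptakeError):
            compare_models(f1, f1)

    def test_biphasic_data_strongly_rejects_single_phase(self, rng):
        t = np.arange(0.0, 121.0, 5.0)
        tcs = []
        for cf in (0.1, 0.4, 2.0):
            mu = model2_predict(t, cf, P2)
            reps = mu[None, :] * (1 + 0.05 * rng.standard_normal((3, t.size)))
            tcs.append(Timecourse(f"{cf:g}", cf, t, np.clip(reps, 0, None)))
        f1 = fit_uptake(tcs, model=1, seed=0, n_starts=5)
        f2 = fit_uptake(tcs, model=2, seed=0, n_starts=5)
        cmp_ = compare_models(f1, f2)
        assert cmp_.p_value < 1e-6
        assert cmp_.aic2 < cmp_.aic1


class TestFreeContribution:
    def test_identical_inputs_are_100_percent(self):
        t = np.arange(0.0, 121.0, 5.0)
        y = model1_predict(t, 0.4, UptakeParams1(90, 0.05))
        tc = Timecourse("a", 0.4, t, y[None, :])
        times, pct = free_contribution_fraction(tc, tc)
        np.testing.assert_allclose(pct, 100.0)
        assert times[0] > 0.0  # zero-denominator point at t=0 omitted

    def test_zero_free_accumulation_is_0_percent(self):
        t = np.arange(0.0, 61.0, 5.0)
        free = Timecourse("f", 0.4, t, np.zeros((1, t.size)))
        bound = Timecourse("b", 2.0, t, np.linspace(0, 50, t.size)[None, :])
        _, pct = free_contribution_fraction(free, bound)
        np.testing.assert_allclose(pct, 0.0)

    def test_known_ratio_recovered_with_interpolation(self):
        tb = np.arange(0.0, 121.0, 5.0)
        tf = np.arange(0.0, 121.0, 2.5)  # finer grid, linear curve: exact interp
        bound = Timecourse("b", 2.0, tb, (2.0 * tb)[None, :])
        free = Timecourse("f", 0.4, tf, (1.0 * tf)[None, :])
        _, pct = free_contribution_fraction(free, bound)
        np.testing.assert_allclose(pct, 50.0, rtol=1e-9)


def test_invalid_timecourse_rejected():
    with pytest.raises(UptakeError):
        Timecourse("x", 1.0, [0.0, 5.0, 5.0], [[0, 1, 2]])
    with pytest.raises(UptakeError):
        Timecourse("x", 1.0, [0.0, 5.0], [[0, -1]])
    with pytest.raises(UptakeError):
        UptakeParams2(1, 1, 1, 1, -1)
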