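"""Quantification chain: SG filter, S0 baseline, normalization, MTR, AUC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dyncest import dynamics, schedule as sched
from dyncest.dynamics import mtr_curve, sg_filter

from conftest import make_series


class TestSGFilter:
    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=40))
    def test_window3_order2_is_identity(self, values):
        np.testing.assert_allclose(sg_filter(np.array(values), 3, 2), values,
                                   atol=1e-9)

    def test_reproduces_quadratics(self):
        x = np.arange(20.0)
        y = 0.3 * x**2 - 2 * x + 5
        np.testing.assert_allclose(sg_filter(y, 7, 2), y, atol=1e-8)

    def test_constant_preserved(self):
        np.testing.assert_allclose(sg_filter(np.full(11, 4.2), 5, 2), 4.2)

    @pytest.mark.parametrize("window, order, n", [(4, 2, 10), (3, 3, 10), (5, 2, 3)])
    def test_invalid_parameters_rejected(self, window, order, n):
        with pytest.raises(ValueError):
            sg_filter(np.zeros(n), window, order)


@pytest.fixture
def flat_series(tiny_fl1):
    return make_series(tiny_fl1, lambda e, t: 1.0)


class TestS0Baseline:
    def test_constant_signal_gives_constant_baseline(self, flat_series):
        base = dynamics.build_s0_baseline(flat_series)
        np.testing.assert_allclose(base.s0_sg_values, 2.0)

    def test_linear_drift_reproduced(self, tiny_fl1):
        series = make_series(tiny_fl1, lambda e, t: 1.0 + 0.01 * t)
        base = dynamics.build_s0_baseline(series)
        t_min = base.times_s / 60.0
        inner = (t_min > t_min.min() + 2) & (t_min < t_min.max() - 2)
        np.testing.assert_allclose(base.s0_sg_values[inner],
                                   2.0 * (1 + 0.01 * t_min[inner]), rtol=1e-6)

    def test_dummy_entries_excluded(self, tiny_fl1):
        # dummies carry a wild value; the baseline must ignore it
        series = make_series(
            tiny_fl1, lambda e, t: 50.0 if e.role == "dummy" else 1.0)
        base = dynamics.build_s0_baseline(series)
        np.testing.assert_allclose(base.s0_sg_values, 2.0)

    def test_too_few_s0_entries_rejected(self, timing):
        fl1 = sched.build_fl1(timing, n_dummy=0, n_cycles=1)
        series = make_series(fl1, lambda e, t: 1.0)
        series.entries = [e for e in series.entries if e.role != "s0"][:3]
        series.images = series.images[:3]
        with pytest.raises(ValueError):
            dynamics.build_s0_baseline(series)


class TestNormalize:
    def test_equal_signal_gives_unit_z(self, flat_series):
        base = dynamics.build_s0_baseline(flat_series)
        tidy = dynamics.normalize(flat_series, base)
        np.testing.assert_allclose(tidy["Z"], 1.0)

    def test_fractional_attenuation(self, tiny_fl1):
        series = make_series(
            tiny_fl1, lambda e, t: 0.99 if e.role == "measure" else 1.0)
        base = dynamics.build_s0_baseline(series)
        np.testing.assert_allclose(dynamics.normalize(series, base)["Z"], 0.99)

    def test_multiplicative_drift_cancels(self, tiny_fl1):
        """A global multiplicative drift common to S and S0 is the artifact
        the normalization exists to remove."""
        z_meas = 0.95
        drifty = make_series(
            tiny_fl1,
            lambda e, t: (z_meas if e.role == "measure" else 1.0) * (1 - 0.003 * t))
        base = dynamics.build_s0_baseline(drifty)
        tidy = dynamics.normalize(drifty, base)
        # beyond the last S0 image the baseline holds its boundary value, so
        # cancellation is only guaranteed inside the S0-bracketed range
        last_s0_min = max(e.t_mid_s for e in drifty.entries if e.role == "s0") / 60
        z = tidy[tidy["time_min"] <= last_s0_min]["Z"].to_numpy()
        np.testing.assert_allclose(z, z_meas, rtol=1e-4)

    def test_only_retained_entries_reported(self, flat_series):
        base = dynamics.build_s0_baseline(flat_series)
        tidy = dynamics.normalize(flat_series, base)
        n_retained = sum(1 for e in flat_series.entries
                         if e.role == "measure" and e.retain)
        assert len(tidy) == n_retained


class TestMTRCurve:
    def test_constant_z_gives_zero_mtr(self):
        t = np.arange(10.0)
        c = mtr_curve(np.full(10, 0.9), t, injection_start_min=5.0)
        np.testing.assert_allclose(c.mtr_values, 0.0)

    def test_signal_loss_is_positive_mtr(self):
        t = np.arange(10.0)
        z = np.where(t < 5, 0.90, 0.90 - 0.013)
        c = mtr_curve(z, t, injection_start_min=5.0)
        assert c.mtr_values[-1] == pytest.approx(0.013)

    def test_pre_injection_mean_is_zero(self):
        rng = np.random.default_rng(7)
        t = np.arange(40.0)
        z = 0.9 + 0.01 * rng.standard_normal(40)
        c = mtr_curve(z, t, injection_start_min=20.0)
        assert abs(c.mtr_values[t < 20].mean()) < 1e-14

    def test_pre_window_restriction(self):
        t = np.arange(10.0)
        z = np.where(t < 3, 2.0, 1.0)  # early pre-steady-state excursion
        c = mtr_curve(z, t, injection_start_min=8.0, pre_window_min=(3.0, 8.0))
        assert c.z_pre_avg == pytest.approx(1.0)

    def test_no_pre_injection_points_rejected(self):
        with pytest.raises(ValueError):
            mtr_curve(np.ones(5), np.arange(5.0) + 10, injection_start_min=5.0)


class TestPixelwiseAUC:
    def test_zero_mtr_gives_zero_map(self, flat_series):
        amap = dynamics.pixelwise_auc(flat_series, (2.0, 6.0), -2.7)
        np.testing.assert_allclose(amap.values, 0.0, atol=1e-12)

    def test_constant_mtr_rectangle(self, timing):
        fl1 = sched.build_fl1(timing, n_dummy=2, n_cycles=40)
        inj = timing.injection_start_min

        def z(e, t):
            if e.role != "measure":
                return 1.0
            return 1.0 - (0.01 if t >= inj else 0.0)

        series = make_series(fl1, z)
        amap = dynamics.pixelwise_auc(series, (30.0, 45.0), -2.7)
        np.testing.assert_allclose(amap.values, 0.01 * 15.0, rtol=1e-10)

    def test_additive_over_adjacent_windows_and_linear(self, timing):
        fl1 = sched.build_fl1(timing, n_dummy=2, n_cycles=40)
        rng = np.random.default_rng(3)
        bumps = {}

        def z(e, t):
            if e.role != "measure":
                return 1.0
            return 1.0 - bumps.setdefault(round(t, 6), 0.01 * rng.random())

        series = make_series(fl1, z)
        a = dynamics.pixelwise_auc(series, (30, 38), -2.7).values
        b = dynamics.pixelwise_auc(series, (38, 44), -2.7).values
        ab = dynamics.pixelwise_auc(series, (30, 44), -2.7).values
        np.testing.assert_allclose(a + b, ab, rtol=1e-10)
        series2 = series
        series2.images = 2.0 * (series.images - 2.0) + 2.0  # doubles the MTR
        a2 = dynamics.pixelwise_auc(series2, (30, 38), -2.7).values
        np.testing.assert_allclose(a2, 2 * a, rtol=1e-8)

    def test_window_outside_scan_rejected(self, flat_series):
        with pytest.raises(ValueError):
            dynamics.pixelwise_auc(flat_series, (500.0, 600.0), -2.7)
        with pytest.raises(ValueError):
            dynamics.pixelwise_auc(flat_series, (20.0, 20.0), -2.7)


class TestGroupAverage:
    def _curve(self, mtr, label=""):
        t = np.arange(len(mtr), dtype=float)
        return dynamics.MTRCurve(t, 1 - np.asarray(mtr, float), 1.0,
                                 np.asarray(mtr, float), label)

    def test_identical_curves_have_zero_sd(self):
        c = self._curve(np.linspace(0, 0.01, 12))
        g = dynamics.group_average([c, c, c])
        np.testing.assert_allclose(g.sd, 0.0, atol=1e-15)
        np.testing.assert_allclose(g.mean, c.mtr_values)

    def test_single_curve_sd_flagged_nan(self):
        g = dynamics.group_average([self._curve(np.zeros(8))])
        assert np.all(np.isnan(g.sd))
        assert g.n == 1

    def test_mismatched_grids_rejected(self):
        a = self._curve(np.zeros(8))
        b = self._curve(np.zeros(9))
        with pytest.raises(ValueError):
            dynamics.group_average([a, b])

    def test_display_smoothing_uses_window7(self):
        rng = np.random.default_rng(0)
        c = [self._curve(rng.standard_normal(30) * 0.01) for _ in range(4)]
        g = dynamics.group_average(c)
        np.testing.assert_allclose(g.smoothed, sg_filter(g.mean, 7, 2))
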