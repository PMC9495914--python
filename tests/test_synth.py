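"""Synthetic-study generator: phantom, uptake model, rendered series, truth."""

import numpy as np
import pytest

from dyncest import bmc, dynamics, schedule as sched, synth


class TestPhantom:
    def test_masks_nonempty_and_disjoint(self):
        ph = synth.make_liver_phantom()
        assert ph.masks["liver"].any()
        assert not (ph.masks["liver"] & ph.masks["background"]).any()
        assert (ph.masks["liver"] | ph.masks["background"]).all()

    def test_liver_area_fraction(self):
        for seed in range(5):
            frac = synth.make_liver_phantom(seed=seed).masks["liver"].mean()
            assert 0.2 <= frac <= 0.4

    def test_deterministic_given_seed(self):
        a = synth.make_liver_phantom(seed=11)
        b = synth.make_liver_phantom(seed=11)
        np.testing.assert_array_equal(a.masks["liver"], b.masks["liver"])
        np.testing.assert_array_equal(a.baseline, b.baseline)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            synth.make_liver_phantom(grid=8)


class TestUptakeModel:
    def test_zero_before_injection(self):
        m = synth.UptakeModel()
        t = np.array([0.0, 10.0, 22.99, 23.0])
        np.testing.assert_array_equal(synth.uptake_fraction_at(t, m), 0.0)

    def test_spike_peaks_at_stated_delay(self):
        m = synth.UptakeModel(accumulation_slope_mtr_per_min=0.0)
        t = np.linspace(23.0, 60.0, 2000)
        resp = synth.uptake_fraction_at(t, m)
        t_peak = t[np.argmax(resp)]
        assert t_peak == pytest.approx(23.0 + m.spike_peak_delay_min, abs=0.05)
        assert resp.max() == pytest.approx(m.spike_amplitude_mtr, rel=1e-4)

    def test_control_model_is_identically_zero(self):
        m = synth.UptakeModel.control()
        t = np.linspace(0, 120, 500)
        np.testing.assert_array_equal(synth.uptake_fraction_at(t, m), 0.0)

    def test_continuous_at_injection(self):
        m = synth.UptakeModel()
        eps = 1e-6
        assert synth.uptake_fraction_at(23.0 + eps, m) < 1e-8

    def test_width_override_sets_fwhm(self):
        m = synth.UptakeModel(spike_width_min=5.0, accumulation_slope_mtr_per_min=0.0)
        t = np.linspace(23, 80, 20000)
        resp = synth.uptake_fraction_at(t, m)
        above = t[resp >= resp.max() / 2]
        assert above[-1] - above[0] == pytest.approx(5.0, rel=0.05)


class TestCalibration:
    def test_fraction_for_mtr_hits_target(self, water, field):
        pools = [water, bmc.thiol_pool(fraction=0.0)]
        train = bmc.SaturationTrain(bmc.SaturationPulse(), n_pulses=50)
        target = 0.005
        f = synth.fraction_for_mtr(target, pools, train, field)
        z0 = bmc.simulate_pulse_train(pools, train, -2.7, field)
        z1 = bmc.simulate_pulse_train(
            [water, bmc.thiol_pool(fraction=f)], train, -2.7, field)
        assert z0 - z1 == pytest.approx(target, abs=1e-9)

    def test_zero_target_needs_no_fraction(self, water, field):
        train = bmc.SaturationTrain(bmc.SaturationPulse(), n_pulses=10)
        assert synth.fraction_for_mtr(0.0, [water, bmc.thiol_pool(0.0)], train,
                                      field) == 0.0


@pytest.fixture(scope="module")
def small_fl1():
    return sched.build_fl1(n_dummy=2, n_cycles=30)


class TestGenerateSeries:
    def test_deterministic_bit_identical(self, small_fl1):
        kw = dict(schedule=small_fl1, uptake=synth.UptakeModel(),
                  artifacts=synth.ArtifactModel(), noise=synth.NoiseModel(),
                  phantom=synth.make_liver_phantom(32, 5), seed=5)
        a = synth.generate_series(**kw)
        b = synth.generate_series(**kw)
        np.testing.assert_array_equal(a.images, b.images)

    def test_null_study_has_identically_zero_mtr(self, small_fl1):
        series = synth.generate_series(
            small_fl1, synth.UptakeModel.control(), synth.ArtifactModel.none(),
            synth.NoiseModel.none(), phantom=synth.make_liver_phantom(32, 0), seed=0)
        curves = dynamics.roi_mtr_curves(series)
        for c in curves.values():
            np.testing.assert_allclose(c.mtr_values, 0.0, atol=1e-12)

    def test_noiseless_roundtrip_recovers_injection(self, small_fl1):
        series = synth.generate_series(
            small_fl1, synth.UptakeModel(), synth.ArtifactModel.none(),
            synth.NoiseModel.none(), phantom=synth.make_liver_phantom(32, 1), seed=1)
        curves = dynamics.roi_mtr_curves(series)
        for offset, curve in curves.items():
            _, mtr_true = series.truth.for_offset(offset)
            assert np.abs(curve.mtr_values - mtr_true).max() < 1e-8

    def test_counts_and_nonnegativity(self, small_fl1):
        series = synth.generate_series(
            small_fl1, synth.UptakeModel(), synth.ArtifactModel(), synth.NoiseModel(),
            phantom=synth.make_liver_phantom(32, 2), seed=2)
        assert len(series.images) == len(series.entries) == len(small_fl1)
        assert np.all(series.images >= 0)

    def test_rician_background_noise_floor(self, small_fl1):
        """Magnitude noise on empty background pixels is Rayleigh with mean
        sigma * sqrt(pi/2)."""
        noise = synth.NoiseModel(sigma_frac=0.01)
        ph = synth.make_liver_phantom(32, 3)
        series = synth.generate_series(
            small_fl1, synth.UptakeModel.control(), synth.ArtifactModel.none(),
            noise, phantom=ph, seed=3)
        sigma_abs = noise.sigma_frac * ph.baseline[ph.masks["liver"]].mean()
        bg = series.images[:, ph.masks["background"]]
        assert bg.mean() == pytest.approx(sigma_abs * np.sqrt(np.pi / 2), rel=0.02)

    def test_motion_term_inflates_late_control_mtr(self, small_fl1):
        artifacts = synth.ArtifactModel(0.0, 0.0, motion_onset_min=20.0,
                                        motion_amplitude_mtr=0.005,
                                        motion_full_scale_min=40.0)
        series = synth.generate_series(
            small_fl1, synth.UptakeModel.control(), artifacts,
            synth.NoiseModel.none(), phantom=synth.make_liver_phantom(32, 4), seed=4)
        c = dynamics.roi_mtr_curves(series)[-2.7]
        late = c.mtr_values[c.times_min > 35].mean()
        assert late == pytest.approx(0.005 * np.clip((c.times_min[c.times_min > 35].mean() - 20) / 20, 0, None), rel=0.15)

    def test_missing_tracked_pool_rejected(self, small_fl1, water):
        with pytest.raises(ValueError):
            synth.generate_series(
                small_fl1, synth.UptakeModel(), synth.ArtifactModel.none(),
                synth.NoiseModel.none(), pools=[water],
                phantom=synth.make_liver_phantom(32, 0), seed=0)


class TestZSpectrumScan:
    def test_uniform_shift_moves_minimum(self):
        offsets = sched.build_full_zspec_list(2.0, 0.2)
        ph = synth.make_liver_phantom(24, 0)
        scan = synth.generate_zspectrum_scan(offsets, phantom=ph, b0_shift_ppm=0.4)
        liver = scan.masks["liver"]
        z = np.array([img[liver].mean() for img in scan.images[1:]])
        assert offsets[np.argmin(z)] == pytest.approx(0.4, abs=0.21)

    def test_deterministic_with_noise(self):
        offsets = sched.build_full_zspec_list(1.0, 0.5)
        kw = dict(phantom=synth.make_liver_phantom(24, 0),
                  noise=synth.NoiseModel(0.01), seed=9)
        a = synth.generate_zspectrum_scan(offsets, **kw)
        b = synth.generate_zspectrum_scan(offsets, **kw)
        np.testing.assert_array_equal(a.images, b.images)
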