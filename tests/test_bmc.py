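"""Bloch-McConnell core: matrix structure, steady-state oracle, pulse train."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dyncest import bmc


class TestExchangeMatrix:
    def test_two_pool_structure(self, water, thiol, field):
        A, b = bmc.build_exchange_matrix([water, thiol], -2.7, 1.2, field)
        assert A.shape == (6, 6)
        k = thiol.k_exch_per_s
        # off-diagonal exchange blocks are +k terms
        assert A[0, 3] == pytest.approx(k)
        assert A[3, 0] == pytest.approx(thiol.fraction * k)
        # solute transverse diagonal includes -(1/T2 + k)
        assert A[3, 3] == pytest.approx(-(1.0 / thiol.T2_s + k))
        # water z recovery term
        assert b[2] == pytest.approx(1.0 / water.T1_s)

    def test_zero_fraction_decouples_water(self, water, field):
        """With fraction 0 the water block reduces to the single-pool Bloch
        matrix and the solute (which holds no magnetization) never feeds it:
        the water dynamics are exactly single-pool."""
        ghost = bmc.thiol_pool(fraction=0.0)
        A2, b2 = bmc.build_exchange_matrix([water, ghost], 1.0, 1.2, field)
        A1, b1 = bmc.build_exchange_matrix([water], 1.0, 1.2, field)
        np.testing.assert_allclose(A2[:3, :3], A1)
        np.testing.assert_allclose(b2[:3], b1)
        z2 = bmc.steady_state_cw([water, ghost], 1.0, 1.2, field)
        z1 = bmc.steady_state_cw([water], 1.0, 1.2, field)
        assert z2 == pytest.approx(z1, abs=1e-12)

    def test_exchange_conserves_z_flow(self, water, thiol, field):
        """The k-only terms move z-magnetization between pools without loss:
        each column of the exchange part sums to zero."""
        A, _ = bmc.build_exchange_matrix([water, thiol], 0.5, 1.0, field)
        no_k = bmc.Pool("thiol", thiol.delta_ppm, thiol.T1_s, thiol.T2_s,
                        thiol.fraction, 0.0)
        A0, _ = bmc.build_exchange_matrix([water, no_k], 0.5, 1.0, field)
        D = A - A0
        np.testing.assert_allclose(D.sum(axis=0), 0.0, atol=1e-12)

    @pytest.mark.parametrize("pools", [
        [],
        [bmc.thiol_pool()],
        "two_waters",
    ])
    def test_water_pool_required_and_unique(self, pools, field, water):
        if pools == "two_waters":
            pools = [water, bmc.Pool("water", 0.0, 1.0, 0.5, 1.0)]
        with pytest.raises(ValueError):
            bmc.build_exchange_matrix(pools, 0.0, 1.2, field)

    def test_invalid_pool_parameters_rejected(self):
        with pytest.raises(ValueError):
            bmc.Pool("x", 1.0, 1.0, 2.0, 1e-4)  # T2 > T1
        with pytest.raises(ValueError):
            bmc.Pool("x", 1.0, -1.0, 0.5, 1e-4)
        with pytest.raises(ValueError):
            bmc.Pool("x", 1.0, 1.0, 0.5, -1e-4)
        with pytest.raises(ValueError):
            bmc.Pool("water", 1.0, 1.0, 0.5, 1.0)  # shifted water


class TestSteadyState:
    def test_no_saturation_gives_unity(self, water, thiol, field):
        assert bmc.steady_state_cw([water, thiol], -2.7, 0.0, field) == pytest.approx(1.0)

    def test_far_off_resonance_is_unsaturated(self, water, field):
        z = bmc.steady_state_cw([water], 333.0, 1.2, field)
        assert z == pytest.approx(1.0, abs=1e-3)

    def test_solute_pool_deepens_saturation(self, water, thiol, field):
        z1 = bmc.steady_state_cw([water], -2.7, 1.2, field)
        z2 = bmc.steady_state_cw([water, thiol], -2.7, 1.2, field)
        assert z2 < z1

    def test_monotone_in_fraction(self, water, field):
        zs = [bmc.steady_state_cw([water, bmc.thiol_pool(fraction=f)], -2.7, 1.2, field)
              for f in (0.0, 1e-4, 3e-4, 1e-3)]
        assert all(a > b for a, b in zip(zs, zs[1:]))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        offset=st.floats(-5, 5),
        b1=st.floats(0.1, 5.0),
        f=st.floats(0, 1e-3),
        k=st.floats(0, 3000),
    )
    def test_z_is_physical(self, offset, b1, f, k):
        field = bmc.FieldParams()
        pools = [bmc.water_pool(), bmc.Pool("s", -2.7, 1.0, 0.02, f, k)]
        z = bmc.steady_state_cw(pools, offset, b1, field)
        assert -1e-9 <= z <= 1.0 + 1e-9


class TestPulseTrain:
    def test_cw_limit_matches_steady_state(self, water, thiol, amide, field):
        train = bmc.SaturationTrain(bmc.SaturationPulse("cw", 1.2, 0.1),
                                    n_pulses=600, interpulse_delay_s=0.0)
        for pools in ([water, thiol], [water, thiol, amide]):
            z_ss = bmc.steady_state_cw(pools, -2.7, 1.2, field)
            z_tr = bmc.simulate_pulse_train(pools, train, -2.7, field)
            assert z_tr == pytest.approx(z_ss, abs=1e-6)

    def test_no_solute_far_off_resonance(self, water, field):
        ghost = bmc.thiol_pool(fraction=0.0)
        train = bmc.SaturationTrain(bmc.SaturationPulse(), n_pulses=50)
        z = bmc.simulate_pulse_train([water, ghost], train, 333.0, field)
        assert z == pytest.approx(1.0, abs=1e-3)

    def test_substep_convergence(self, water, thiol, field):
        train = bmc.SaturationTrain(bmc.SaturationPulse(), n_pulses=302)
        z1 = bmc.simulate_pulse_train([water, thiol], train, -2.7, field)
        z2 = bmc.simulate_pulse_train([water, thiol], train, -2.7, field,
                                      substep_s=0.5e-4)
        assert abs(z1 - z2) < 1e-6

    def test_oversized_substep_rejected(self, water, field, short_train):
        with pytest.raises(ValueError):
            bmc.simulate_pulse_train([water], short_train, 0.0, field, substep_s=1.0)

    def test_deterministic(self, water, thiol, field, short_train):
        z1 = bmc.simulate_pulse_train([water, thiol], short_train, -2.7, field)
        z2 = bmc.simulate_pulse_train([water, thiol], short_train, -2.7, field)
        assert z1 == z2


class TestZSpectrum:
    def test_single_pool_spectrum_is_even(self, water, field, short_train):
        offsets = np.arange(-4, 4.5, 0.5)
        zs = bmc.zspectrum([water], offsets, short_train, field)
        np.testing.assert_allclose(zs.z_values, zs.z_values[::-1], atol=1e-9)

    def test_thiol_breaks_symmetry_upfield(self, water, thiol, field, short_train):
        offsets = np.arange(-4, 4.5, 0.5)
        zs = bmc.zspectrum([water, thiol], offsets, short_train, field)
        up = zs.z_values[offsets < -1].min()
        down = zs.z_values[offsets > 1].min()
        assert up < down

    def test_default_full_grid_has_51_offsets(self, water, field, short_train):
        from dyncest.schedule import build_full_zspec_list
        offsets = build_full_zspec_list()
        assert len(offsets) == 51
        zs = bmc.zspectrum([water], offsets, short_train, field)
        assert len(zs.z_values) == 51

    def test_empty_offsets_rejected(self, water, field, short_train):
        with pytest.raises(ValueError):
            bmc.zspectrum([water], [], short_train, field)

    def test_solute_never_increases_z_off_resonance(self, water, thiol, field, short_train):
        """Saturation transfer only removes water signal wherever the water is
        less saturated than the solute, i.e. everywhere outside the direct-
        saturation core (within it, exchange can marginally return
        magnetization from the less-saturated solute)."""
        offsets = np.array([-5, -4, -3, -2, -1, 1, 2, 3, 4, 5], float)
        z0 = bmc.zspectrum([water], offsets, short_train, field).z_values
        z1 = bmc.zspectrum([water, thiol], offsets, short_train, field).z_values
        assert np.all(z1 <= z0 + 1e-12)

    def test_noiseless_z_in_unit_interval(self, water, thiol, field, short_train):
        offsets = np.arange(-5, 5.5, 1.0)
        z = bmc.zspectrum([water, thiol], offsets, short_train, field).z_values
        assert np.all((z >= 0) & (z <= 1 + 1e-12))


class TestMTRProfile:
    def test_identical_spectra_give_zero(self, water, field, short_train):
        offsets = np.arange(-4, 4.5, 0.5)
        zs = bmc.zspectrum([water], offsets, short_train, field)
        np.testing.assert_array_equal(bmc.mtr_profile(zs, zs), 0.0)

    def test_thiol_phantom_peak_at_minus_2p7(self, water, field, short_train):
        offsets = np.arange(-4.3, -1.0, 0.4)
        z0 = bmc.zspectrum([water], offsets, short_train, field)
        z1 = bmc.zspectrum([water, bmc.thiol_pool(fraction=2e-3)], offsets,
                           short_train, field)
        prof = bmc.mtr_profile(z0, z1)
        assert offsets[np.argmax(prof)] == pytest.approx(-2.7, abs=0.21)

    def test_profile_peak_monotone_in_fraction(self, water, field, short_train):
        offsets = np.array([-3.1, -2.7, -2.3])
        z0 = bmc.zspectrum([water], offsets, short_train, field)
        peaks = []
        for f in (1e-4, 3e-4, 1e-3):
            z1 = bmc.zspectrum([water, bmc.thiol_pool(fraction=f)], offsets,
                               short_train, field)
            peaks.append(bmc.mtr_profile(z0, z1).max())
        assert peaks[0] < peaks[1] < peaks[2]

    def test_grid_mismatch_rejected(self, water, field, short_train):
        z1 = bmc.zspectrum([water], [-1, 0, 1], short_train, field)
        z2 = bmc.zspectrum([water], [-2, 0, 2], short_train, field)
        with pytest.raises(ValueError):
            bmc.mtr_profile(z1, z2)


def test_hz_domain_quantities_are_gamma_b0_invariant():
    """Doubling gamma while halving B0 leaves the ppm->Hz conversion (and so
    every Hz-domain offset) unchanged."""
    f1 = bmc.FieldParams(7.0, bmc.GAMMA_HZ_PER_T)
    f2 = bmc.FieldParams(3.5, 2 * bmc.GAMMA_HZ_PER_T)
    assert f1.hz_per_ppm == pytest.approx(f2.hz_per_ppm, rel=1e-15)
    assert f1.ppm_to_hz(-2.7) == pytest.approx(f2.ppm_to_hz(-2.7), rel=1e-15)


def test_gaussian_rms_below_peak():
    p = bmc.SaturationPulse("gaussian", 1.2, 0.030)
    assert 0 < p.b1_rms_uT < 1.2
    assert p.as_equivalent_cw().b1_peak_uT == pytest.approx(p.b1_rms_uT)
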