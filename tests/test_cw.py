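"""CW spectral-derivative analysis: attenuation, derivatives, two-step fit,
water-band pathlength."""

import numpy as np
import pytest

from nirsim.chromophores import PhantomState, SpectralGrid, ExtinctionTable
from nirsim.cw import (AttenuationSpectrum, CwConfig, PathlengthSpectrum,
                       analyze_timecourse_cw, delta_attenuation,
                       fit_cw_step1, fit_cw_step2, moving_average,
                       pathlength_water, second_derivative)


@pytest.fixture(scope="module")
def grid80():
    return SpectralGrid(np.linspace(675.0, 875.0, 80))


@pytest.fixture(scope="module")
def table80(grid80):
    return ExtinctionTable.compiled(grid80)


@pytest.fixture(scope="module")
def L80(grid80):
    # gently wavelength-dependent pathlength around 200 mm
    L = 200.0 * (grid80.wavelengths / 775.0) ** -0.6
    return PathlengthSpectrum(grid=grid80, L=L)


def synth_dA(table, L, dhb, dcco, drift=0.0):
    """Noiseless attenuation change from known chromophore changes."""
    dmua = dhb * (table.eps_Hb - table.eps_HbO) + dcco * table.eps_oxredCCO_diff
    return AttenuationSpectrum(grid=table.grid, dA=dmua * L.L + drift)


class TestDeltaAttenuation:
    def test_equal_intensities_give_zero(self, grid16):
        I = np.linspace(1.0, 2.0, 16)
        dA = delta_attenuation(I, I, grid16)
        np.testing.assert_allclose(dA.dA, 0.0, atol=1e-15)

    def test_closed_form_factor(self, grid16):
        I0 = np.full(16, 2.0)
        dA = delta_attenuation(I0 * np.exp(-0.5), I0, grid16)
        np.testing.assert_allclose(dA.dA, 0.5, rtol=1e-12)

    def test_additivity_of_sequential_steps(self, grid16):
        rng = np.random.default_rng(0)
        I0 = rng.uniform(1.0, 2.0, 16)
        I1 = I0 * np.exp(-rng.uniform(0.1, 0.3, 16))
        I2 = I1 * np.exp(-rng.uniform(0.1, 0.3, 16))
        d01 = delta_attenuation(I1, I0, grid16).dA
        d12 = delta_attenuation(I2, I1, grid16).dA
        d02 = delta_attenuation(I2, I0, grid16).dA
        np.testing.assert_allclose(d01 + d12, d02, rtol=1e-12)

    def test_dark_correction_and_flagging(self, grid16):
        I0 = np.full(16, 2.0)
        It = np.full(16, 1.5)
        It[4] = 0.05                              # below the dark level
        dA = delta_attenuation(It, I0, grid16, dark=0.1)
        assert np.isnan(dA.dA[4])
        assert np.isfinite(np.delete(dA.dA, 4)).all()
        with pytest.raises(ValueError):
            delta_attenuation(np.zeros(16), I0, grid16)


class TestSecondDerivative:
    def test_exact_for_quadratic(self, grid16):
        wl = grid16.wavelengths
        y = 3.0 + 0.2 * wl + 0.007 * wl**2
        d2 = second_derivative(y, grid16)
        np.testing.assert_allclose(d2[1:-1], 2 * 0.007, rtol=1e-7)
        assert np.isnan(d2[0]) and np.isnan(d2[-1])

    def test_zero_for_linear(self, grid16):
        y = 1.0 - 0.4 * grid16.wavelengths
        d2 = second_derivative(y, grid16)
        np.testing.assert_allclose(d2[1:-1], 0.0, atol=1e-10)

    def test_oversized_window_rejected(self, grid16):
        with pytest.raises(ValueError):
            second_derivative(np.zeros(16), grid16, smooth_window=17)
        with pytest.raises(ValueError):
            moving_average(np.zeros(16), 4)       # even window

    def test_smoothing_reduces_white_noise_variance(self, grid80):
        """A w-point moving average reduces white-noise variance ~ 1/w
        before differencing."""
        rng = np.random.default_rng(7)
        w = 5
        raw_var, smooth_var = [], []
        for _ in range(300):
            y = rng.normal(size=80)
            s = moving_average(y, w)
            raw_var.append(np.nanvar(y[2:-2]))
            smooth_var.append(np.nanvar(s))
        ratio = np.mean(smooth_var) / np.mean(raw_var)
        assert ratio == pytest.approx(1.0 / w, rel=0.15)


class TestTwoStepFit:
    def test_step1_round_trip_exact(self, table80, L80):
        dA = synth_dA(table80, L80, dhb=1.7, dcco=0.0)
        dhb = fit_cw_step1(dA, L80, table80, smooth_window=0)
        assert dhb == pytest.approx(1.7, abs=1e-9)

    def test_step1_zero_attenuation(self, table80, L80):
        dA = AttenuationSpectrum(grid=table80.grid, dA=np.zeros(80))
        assert fit_cw_step1(dA, L80, table80) == pytest.approx(0.0, abs=1e-12)

    @staticmethod
    def _featureless_cco_table(table):
        """Table whose CCO difference band vanishes below 790 nm -- the
        regime step 1 assumes (no CCO contribution in its window)."""
        wl = table.grid.wavelengths
        i790 = int(np.argmin(np.abs(wl - 790.0)))
        eps = table.eps_oxredCCO_diff.copy()
        eps[:i790] = 0.0
        return ExtinctionTable(grid=table.grid, eps_Hb=table.eps_Hb,
                               eps_HbO=table.eps_HbO, eps_oxredCCO_diff=eps,
                               mua_water=table.mua_water)

    def test_two_step_round_trip_exact(self, table80, L80):
        """Known (dHb, doxCCO) with the exact pathlength are recovered
        exactly when the CCO band is featureless in the step-1 window
        (the assumption the two-step split rests on)."""
        t = self._featureless_cco_table(table80)
        dA = synth_dA(t, L80, dhb=2.0, dcco=-0.5)
        dhb = fit_cw_step1(dA, L80, t, smooth_window=0)
        dcco, drift, resid = fit_cw_step2(dA, L80, t, dhb)
        assert dhb == pytest.approx(2.0, abs=1e-6)
        assert dcco == pytest.approx(-0.5, abs=1e-6)
        assert abs(drift) < 1e-6

    def test_two_step_crosstalk_small_with_realistic_band(self, table80, L80):
        """With the compiled CCO band the residual step-1 cross talk stays
        below ~2% of dHb."""
        dA = synth_dA(table80, L80, dhb=2.0, dcco=-0.5)
        dhb = fit_cw_step1(dA, L80, table80, smooth_window=0)
        dcco, _, _ = fit_cw_step2(dA, L80, table80, dhb)
        assert dhb == pytest.approx(2.0, rel=0.02)
        assert dcco == pytest.approx(-0.5, rel=0.10)

    def test_constant_offset_absorbed_by_drift_term(self, table80, L80):
        """A wavelength-independent attenuation offset lands entirely in the
        drift amplitude, leaving doxCCO unchanged."""
        clean = synth_dA(table80, L80, dhb=1.0, dcco=-0.4)
        shifted = synth_dA(table80, L80, dhb=1.0, dcco=-0.4, drift=0.05)
        dhb_c = fit_cw_step1(clean, L80, table80, smooth_window=0)
        dhb_s = fit_cw_step1(shifted, L80, table80, smooth_window=0)
        assert dhb_s == pytest.approx(dhb_c, abs=1e-9)   # d2 kills constants
        cco_c, drift_c, _ = fit_cw_step2(clean, L80, table80, dhb_c)
        cco_s, drift_s, _ = fit_cw_step2(shifted, L80, table80, dhb_s)
        assert cco_s == pytest.approx(cco_c, abs=1e-9)
        assert drift_s - drift_c == pytest.approx(0.05, abs=1e-9)

    def test_uncorrected_step2_corrupted_by_offset(self, table80, L80):
        clean = synth_dA(table80, L80, dhb=1.0, dcco=-0.4)
        shifted = synth_dA(table80, L80, dhb=1.0, dcco=-0.4, drift=0.05)
        dhb = fit_cw_step1(clean, L80, table80, smooth_window=0)
        cco_c, _, _ = fit_cw_step2(clean, L80, table80, dhb, drift_term=False)
        cco_s, _, _ = fit_cw_step2(shifted, L80, table80, dhb, drift_term=False)
        assert abs(cco_s - cco_c) > 0.05

    def test_step_ranges_match_method(self, table80, L80):
        from nirsim.cw import STEP1_RANGE, STEP2_RANGE
        assert STEP1_RANGE == (720.0, 780.0)
        assert STEP2_RANGE == (815.0, 845.0)       # centered on the 830 nm band


class TestPathlengthWater:
    def test_round_trip_within_5pct(self, table80, L80):
        """Reflectance generated with a known pathlength and 0.99 water
        yields the pathlength scale within 5% (noiseless)."""
        refl = np.exp(-0.99 * table80.mua_water * L80.L)
        got = pathlength_water(refl, table80, L80, water_fraction=0.99)
        ratio = got.L / L80.L
        assert np.median(ratio) == pytest.approx(1.0, abs=0.05)
        assert got.source == "water_band_corrected"

    def test_output_shape_proportional_to_tr_shape(self, table80, L80):
        refl = np.exp(-0.99 * table80.mua_water * L80.L)
        got = pathlength_water(refl, table80, L80)
        ratio = got.L / L80.L
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)

    def test_flat_second_derivative_not_identifiable(self, table80, grid80):
        flat = PathlengthSpectrum(grid=grid80, L=np.full(80, 200.0))
        refl = np.exp(-np.linspace(0.5, 0.6, 80))    # featureless attenuation
        table_flat = ExtinctionTable(
            grid=grid80, eps_Hb=table80.eps_Hb, eps_HbO=table80.eps_HbO,
            eps_oxredCCO_diff=table80.eps_oxredCCO_diff,
            mua_water=np.full(80, 3e-3))             # no water curvature
        with pytest.raises(np.linalg.LinAlgError):
            pathlength_water(refl, table_flat, flat)


class TestTimecourseCw:
    def test_constant_intensities_give_zero_deltas(self, table80, L80):
        I = np.tile(np.exp(-0.004 * L80.L), (5, 1))
        df = analyze_timecourse_cw(I, table80, L80)
        np.testing.assert_allclose(df.dHb_uM, 0.0, atol=1e-9)
        np.testing.assert_allclose(df.doxCCO_uM, 0.0, atol=1e-9)
        assert not df.flagged.any()

    def test_known_changes_recovered_in_sequence(self, table80, L80):
        from nirsim.chromophores import make_mua
        states = [PhantomState(tHb=6.6, sO2=1.0),
                  PhantomState(tHb=6.6, sO2=0.6, d_oxCCO=-0.3),
                  PhantomState(tHb=6.6, sO2=0.2, d_oxCCO=-0.8)]
        I = np.stack([np.exp(-make_mua(s, table80) * L80.L) for s in states])
        df = analyze_timecourse_cw(I, table80, L80,
                                   CwConfig(smooth_window=0))
        truth_hb = [0.0, 6.6 * 0.4, 6.6 * 0.8]
        # residual CCO/HbO cross talk with the realistic band caps accuracy
        np.testing.assert_allclose(df.dHb_uM, truth_hb, atol=0.06)
        np.testing.assert_allclose(df.doxCCO_uM, [0.0, -0.3, -0.8], atol=0.05)
        np.testing.assert_allclose(df.dHbO_uM, -df.dHb_uM)
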