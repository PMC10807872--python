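"""Time-resolved tail analysis: windows, slopes, unmixing, pipeline."""

import numpy as np
import pytest

from nirsim.chromophores import (ExtinctionTable, GridError, PhantomState,
                                 SpectralGrid, make_levels, make_mua, make_musp)
from nirsim.constants import C_MM_PER_NS
from nirsim.forward import Geometry, LayerOptics, tpsf_homogeneous
from nirsim.instrument import convolve_irf, synth_irf
from nirsim.tr import (TailWindow, TrConfig, WINDOW_5_1, WINDOW_50_20,
                       analyze_timecourse_tr, delta_mua, find_window,
                       fit_chromophores, fit_slope, mua_from_slope,
                       mua_spectrum, MuaSpectrum)


def exp_counts(times_ps, rate_per_ns, amplitude=1000.0, onset_bin=5):
    """Rising step then exponential decay at the given rate."""
    c = amplitude * np.exp(-rate_per_ns * (times_ps - times_ps[onset_bin]) / 1000.0)
    c[:onset_bin] = np.linspace(0, amplitude, onset_bin, endpoint=False)
    return c


class TestFindWindow:
    def test_pure_decay_window_spans_stated_fractions(self, geom_small):
        """On a clean decay from peak 1000 the 50-20% window spans the bins
        with counts in (200, 500]."""
        t = geom_small.times
        c = exp_counts(t, rate_per_ns=1.0)
        i0, i1 = find_window(c, WINDOW_50_20)
        peak = c.max()
        assert c[i0] < 0.5 * peak <= c[i0 - 1]
        assert c[i1] >= 0.2 * peak > c[i1 + 1]

    def test_monotonically_rising_input_flagged(self, geom_small):
        c = np.arange(geom_small.times.size, dtype=float)
        assert find_window(c, WINDOW_50_20) is None

    def test_convolved_window_opens_later(self, scene16):
        tp = scene16["tpsf"]
        conv = convolve_irf(tp, synth_irf(550.0, tp.times))
        for iw in range(tp.grid.n):
            raw = find_window(tp.reflectance[iw], WINDOW_5_1)
            blur = find_window(conv.reflectance[iw], WINDOW_5_1)
            assert blur[0] > raw[0]

    def test_short_window_rejected(self, geom_small):
        c = np.zeros(geom_small.times.size)
        c[10] = 1000.0
        c[11] = 400.0
        c[12] = 100.0      # crosses 50% and 20% within 2 bins
        assert find_window(c, WINDOW_50_20) is None

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            TailWindow(0.2, 0.5)


class TestFitSlope:
    def test_exact_on_noiseless_exponential(self, geom_small):
        t = geom_small.times
        c = exp_counts(t, rate_per_ns=2.0)
        m, r2, n = fit_slope(c, t, find_window(c, WINDOW_50_20))
        assert m == pytest.approx(-2.0, abs=1e-6)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_amplitude_invariance(self, geom_small):
        t = geom_small.times
        c = exp_counts(t, rate_per_ns=1.5)
        w = find_window(c, WINDOW_50_20)
        m1, _, _ = fit_slope(c, t, w)
        m2, _, _ = fit_slope(123.0 * c, t, w)
        assert m1 == pytest.approx(m2, rel=1e-12)

    def test_poisson_noise_recovery_within_5pct(self, geom_small):
        """With ~1e4 counts in the window the slope lands within 5%."""
        t = geom_small.times
        lam = exp_counts(t, rate_per_ns=2.0, amplitude=3.0e4)
        rng = np.random.default_rng(12)
        c = rng.poisson(lam)
        w = find_window(c, WINDOW_50_20)
        assert lam[w[0]:w[1] + 1].sum() > 1e4
        m, _, _ = fit_slope(c, t, w)
        assert m == pytest.approx(-2.0, rel=0.05)

    def test_insufficient_positive_bins_flagged(self, geom_small):
        t = geom_small.times
        c = np.zeros(t.size)
        m, r2, n = fit_slope(c, t, (10, 20))
        assert np.isnan(m) and n == 0


class TestEq2:
    def test_arithmetic(self):
        # m = -2.254 ns^-1 at n=1.33: mua = 2.254*1.33/299.792 ~ 0.0100 mm^-1
        assert mua_from_slope(-2.254, 1.33) == pytest.approx(0.0100, abs=5e-5)
        assert mua_from_slope(0.0) == 0.0

    def test_negative_mua_passes_through(self):
        assert mua_from_slope(0.5) < 0


class TestDeltaMua:
    def _spec(self, grid, mua):
        n = grid.n
        return MuaSpectrum(grid=grid, mua=mua, slope=np.zeros(n),
                           r_squared=np.ones(n), n_bins=np.full(n, 10))

    def test_identical_spectra_give_zero(self, grid16):
        s = self._spec(grid16, np.full(16, 0.01))
        assert np.all(delta_mua(s, s) == 0)

    def test_linearity_and_nan_propagation(self, grid16):
        base = self._spec(grid16, np.full(16, 0.01))
        m = np.full(16, 0.012)
        m[3] = np.nan
        cur = self._spec(grid16, m)
        d = delta_mua(cur, base)
        assert np.isnan(d[3])
        np.testing.assert_allclose(np.delete(d, 3), 0.002)

    def test_grid_mismatch_rejected(self, grid16):
        other = SpectralGrid(np.linspace(675.0, 875.0, 17))
        a = self._spec(grid16, np.full(16, 0.01))
        b = self._spec(other, np.full(17, 0.01))
        with pytest.raises(GridError):
            delta_mua(a, b)

    def test_baseline_averaging_reduces_noise_variance(self, grid16):
        """Averaging k baseline acquisitions shrinks the delta-mua variance
        by the factor (1 + 1/k)/2 relative to a single-acquisition baseline."""
        rng = np.random.default_rng(3)
        sigma = 1e-4
        n_rep = 3000
        for k in (4,):
            d1, dk = [], []
            for _ in range(n_rep):
                base_acqs = rng.normal(0.01, sigma, size=k)
                cur = rng.normal(0.01, sigma)
                d1.append(cur - base_acqs[0])
                dk.append(cur - base_acqs.mean())
            ratio = np.var(dk) / np.var(d1)
            assert ratio == pytest.approx((1 + 1 / k) / 2, rel=0.1)


class TestChromophoreFit:
    def test_round_trip_exact(self, table16):
        """A noiseless dmua built from (dHb=+2, doxCCO=-0.5) is recovered
        exactly by the constrained fit."""
        dmua = (2.0 * (table16.eps_Hb - table16.eps_HbO)
                - 0.5 * table16.eps_oxredCCO_diff)
        cd = fit_chromophores(dmua, table16)
        assert cd.d_Hb == pytest.approx(2.0, abs=1e-10)
        assert cd.d_HbO == -cd.d_Hb
        assert cd.d_oxCCO == pytest.approx(-0.5, abs=1e-10)
        assert cd.residual_norm == pytest.approx(0.0, abs=1e-12)

    def test_zero_spectrum_gives_zero_deltas(self, table16):
        cd = fit_chromophores(np.zeros(16), table16)
        assert (cd.d_Hb, cd.d_HbO, cd.d_oxCCO) == (0.0, 0.0, 0.0)

    def test_default_range_is_optimized_band(self, table16):
        cd = fit_chromophores(np.zeros(16), table16)
        assert cd.fit_range == (680.0, 840.0)

    def test_unconstrained_recovers_three_components(self, table16):
        dmua = (1.5 * table16.eps_Hb - 0.7 * table16.eps_HbO
                - 0.3 * table16.eps_oxredCCO_diff)
        cd = fit_chromophores(dmua, table16, constrain=False)
        assert cd.d_Hb == pytest.approx(1.5, abs=1e-8)
        assert cd.d_HbO == pytest.approx(-0.7, abs=1e-8)
        assert cd.d_oxCCO == pytest.approx(-0.3, abs=1e-8)

    def test_missing_wavelengths_excluded(self, table16):
        dmua = 2.0 * (table16.eps_Hb - table16.eps_HbO)
        dmua[5] = np.nan
        cd = fit_chromophores(dmua, table16)
        assert cd.d_Hb == pytest.approx(2.0, abs=1e-10)


class FixedWindowPipeline:
    """TR ladder analysis with window bins frozen from the baseline DTOF.

    Freezing the bins removes the window-migration bias of peak-fraction
    windows, isolating the slope -> absorption -> unmixing chain itself.
    """

    @staticmethod
    def recover(counts_list, times, grid, table, window):
        base_windows = [find_window(counts_list[0][iw], window)
                        for iw in range(grid.n)]
        muas = []
        for counts in counts_list:
            mua = np.full(grid.n, np.nan)
            for iw in range(grid.n):
                m, _, _ = fit_slope(counts[iw], times, base_windows[iw])
                if np.isfinite(m):
                    mua[iw] = mua_from_slope(m)
            muas.append(mua)
        return [fit_chromophores(m - muas[0], table) for m in muas]


class TestParameterRecovery:
    def test_very_late_fixed_window_recovers_ladder(self, geom_small):
        """Noiseless homogeneous forward -> tail slopes over a very late
        window (bins frozen from baseline) recover dHb within 5% and doxCCO
        within 15% across the 11-level ladder."""
        grid = SpectralGrid(np.linspace(675.0, 875.0, 24))
        table = ExtinctionTable.compiled(grid)
        musp = make_musp(0.8, grid)
        levels = make_levels(11, PhantomState(tHb=6.6, sO2=1.0),
                             PhantomState(tHb=6.6, sO2=0.0, d_oxCCO=-1.0))
        cubes = [tpsf_homogeneous(LayerOptics(mua=make_mua(s, table), musp=musp),
                                  geom_small, grid).reflectance
                 for s in levels]
        very_late = TailWindow(0.02, 0.002)
        cds = FixedWindowPipeline.recover(cubes, geom_small.times, grid,
                                          table, very_late)
        for s, cd in zip(levels[1:], cds[1:]):
            truth_hb = s.Hb - levels[0].Hb
            truth_cco = s.d_oxCCO
            assert cd.d_Hb == pytest.approx(truth_hb, rel=0.05)
            assert cd.d_oxCCO == pytest.approx(truth_cco, rel=0.15)


class TestTimecoursePipeline:
    def _cubes(self, states, grid, table, geom, with_irf=True):
        musp = make_musp(0.8, grid)
        irf = synth_irf(550.0, geom.times)
        out = []
        for s in states:
            tp = tpsf_homogeneous(LayerOptics(mua=make_mua(s, table), musp=musp),
                                  geom, grid)
            if with_irf:
                tp = convolve_irf(tp, irf)
            out.append(tp)
        return out

    class _Acq:
        def __init__(self, tp):
            self.counts = tp.reflectance
            self.grid = tp.grid
            self.times = tp.times

    def test_constant_input_gives_zero_deltas(self, grid16, table16, geom_small):
        states = [PhantomState(tHb=6.6, sO2=0.8)] * 4
        cubes = self._cubes(states, grid16, table16, geom_small)
        df = analyze_timecourse_tr([self._Acq(c) for c in cubes], table16)
        np.testing.assert_allclose(df.dHb_uM, 0.0, atol=1e-9)
        np.testing.assert_allclose(df.doxCCO_uM, 0.0, atol=1e-9)

    def test_deoxygenation_sign_pattern(self, grid16, table16, geom_small):
        """During deoxygenation Hb rises, HbO falls, and oxCCO falls."""
        states = [PhantomState(tHb=6.6, sO2=1.0),
                  PhantomState(tHb=6.6, sO2=0.3, d_oxCCO=-0.6)]
        cubes = self._cubes(states, grid16, table16, geom_small)
        df = analyze_timecourse_tr([self._Acq(c) for c in cubes], table16)
        assert df.dHb_uM.iloc[1] > 0.5
        assert df.dHbO_uM.iloc[1] < -0.5
        assert df.doxCCO_uM.iloc[1] < -0.1

    def test_amplitude_drift_immunity(self, grid16, table16, geom_small):
        """Multiplying all DTOFs by a wavelength-independent constant leaves
        the recovered time course unchanged (log-slope analysis)."""
        states = [PhantomState(tHb=6.6, sO2=1.0),
                  PhantomState(tHb=6.6, sO2=0.5, d_oxCCO=-0.3)]
        cubes = self._cubes(states, grid16, table16, geom_small)
        ref = analyze_timecourse_tr([self._Acq(c) for c in cubes], table16)
        drift = analyze_timecourse_tr(
            [self._Acq(c.scaled(1.0 + 0.3 * i)) for i, c in enumerate(cubes)],
            table16)
        np.testing.assert_allclose(drift.dHb_uM, ref.dHb_uM, atol=1e-9)
        np.testing.assert_allclose(drift.doxCCO_uM, ref.doxCCO_uM, atol=1e-9)
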