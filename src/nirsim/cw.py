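"""Continuous-wave spectral-derivative analysis.

Attenuation changes relative to baseline (modified Beer-Lambert law,
dA = dmu_a * L) are analyzed in two steps: (1) the second wavelength
derivative of dA is fit between 720 and 780 nm, where the hemoglobin
difference spectrum carries strong curvature while oxidized-minus-reduced
CCO and HbO are featureless, recovering dHb with minimal cross talk; (2)
with dHb fixed (and dHbO = -dHb), raw dA between 815 and 845 nm -- centered
on the 830 nm CCO band -- is fit for doxCCO, optionally with a
wavelength-independent amplitude term absorbing source-intensity drift.

The wavelength-dependent pathlength L(lambda) either comes from the mean
time-of-flight of paired TR data or, when the TR probe samples a different
compartment, from the amplitude of the water absorption feature in the
second derivative of the CW reflectance, shape-corrected by the TR
pathlength spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chromophores import ExtinctionTable, SpectralGrid, GridError

__all__ = [
    "AttenuationSpectrum",
    "PathlengthSpectrum",
    "CwConfig",
    "delta_attenuation",
    "second_derivative",
    "fit_cw_step1",
    "fit_cw_step2",
    "pathlength_water",
    "analyze_timecourse_cw",
]

STEP1_RANGE = (720.0, 780.0)
STEP2_RANGE = (815.0, 845.0)
WATER_FIT_RANGE = (720.0, 760.0)
DEFAULT_SMOOTH_WINDOW = 5


@dataclass(frozen=True)
class AttenuationSpectrum:
    """Attenuation change dA(lambda) relative to baseline (dimensionless)."""

    grid: SpectralGrid
    dA: np.ndarray              # NaN where intensities were unusable
    smooth_window: int = 0


@dataclass(frozen=True)
class PathlengthSpectrum:
    """Wavelength-dependent optical pathlength in mm."""

    grid: SpectralGrid
    L: np.ndarray
    source: str = "mean_tof"    # 'mean_tof' | 'water_band_corrected'

    def __post_init__(self):
        L = np.asarray(self.L, dtype=float)
        if np.any(L[np.isfinite(L)] <= 0):
            raise ValueError("pathlength must be > 0")
        object.__setattr__(self, "L", L)


def delta_attenuation(I_t: np.ndarray, I_baseline: np.ndarray,
                      grid: SpectralGrid,
                      dark: np.ndarray | float = 0.0) -> AttenuationSpectrum:
    """dA = -ln((I_t - dark) / (I_0 - dark)); unusable wavelengths -> NaN."""
    It = np.asarray(I_t, dtype=float) - dark
    I0 = np.asarray(I_baseline, dtype=float) - dark
    ok = (It > 0) & (I0 > 0)
    if not ok.any():
        raise ValueError("all wavelengths excluded: non-positive corrected intensities")
    dA = np.full(grid.n, np.nan)
    dA[ok] = -np.log(It[ok] / I0[ok])
    return AttenuationSpectrum(grid=grid, dA=dA)


def moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; endpoints where the window does not fit -> NaN."""
    if window <= 1:
        return np.asarray(y, dtype=float).copy()
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    y = np.asarray(y, dtype=float)
    if window >= y.size:
        raise ValueError("smoothing window must be shorter than the spectrum")
    out = np.full_like(y, np.nan)
    half = window // 2
    kern = np.ones(window) / window
    out[half:y.size - half] = np.convolve(y, kern, mode="valid")
    return out


def second_derivative(y: np.ndarray, grid: SpectralGrid,
                      smooth_window: int = 0) -> np.ndarray:
    """d^2 y / d lambda^2 on the uniform grid (central differences).

    Optional centered moving-average smoothing before differencing; the
    endpoints of the stencil (and of the smoothing window) are NaN. Exact
    for quadratics when unsmoothed.
    """
    y = np.asarray(y, dtype=float)
    if smooth_window:
        y = moving_average(y, smooth_window)
    h = grid.spacing
    d2 = np.full_like(y, np.nan)
    d2[1:-1] = (y[2:] - 2.0 * y[1:-1] + y[:-2]) / h**2
    return d2


def _range_mask(grid: SpectralGrid, rng, *arrays):
    wl = grid.wavelengths
    sel = (wl >= rng[0]) & (wl <= rng[1])
    for a in arrays:
        sel &= np.isfinite(a)
    return sel


def fit_cw_step1(dA: AttenuationSpectrum, L: PathlengthSpectrum,
                 table: ExtinctionTable, fit_range=STEP1_RANGE,
                 smooth_window: int = DEFAULT_SMOOTH_WINDOW,
                 drift_term: bool = True) -> float:
    """Second-derivative fit for dHb over the 720-780 nm window.

    Model: dA = dHb (eps_Hb - eps_HbO) L(lambda) (+ drift constant, which
    vanishes under the second derivative). Data and model are smoothed and
    differentiated identically so discretization bias cancels.
    """
    table.grid.require_match(dA.grid)
    d2_data = second_derivative(dA.dA, dA.grid, smooth_window)
    model = (table.eps_Hb - table.eps_HbO) * L.L
    d2_model = second_derivative(model, dA.grid, smooth_window)
    sel = _range_mask(dA.grid, fit_range, d2_data, d2_model)
    if sel.sum() < 2:
        return np.nan
    X = d2_model[sel][:, None]
    y = d2_data[sel]
    denom = float(X[:, 0] @ X[:, 0])
    if denom <= 0:
        raise np.linalg.LinAlgError("degenerate step-1 design")
    return float(X[:, 0] @ y / denom)


def fit_cw_step2(dA: AttenuationSpectrum, L: PathlengthSpectrum,
                 table: ExtinctionTable, dHb_fixed: float,
                 fit_range=STEP2_RANGE, drift_term: bool = True):
    """Raw-dA fit for doxCCO over 815-845 nm with dHb fixed and dHbO = -dHb.

    Optionally fits an additional wavelength-independent amplitude term
    (source-drift correction). Returns (doxCCO, drift_amplitude, resid).
    """
    table.grid.require_match(dA.grid)
    hb_part = dHb_fixed * (table.eps_Hb - table.eps_HbO) * L.L
    sel = _range_mask(dA.grid, fit_range, dA.dA, hb_part)
    if sel.sum() < (2 if drift_term else 1):
        return np.nan, np.nan, np.nan
    y = dA.dA[sel] - hb_part[sel]
    basis = table.eps_oxredCCO_diff[sel] * L.L[sel]
    if drift_term:
        X = np.column_stack([basis, np.ones(sel.sum())])
    else:
        X = basis[:, None]
    cond = np.linalg.cond(X)
    if cond > 1e10:
        raise np.linalg.LinAlgError(
            f"rank-deficient step-2 design (condition number {cond:.2e})")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = float(np.linalg.norm(y - X @ coef))
    drift = float(coef[1]) if drift_term else 0.0
    return float(coef[0]), drift, resid


def pathlength_water(cw_reflectance: np.ndarray, table: ExtinctionTable,
                     tr_shape: PathlengthSpectrum,
                     water_fraction: float = 0.99,
                     fit_range=WATER_FIT_RANGE,
                     smooth_window: int = DEFAULT_SMOOTH_WINDOW) -> PathlengthSpectrum:
    """Pathlength from the water feature in the CW reflectance.

    The second derivative of -ln(reflectance) is fit (over the strongest
    in-grid water curvature feature, 720-760 nm by default) to the second
    derivative of water_fraction * mua_water(lambda) * l(lambda), where
    l is the TR pathlength spectrum normalized to unit mean over the fit
    range. The recovered scalar times l gives L(lambda).
    """
    refl = np.asarray(cw_reflectance, dtype=float)
    grid = table.grid
    if refl.shape != grid.wavelengths.shape:
        raise GridError("reflectance not on the extinction-table grid")
    if np.any(~np.isfinite(tr_shape.L)) or np.any(tr_shape.L <= 0):
        raise ValueError("TR pathlength shape must be positive and finite")
    wl = grid.wavelengths
    sel_rng = (wl >= fit_range[0]) & (wl <= fit_range[1])
    shape = tr_shape.L / tr_shape.L[sel_rng].mean()
    att = np.full(grid.n, np.nan)
    ok = refl > 0
    att[ok] = -np.log(refl[ok])
    d2_data = second_derivative(att, grid, smooth_window)
    d2_model = second_derivative(water_fraction * table.mua_water * shape,
                                 grid, smooth_window)
    sel = sel_rng & np.isfinite(d2_data) & np.isfinite(d2_model)
    denom = float(d2_model[sel] @ d2_model[sel])
    if sel.sum() < 3 or denom <= 0 or np.ptp(d2_model[sel]) == 0:
        raise np.linalg.LinAlgError("water feature not identifiable "
                                    "(flat second derivative in fit range)")
    scalar = float(d2_model[sel] @ d2_data[sel] / denom)
    return PathlengthSpectrum(grid=grid, L=scalar * shape,
                              source="water_band_corrected")


@dataclass(frozen=True)
class CwConfig:
    """Configuration of the CW time-course pipeline."""

    step1_range: tuple = STEP1_RANGE
    step2_range: tuple = STEP2_RANGE
    smooth_window: int = DEFAULT_SMOOTH_WINDOW
    drift_term: bool = True
    baseline_span: int = 1
    water_fraction: float = 0.99


def analyze_timecourse_cw(intensities: np.ndarray, table: ExtinctionTable,
                          pathlengths, config: CwConfig | None = None,
                          dark: np.ndarray | float = 0.0) -> pd.DataFrame:
    """Run the two-step CW pipeline over an intensity time series.

    ``intensities`` is (n_time, n_wavelength); ``pathlengths`` is either a
    single PathlengthSpectrum or a sequence of per-time-point spectra.
    The baseline intensity is the mean over the first ``baseline_span``
    acquisitions. Returns a DataFrame matching the TR time-course schema.
    """
    cfg = config or CwConfig()
    I = np.asarray(intensities, dtype=float)
    if I.ndim != 2 or I.shape[1] != table.grid.n:
        raise GridError("intensities must be (n_time, n_wavelength) on the table grid")
    span = max(1, min(cfg.baseline_span, I.shape[0]))
    I0 = I[:span].mean(axis=0)
    rows = []
    for i in range(I.shape[0]):
        L = pathlengths[i] if isinstance(pathlengths, (list, tuple)) else pathlengths
        try:
            dA = delta_attenuation(I[i], I0, table.grid, dark)
            dhb = fit_cw_step1(dA, L, table, cfg.step1_range,
                               cfg.smooth_window, cfg.drift_term)
            dcco, drift, resid = fit_cw_step2(dA, L, table, dhb,
                                              cfg.step2_range, cfg.drift_term)
        except (ValueError, np.linalg.LinAlgError):
            dhb, dcco, drift, resid = np.nan, np.nan, np.nan, np.nan
        rows.append({
            "time_index": i,
            "dHb_uM": dhb,
            "dHbO_uM": -dhb if np.isfinite(dhb) else np.nan,
            "doxCCO_uM": dcco,
            "resid": resid,
            "drift": drift,
            "flagged": not (np.isfinite(dhb) and np.isfinite(dcco)),
        })
    return pd.DataFrame(rows)
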