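"""Time-resolved late-photon tail analysis.

The absorption coefficient at each wavelength is estimated from the
asymptotic log-slope m of the DTOF tail, mu_a = -m n / c, over a window
defined by fractions of the after-peak peak intensity (presets 50%-20% and
5%-1%). Absorption changes relative to a baseline period are then unmixed
into chromophore concentration changes by linear least squares on the
specific extinction spectra, with the constraint dHbO = -dHb when total
hemoglobin is conserved (closed liquid phantoms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chromophores import ExtinctionTable, SpectralGrid, GridError
from .constants import C_MM_PER_NS, DEFAULT_N

__all__ = [
    "TailWindow",
    "WINDOW_50_20",
    "WINDOW_5_1",
    "MuaSpectrum",
    "ChromophoreDeltas",
    "find_window",
    "fit_slope",
    "mua_from_slope",
    "mua_spectrum",
    "delta_mua",
    "fit_chromophores",
    "analyze_timecourse_tr",
]

#: Default wavelength range for the chromophore fit, nm.
DEFAULT_FIT_RANGE = (680.0, 840.0)

#: Minimum usable bins in a tail window.
MIN_WINDOW_BINS = 5


@dataclass(frozen=True)
class TailWindow:
    """After-peak intensity-fraction window (upper_frac > lower_frac)."""

    upper_frac: float
    lower_frac: float

    def __post_init__(self):
        if not (0.0 < self.lower_frac < self.upper_frac <= 1.0):
            raise ValueError("need 0 < lower_frac < upper_frac <= 1")

    def __str__(self):
        return f"{self.upper_frac:.0%}-{self.lower_frac:.0%}"


WINDOW_50_20 = TailWindow(0.50, 0.20)
WINDOW_5_1 = TailWindow(0.05, 0.01)


@dataclass(frozen=True)
class MuaSpectrum:
    """Per-wavelength absorption estimates with tail-fit diagnostics."""

    grid: SpectralGrid
    mua: np.ndarray          # mm^-1, NaN where the fit failed
    slope: np.ndarray        # ns^-1
    r_squared: np.ndarray
    n_bins: np.ndarray


@dataclass(frozen=True)
class ChromophoreDeltas:
    """Concentration changes from baseline (uM) and fit diagnostics."""

    d_Hb: float
    d_HbO: float
    d_oxCCO: float
    residual_norm: float = np.nan
    fit_range: tuple = DEFAULT_FIT_RANGE
    constrained: bool = True
    n_wavelengths: int = 0

    def __post_init__(self):
        if self.constrained and np.isfinite(self.d_Hb):
            assert self.d_HbO == -self.d_Hb


def find_window(counts_1wl: np.ndarray, window: TailWindow):
    """Bin index range [i0, i1] of the after-peak tail window, or None.

    i0 is the first bin after the peak where counts fall below
    upper_frac * peak; i1 is the last bin before counts fall below
    lower_frac * peak. Threshold crossing acts on raw counts without
    smoothing or sub-bin interpolation; windows shorter than
    MIN_WINDOW_BINS are rejected.
    """
    c = np.asarray(counts_1wl, dtype=float)
    ipk = int(np.argmax(c))
    peak = c[ipk]
    if peak <= 0:
        return None
    after = c[ipk:]
    below_hi = np.flatnonzero(after < window.upper_frac * peak)
    if below_hi.size == 0:
        return None
    i0 = ipk + int(below_hi[0])
    below_lo = np.flatnonzero(c[i0:] < window.lower_frac * peak)
    if below_lo.size == 0:
        i1 = c.size - 1
    else:
        i1 = i0 + int(below_lo[0]) - 1
    if i1 - i0 + 1 < MIN_WINDOW_BINS:
        return None
    return i0, i1


def fit_slope(counts_1wl: np.ndarray, times_ps: np.ndarray, window_bins):
    """OLS slope of ln(counts) vs time over the window, ns^-1.

    Zero-count bins are dropped before the log; the fit is refused (NaN)
    if fewer than MIN_WINDOW_BINS positive bins remain.
    Returns (slope ns^-1, r_squared, n_used).
    """
    if window_bins is None:
        return np.nan, np.nan, 0
    i0, i1 = window_bins
    c = np.asarray(counts_1wl, dtype=float)[i0:i1 + 1]
    t = np.asarray(times_ps, dtype=float)[i0:i1 + 1] / 1000.0   # ns
    pos = c > 0
    if pos.sum() < MIN_WINDOW_BINS:
        return np.nan, np.nan, int(pos.sum())
    y = np.log(c[pos])
    x = t[pos]
    X = np.column_stack([x, np.ones_like(x)])
    coef, res, _, _ = np.linalg.lstsq(X, y, rcond=None)
    yhat = X @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum((y - yhat) ** 2) / ss_tot if ss_tot > 0 else 1.0
    return float(coef[0]), float(r2), int(pos.sum())


def mua_from_slope(m, n: float = DEFAULT_N):
    """Absorption from the asymptotic slope: mu_a = -m n / c (m in ns^-1)."""
    return -np.asarray(m, dtype=float) * n / C_MM_PER_NS


def mua_spectrum(counts: np.ndarray, times_ps: np.ndarray, grid: SpectralGrid,
                 window: TailWindow, n: float = DEFAULT_N) -> MuaSpectrum:
    """Tail-fit mu_a(lambda) for a full DTOF cube (one acquisition)."""
    n_wl = grid.n
    mua = np.full(n_wl, np.nan)
    slope = np.full(n_wl, np.nan)
    r2 = np.full(n_wl, np.nan)
    nb = np.zeros(n_wl, dtype=int)
    for iw in range(n_wl):
        bins = find_window(counts[iw], window)
        m, r, k = fit_slope(counts[iw], times_ps, bins)
        slope[iw], r2[iw], nb[iw] = m, r, k
        if np.isfinite(m):
            mua[iw] = mua_from_slope(m, n)
    return MuaSpectrum(grid=grid, mua=mua, slope=slope, r_squared=r2, n_bins=nb)


def delta_mua(current: MuaSpectrum, baseline: MuaSpectrum) -> np.ndarray:
    """Pointwise mu_a difference; missing values (NaN) propagate."""
    current.grid.require_match(baseline.grid)
    return current.mua - baseline.mua


def fit_chromophores(dmua: np.ndarray, table: ExtinctionTable,
                     fit_range=DEFAULT_FIT_RANGE,
                     constrain: bool = True) -> ChromophoreDeltas:
    """Unmix an absorption-change spectrum into chromophore changes.

    Constrained (default): design {eps_Hb - eps_HbO, eps_diff}, enforcing
    dHbO = -dHb (conserved total hemoglobin). Unconstrained: design
    {eps_Hb, eps_HbO, eps_diff}. NaN wavelengths and wavelengths outside
    ``fit_range`` are excluded.
    """
    wl = table.grid.wavelengths
    dmua = np.asarray(dmua, dtype=float)
    if dmua.shape != wl.shape:
        raise GridError("dmua not on the extinction-table grid")
    sel = (wl >= fit_range[0]) & (wl <= fit_range[1]) & np.isfinite(dmua)
    n_min = 2 if constrain else 3
    if sel.sum() < n_min:
        return ChromophoreDeltas(np.nan, np.nan, np.nan, np.nan,
                                 tuple(fit_range), constrain, int(sel.sum()))
    y = dmua[sel]
    if constrain:
        X = np.column_stack([table.eps_Hb[sel] - table.eps_HbO[sel],
                             table.eps_oxredCCO_diff[sel]])
    else:
        X = np.column_stack([table.eps_Hb[sel], table.eps_HbO[sel],
                             table.eps_oxredCCO_diff[sel]])
    cond = np.linalg.cond(X)
    if cond > 1e10:
        raise np.linalg.LinAlgError(
            f"rank-deficient chromophore design (condition number {cond:.2e})")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = float(np.linalg.norm(y - X @ coef))
    if constrain:
        d_hb, d_cco = float(coef[0]), float(coef[1])
        return ChromophoreDeltas(d_hb, -d_hb, d_cco, resid,
                                 tuple(fit_range), True, int(sel.sum()))
    return ChromophoreDeltas(float(coef[0]), float(coef[1]), float(coef[2]),
                             resid, tuple(fit_range), False, int(sel.sum()))


@dataclass(frozen=True)
class TrConfig:
    """Configuration of the TR time-course pipeline."""

    window: TailWindow = WINDOW_50_20
    fit_range: tuple = DEFAULT_FIT_RANGE
    constrain: bool = True
    n: float = DEFAULT_N
    baseline_span: int = 1       # acquisitions averaged into the baseline mu_a


def analyze_timecourse_tr(dtofs, table: ExtinctionTable,
                          config: TrConfig | None = None,
                          irf=None) -> pd.DataFrame:
    """Run the full TR pipeline over a sequence of DTOF acquisitions.

    Per acquisition: tail-window mu_a(lambda); the baseline mu_a is the mean
    over the first ``baseline_span`` acquisitions; dmu_a is unmixed into
    (dHb, dHbO, doxCCO). ``irf`` is accepted for interface symmetry with the
    acquisition chain; the tail analysis itself operates on the measured
    (already IRF-blurred) DTOFs.

    Returns a DataFrame with columns time_index, dHb_uM, dHbO_uM, doxCCO_uM,
    resid, n_wavelengths, flagged.
    """
    cfg = config or TrConfig()
    dtofs = list(dtofs)
    if not dtofs:
        raise ValueError("no acquisitions given")
    grid = dtofs[0].grid
    table.grid.require_match(grid)
    spectra = [mua_spectrum(d.counts, d.times, grid, cfg.window, cfg.n)
               for d in dtofs]
    span = max(1, min(cfg.baseline_span, len(spectra)))
    base_mua = np.nanmean(np.stack([s.mua for s in spectra[:span]]), axis=0)
    baseline = MuaSpectrum(grid=grid, mua=base_mua,
                           slope=np.full(grid.n, np.nan),
                           r_squared=np.full(grid.n, np.nan),
                           n_bins=np.zeros(grid.n, dtype=int))
    rows = []
    for i, s in enumerate(spectra):
        dm = delta_mua(s, baseline)
        cd = fit_chromophores(dm, table, cfg.fit_range, cfg.constrain)
        rows.append({
            "time_index": i,
            "dHb_uM": cd.d_Hb,
            "dHbO_uM": cd.d_HbO,
            "doxCCO_uM": cd.d_oxCCO,
            "resid": cd.residual_norm,
            "n_wavelengths": cd.n_wavelengths,
            "flagged": not np.isfinite(cd.d_Hb),
        })
    return pd.DataFrame(rows)
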