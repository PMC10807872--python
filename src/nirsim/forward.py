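"""Time-domain diffuse-reflectance forward models.

Homogeneous semi-infinite media use the closed-form diffusion solution with an
extrapolated boundary (image-source pair); two-layer slab-over-half-space
media use the layered diffusion Green's function evaluated in
(spatial-frequency, temporal-frequency) space, inverted numerically by
Gauss-Legendre quadrature over the Hankel variable and an inverse FFT over
temporal frequency. Both return the reflected photon flux at the surface at a
single source-detector separation.

Conventions: time axis in ps, distances in mm, optical coefficients in mm^-1.
The diffusion coefficient is absorption-free, D = 1/(3 mus'), so the
asymptotic log-slope of the homogeneous reflectance tends to -mua * c/n, the
relation the late-photon tail analysis inverts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import j0
from numpy.polynomial.legendre import leggauss

from .chromophores import SpectralGrid, GridError
from .constants import (C_MM_PER_PS, DEFAULT_N, DEFAULT_N_BINS, DEFAULT_RHO,
                        DEFAULT_TIME_SPAN_PS)

__all__ = [
    "LayerOptics",
    "Geometry",
    "TPSF",
    "tpsf_homogeneous",
    "tpsf_two_layer",
    "cw_intensity",
    "mean_tof",
    "pathlength_from_mean_tof",
    "effective_reflection_coefficient",
]


def effective_reflection_coefficient(n: float) -> float:
    """Internal-reflection parameter R_eff for an index-mismatched surface.

    Groenhuis/Egan polynomial fit in the relative refractive index; feeds the
    extrapolated-boundary distance z_b = 2 A D with A = (1+R_eff)/(1-R_eff).
    """
    return -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n


@dataclass(frozen=True)
class LayerOptics:
    """Optical properties of one layer on a spectral grid."""

    mua: np.ndarray          # mm^-1
    musp: np.ndarray         # mm^-1
    n: float = DEFAULT_N
    thickness: float = np.inf   # mm; inf marks the unbounded bottom layer

    def __post_init__(self):
        mua = np.atleast_1d(np.asarray(self.mua, dtype=float))
        musp = np.atleast_1d(np.asarray(self.musp, dtype=float))
        if mua.shape != musp.shape:
            raise GridError("mua and musp must share a grid")
        if np.any(mua < 0):
            raise ValueError("mua must be >= 0")
        if np.any(musp <= 0):
            raise ValueError("musp must be > 0 (diffusion model invalid otherwise)")
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")
        if self.thickness <= 0:
            raise ValueError("thickness must be > 0")
        object.__setattr__(self, "mua", mua)
        object.__setattr__(self, "musp", musp)


def default_times() -> np.ndarray:
    dt = DEFAULT_TIME_SPAN_PS / DEFAULT_N_BINS
    return (np.arange(DEFAULT_N_BINS) + 0.5) * dt


@dataclass(frozen=True)
class Geometry:
    """Source-detector separation and the uniform time axis (bin centers, ps)."""

    rho: float = DEFAULT_RHO
    times: np.ndarray = field(default_factory=default_times)

    def __post_init__(self):
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        t = np.asarray(self.times, dtype=float)
        dt = np.diff(t)
        if t.ndim != 1 or t.size < 8 or np.any(dt <= 0) or not np.allclose(dt, dt[0]):
            raise ValueError("times must be a uniform ascending 1-D axis")
        object.__setattr__(self, "times", t)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class TPSF:
    """Noiseless wavelength-resolved temporal reflectance (arbitrary amplitude)."""

    grid: SpectralGrid
    times: np.ndarray                 # ps, bin centers
    reflectance: np.ndarray           # (n_wavelength, n_time), >= 0

    def __post_init__(self):
        r = np.asarray(self.reflectance, dtype=float)
        if r.shape != (self.grid.n, np.asarray(self.times).size):
            raise GridError("reflectance must be (n_wavelength, n_time)")
        if not np.all(np.isfinite(r)):
            raise ValueError("reflectance must be finite")
        if np.any(r < 0):
            raise ValueError("reflectance must be >= 0")
        object.__setattr__(self, "reflectance", r)
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def scaled(self, factor) -> "TPSF":
        return TPSF(self.grid, self.times, self.reflectance * factor)


def _boundary_lengths(optics: LayerOptics):
    D = 1.0 / (3.0 * optics.musp)
    z0 = 1.0 / optics.musp
    reff = effective_reflection_coefficient(optics.n)
    A = (1.0 + reff) / (1.0 - reff)
    zb = 2.0 * A * D
    return D, z0, zb


def tpsf_homogeneous(optics: LayerOptics, geom: Geometry,
                     grid: SpectralGrid | None = None) -> TPSF:
    """Reflectance of a homogeneous semi-infinite medium.

    Extrapolated-boundary image-source solution: the reflected flux at
    separation rho is the sum of a positive source at depth z0 = 1/mus' and
    its mirrored image across the extrapolated boundary at -(z0 + 2 z_b).
    """
    if grid is None:
        grid = (SpectralGrid(np.linspace(675.0, 875.0, optics.mua.size))
                if optics.mua.size > 1 else SpectralGrid(np.array([800.0])))
    if optics.mua.size != grid.n:
        raise GridError("optics not defined on the requested grid")
    v = C_MM_PER_PS / optics.n                      # mm/ps
    D, z0, zb = _boundary_lengths(optics)
    t = geom.times[None, :]                         # (1, n_t)
    mua = optics.mua[:, None]
    Dw = D[:, None]
    z0w = z0[:, None]
    zbw = zb[:, None]
    with np.errstate(over="ignore", under="ignore"):
        diff = 4.0 * Dw * v * t
        pref = (4.0 * np.pi * Dw * v) ** -1.5 * t ** -2.5
        decay = np.exp(-mua * v * t - geom.rho**2 / diff)
        imgs = (z0w * np.exp(-z0w**2 / diff)
                + (z0w + 2 * zbw) * np.exp(-(z0w + 2 * zbw) ** 2 / diff))
        r = 0.5 * pref * decay * imgs
    return TPSF(grid=grid, times=geom.times, reflectance=np.clip(r, 0.0, None))


def _two_layer_hat(s2, om_over_v, top: LayerOptics, bot: LayerOptics, iw: int,
                   l: float, zb: float, z0: float):
    """Layered Green's-function reflectance in (s, omega) space, one wavelength.

    Overflow-safe form: every exponential has a non-positive real-part
    argument. ``s2`` is s^2 (n_s,), ``om_over_v`` is omega/v (n_freq,).
    Returns array (n_freq, n_s).
    """
    D1 = 1.0 / (3.0 * top.musp[iw])
    D2 = 1.0 / (3.0 * bot.musp[iw])
    q1 = (top.mua[iw] + 1j * om_over_v[:, None]) / D1 + s2[None, :]
    q2 = (bot.mua[iw] + 1j * om_over_v[:, None]) / D2 + s2[None, :]
    a1 = np.sqrt(q1)
    a2 = np.sqrt(q2)
    kappa = (D2 * a2) / (D1 * a1)
    e1 = np.exp(-a1 * z0)
    e2 = np.exp(-a1 * (z0 + 2.0 * zb))
    e3 = np.exp(-a1 * (2.0 * l - z0))
    e4 = np.exp(-a1 * (2.0 * l - z0 + 2.0 * zb))
    e5 = np.exp(-2.0 * a1 * (l + zb))
    num = (1.0 + kappa) * (e1 + e2) + (1.0 - kappa) * (e3 + e4)
    den = 2.0 * ((1.0 + kappa) + (1.0 - kappa) * e5)
    return num / den


def tpsf_two_layer(top: LayerOptics, bottom: LayerOptics, geom: Geometry,
                   grid: SpectralGrid | None = None,
                   n_s: int = 600, s_max: float | None = None,
                   freq_chunk: int = 256) -> TPSF:
    """Reflectance of a finite top layer over a semi-infinite bottom layer.

    The 1-D two-layer diffusion problem is solved analytically in
    (spatial-frequency s, temporal-frequency omega) space with an extrapolated
    boundary above the top layer and continuity of fluence and flux at the
    interface; the surface flux is then recovered by a Hankel transform over s
    (Gauss-Legendre quadrature) and an inverse real FFT over omega.

    Both layers must share the refractive index (index-mismatched internal
    interfaces are not implemented); the top thickness must be finite and the
    bottom unbounded.
    """
    if not np.isclose(top.n, bottom.n):
        raise NotImplementedError("unequal refractive indices between layers")
    if not np.isfinite(top.thickness):
        raise ValueError("top layer thickness must be finite")
    if np.isfinite(bottom.thickness):
        raise ValueError("bottom layer must be unbounded")
    if top.mua.shape != bottom.mua.shape:
        raise GridError("layers must share a spectral grid")
    n_wl = top.mua.size
    grid = grid or SpectralGrid(np.linspace(675.0, 875.0, n_wl))
    if n_wl != grid.n:
        raise GridError("optics not defined on the requested grid")

    v = C_MM_PER_PS / top.n
    l = float(top.thickness)
    reff = effective_reflection_coefficient(top.n)
    A = (1.0 + reff) / (1.0 - reff)

    t = geom.times
    dt = geom.dt
    n_t = t.size
    # Oversample the FFT axis when bins are coarse: the sharp early rise
    # aliases above the Nyquist of bins wider than ~5 ps. Odd factor so the
    # internal samples include the original bin centers.
    ov = _oversample_factor(dt)
    dt_i = dt / ov
    n_i = n_t * ov
    omega = 2.0 * np.pi * np.fft.rfftfreq(n_i, d=dt_i)     # rad/ps
    pick = np.arange(n_t) * ov + (ov - 1) // 2

    out = np.empty((n_wl, n_t), dtype=float)
    for iw in range(n_wl):
        musp1 = top.musp[iw]
        z0 = 1.0 / musp1
        zb = 2.0 * A / (3.0 * musp1)
        smax = s_max if s_max is not None else max(18.0 * musp1, 3.0)
        x, w = leggauss(n_s)
        s = 0.5 * smax * (x + 1.0)
        ws = 0.5 * smax * w
        u = ws * s * j0(s * geom.rho) / (2.0 * np.pi)
        spec = np.empty(omega.size, dtype=complex)
        for k0 in range(0, omega.size, freq_chunk):
            sl = slice(k0, min(k0 + freq_chunk, omega.size))
            rh = _two_layer_hat(s**2, omega[sl] / v, top, bottom, iw, l, zb, z0)
            spec[sl] = rh @ u
        # shift to bin centers and invert; clip FFT ringing at machine level
        spec *= np.exp(-1j * omega * (0.5 * dt_i))
        rt = np.fft.irfft(spec, n=n_i) / dt_i
        out[iw] = np.clip(rt[pick], 0.0, None)
    return TPSF(grid=grid, times=t, reflectance=out)


def _oversample_factor(dt: float, target: float = 5.0) -> int:
    ov = max(1, int(np.ceil(dt / target)))
    return ov if ov % 2 == 1 else ov + 1


def tpsf_two_layer_ladder(top: LayerOptics, bottoms, geom: Geometry,
                          grid: SpectralGrid | None = None,
                          n_s: int = 600, freq_chunk: int = 512) -> list:
    """Two-layer TPSFs for a sequence of bottom-layer optics with a fixed top.

    Equivalent to calling :func:`tpsf_two_layer` per level, but the top-layer
    terms of the layered Green's function (which dominate the cost) are
    computed once per wavelength and reused across levels.
    """
    if not np.isfinite(top.thickness):
        raise ValueError("top layer thickness must be finite")
    n_wl = top.mua.size
    if grid is None:
        grid = SpectralGrid(np.linspace(675.0, 875.0, n_wl)) if n_wl > 1 \
            else SpectralGrid(np.array([800.0]))
    for b in bottoms:
        if not np.isclose(top.n, b.n):
            raise NotImplementedError("unequal refractive indices between layers")
        if np.isfinite(b.thickness):
            raise ValueError("bottom layer must be unbounded")

    v = C_MM_PER_PS / top.n
    l = float(top.thickness)
    reff = effective_reflection_coefficient(top.n)
    A = (1.0 + reff) / (1.0 - reff)
    t = geom.times
    dt = geom.dt
    n_t = t.size
    ov = _oversample_factor(dt)
    dt_i = dt / ov
    n_i = n_t * ov
    omega = 2.0 * np.pi * np.fft.rfftfreq(n_i, d=dt_i)
    phase = np.exp(-1j * omega * (0.5 * dt_i))
    pick = np.arange(n_t) * ov + (ov - 1) // 2

    out = [np.empty((n_wl, n_t)) for _ in bottoms]
    for iw in range(n_wl):
        musp1 = top.musp[iw]
        D1 = 1.0 / (3.0 * musp1)
        z0 = 1.0 / musp1
        zb = 2.0 * A * D1
        smax = max(18.0 * musp1, 3.0)
        x, w = leggauss(n_s)
        s = 0.5 * smax * (x + 1.0)
        u = (0.5 * smax * w) * s * j0(s * geom.rho) / (2.0 * np.pi)
        s2 = s**2
        specs = [np.empty(omega.size, dtype=complex) for _ in bottoms]
        for k0 in range(0, omega.size, freq_chunk):
            sl = slice(k0, min(k0 + freq_chunk, omega.size))
            a1 = np.sqrt((top.mua[iw] + 1j * (omega[sl] / v)[:, None]) / D1 + s2[None, :])
            e12 = np.exp(-a1 * z0) + np.exp(-a1 * (z0 + 2.0 * zb))
            e34 = np.exp(-a1 * (2.0 * l - z0)) + np.exp(-a1 * (2.0 * l - z0 + 2.0 * zb))
            e5 = np.exp(-2.0 * a1 * (l + zb))
            d1a1 = D1 * a1
            for ib, b in enumerate(bottoms):
                D2 = 1.0 / (3.0 * b.musp[iw])
                a2 = np.sqrt((b.mua[iw] + 1j * (omega[sl] / v)[:, None]) / D2 + s2[None, :])
                kap = (D2 * a2) / d1a1
                rh = ((1.0 + kap) * e12 + (1.0 - kap) * e34) / \
                     (2.0 * ((1.0 + kap) + (1.0 - kap) * e5))
                specs[ib][sl] = rh @ u
        for ib in range(len(bottoms)):
            rt = np.fft.irfft(specs[ib] * phase, n=n_i) / dt_i
            out[ib][iw] = np.clip(rt[pick], 0.0, None)
    return [TPSF(grid=grid, times=t, reflectance=r) for r in out]


def cw_intensity(tpsf: TPSF) -> np.ndarray:
    """Time-integrated intensity per wavelength (sum over bins x bin width)."""
    return tpsf.reflectance.sum(axis=1) * tpsf.dt


def mean_tof(tpsf: TPSF) -> np.ndarray:
    """First temporal moment per wavelength, ps; NaN where total intensity is 0."""
    total = tpsf.reflectance.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = (tpsf.reflectance @ tpsf.times) / total
    return np.where(total > 0, m, np.nan)


def pathlength_from_mean_tof(mean_tofs: np.ndarray, n: float = DEFAULT_N) -> np.ndarray:
    """Optical pathlength L = (c/n) <t> in mm, with <t> in ps."""
    if n < 1:
        raise ValueError("refractive index must be >= 1")
    mt = np.asarray(mean_tofs, dtype=float)
    if np.any(mt[np.isfinite(mt)] < 0):
        raise ValueError("mean times-of-flight must be >= 0")
    return (C_MM_PER_PS / n) * mt
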