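"""Layered photon-packet Monte-Carlo oracle.

A brute-force random-walk estimate of the time-resolved reflectance of a
two-layer (slab over half-space) turbid medium, used only to validate the
diffusion forward models at a handful of wavelengths. Isotropic scattering
at the reduced scattering coefficient (similarity scaling), continuous
absorption weighting with Russian-roulette termination, Fresnel reflection
at the index-mismatched surface, and annulus detection around the nominal
source-detector separation.

The default photon budget (1e6) is a scaled-down stand-in for the budgets a
full study would use (1e7-1e8); bin noise is correspondingly larger.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .chromophores import SpectralGrid
from .constants import C_MM_PER_PS
from .forward import Geometry, LayerOptics, TPSF

__all__ = ["mc_oracle"]


@njit(cache=True, fastmath=True)
def _run_layered_mc(n_photons, seed, mua1, mus1, mua2, mus2, l, n_rel, v,
                    rho_min, rho_max, dt, n_bins, tmax_ps):
    np.random.seed(seed)
    hist = np.zeros(n_bins)
    sin_crit = 1.0 / n_rel
    max_path = v * tmax_ps
    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 1e-9
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        path = 0.0
        alive = True
        while alive:
            tau = -math.log(np.random.random())
            while True:
                in2 = z >= l
                mus = mus2 if in2 else mus1
                mua = mua2 if in2 else mua1
                step = tau / mus
                # distance to the nearest horizontal boundary along uz
                if uz < 0.0:
                    db = (0.0 - z) / uz if not in2 else (l - z) / uz
                elif uz > 0.0:
                    db = (l - z) / uz if not in2 else 1e30
                else:
                    db = 1e30
                if step < db:
                    x += ux * step
                    y += uy * step
                    z += uz * step
                    w *= math.exp(-mua * step)
                    path += step
                    break
                # move to the boundary
                x += ux * db
                y += uy * db
                z += uz * db
                w *= math.exp(-mua * db)
                path += db
                tau -= db * mus
                if uz < 0.0 and not in2:
                    # surface: Fresnel reflect or escape
                    ci = -uz
                    si = math.sqrt(max(0.0, 1.0 - ci * ci))
                    if si >= sin_crit:
                        r_f = 1.0
                    else:
                        st = si * n_rel
                        ct = math.sqrt(max(0.0, 1.0 - st * st))
                        rs = (n_rel * ci - ct) / (n_rel * ci + ct)
                        rp = (n_rel * ct - ci) / (n_rel * ct + ci)
                        r_f = 0.5 * (rs * rs + rp * rp)
                    if np.random.random() < r_f:
                        uz = -uz
                        z = 1e-9
                    else:
                        t = path / v
                        r = math.sqrt(x * x + y * y)
                        if rho_min <= r <= rho_max and t < tmax_ps:
                            ib = int(t / dt)
                            if 0 <= ib < n_bins:
                                hist[ib] += w
                        alive = False
                        break
                else:
                    # internal interface (matched index): nudge across
                    z = l + 1e-9 if uz > 0.0 else l - 1e-9
            if not alive:
                break
            if path > max_path:
                break
            if w < 1e-4:
                if np.random.random() < 0.1:
                    w *= 10.0
                else:
                    break
            # isotropic scatter
            uz = 2.0 * np.random.random() - 1.0
            phi = 2.0 * math.pi * np.random.random()
            s = math.sqrt(max(0.0, 1.0 - uz * uz))
            ux = s * math.cos(phi)
            uy = s * math.sin(phi)
    return hist


def mc_oracle(top: LayerOptics, bottom: LayerOptics, geom: Geometry,
              n_photons: int = 1_000_000, seed: int = 0,
              annulus_halfwidth: float = 2.0,
              grid: SpectralGrid | None = None) -> TPSF:
    """Monte-Carlo TPSF estimate for a two-layer medium.

    Photons exiting the surface within ``annulus_halfwidth`` mm of the
    nominal separation are binned on the geometry's time axis; identical
    seeds give bit-identical histograms. Pass identical layers for a
    homogeneous check.
    """
    if n_photons <= 0:
        raise ValueError("n_photons must be > 0")
    if not np.isclose(top.n, bottom.n):
        raise NotImplementedError("unequal refractive indices between layers")
    n_wl = top.mua.size
    if grid is None:
        grid = (SpectralGrid(np.linspace(675.0, 875.0, n_wl)) if n_wl > 1
                else SpectralGrid(np.array([800.0])))
    v = C_MM_PER_PS / top.n
    t = geom.times
    dt = geom.dt
    tmax = t[-1] + 0.5 * dt
    l = float(top.thickness) if np.isfinite(top.thickness) else 1e9
    out = np.empty((n_wl, t.size))
    for iw in range(n_wl):
        out[iw] = _run_layered_mc(
            int(n_photons), int(seed) + iw,
            float(top.mua[iw]), float(top.musp[iw]),
            float(bottom.mua[iw]), float(bottom.musp[iw]),
            l, float(top.n), v,
            geom.rho - annulus_halfwidth, geom.rho + annulus_halfwidth,
            dt, t.size, tmax)
    return TPSF(grid=grid, times=t, reflectance=out)
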