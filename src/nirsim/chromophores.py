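"""Wavelength grids, extinction tables, and phantom composition.

Maps the composition of a blood/Intralipid liquid phantom (total hemoglobin,
oxygen saturation, oxidized-CCO shift, water fraction, Intralipid volume
percent) to per-layer absorption and reduced-scattering spectra, and generates
the oxygenation trajectories and discrete deoxygenation ladders that the
simulated experiments step through.

Units follow broadband-NIRS convention throughout: wavelength in nm,
absorption in mm^-1 (natural log), concentrations in uM, specific extinction
in mm^-1 uM^-1.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "SpectralGrid",
    "ExtinctionTable",
    "PhantomState",
    "OxygenationTrajectory",
    "GridError",
    "make_mua",
    "make_musp",
    "make_levels",
    "make_trajectory",
]


class GridError(ValueError):
    """Raised when two objects are defined on different wavelength grids."""


@dataclass(frozen=True)
class SpectralGrid:
    """Uniform, strictly ascending wavelength axis in nm."""

    wavelengths: np.ndarray

    def __post_init__(self):
        wl = np.atleast_1d(np.asarray(self.wavelengths, dtype=float))
        if wl.ndim != 1 or wl.size < 1:
            raise ValueError("wavelength grid must be a 1-D array")
        if wl.size > 1:
            dw = np.diff(wl)
            if np.any(dw <= 0):
                raise ValueError("wavelengths must be strictly ascending")
            if not np.allclose(dw, dw[0], rtol=1e-8):
                raise ValueError("wavelength spacing must be uniform")
        object.__setattr__(self, "wavelengths", wl)

    @classmethod
    def default(cls) -> "SpectralGrid":
        """170 points spanning 675-875 nm (the instrument's spectral axis)."""
        return cls(np.linspace(675.0, 875.0, 170))

    @property
    def n(self) -> int:
        return self.wavelengths.size

    @property
    def spacing(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])

    def matches(self, other: "SpectralGrid") -> bool:
        return self.n == other.n and np.allclose(self.wavelengths, other.wavelengths)

    def require_match(self, other: "SpectralGrid") -> None:
        if not self.matches(other):
            raise GridError("wavelength grids do not match")


@dataclass(frozen=True)
class ExtinctionTable:
    """Specific extinction spectra of the phantom chromophores on a grid.

    ``eps_Hb``/``eps_HbO`` are the deoxy/oxy-hemoglobin specific extinction
    coefficients (mm^-1 uM^-1, natural log), ``eps_oxredCCO_diff`` the
    oxidized-minus-reduced cytochrome-c-oxidase difference extinction (its
    broad band peaks near 830 nm), and ``mua_water`` the absorption of pure
    water in mm^-1 per unit water fraction.
    """

    grid: SpectralGrid
    eps_Hb: np.ndarray
    eps_HbO: np.ndarray
    eps_oxredCCO_diff: np.ndarray
    mua_water: np.ndarray

    def __post_init__(self):
        for name in ("eps_Hb", "eps_HbO", "eps_oxredCCO_diff", "mua_water"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.grid.wavelengths.shape:
                raise GridError(f"{name} is not defined at every grid point")
            object.__setattr__(self, name, arr)
        if np.any(self.eps_Hb < 0) or np.any(self.eps_HbO < 0) or np.any(self.mua_water < 0):
            raise ValueError("hemoglobin extinctions and water absorption must be >= 0")

    @classmethod
    def from_knots(cls, grid: SpectralGrid, knots: pd.DataFrame) -> "ExtinctionTable":
        """Interpolate a knot table (monotone cubic) onto ``grid``."""
        wl = knots["wavelength_nm"].to_numpy(dtype=float)
        lo, hi = grid.wavelengths[0], grid.wavelengths[-1]
        if lo < wl[0] or hi > wl[-1]:
            raise ValueError("grid extends beyond the bundled knot range")
        cols = {}
        for name in ("eps_Hb", "eps_HbO", "eps_oxredCCO_diff", "mua_water"):
            cols[name] = PchipInterpolator(wl, knots[name].to_numpy(dtype=float))(grid.wavelengths)
        return cls(grid=grid, **cols)

    @classmethod
    def compiled(cls, grid: SpectralGrid | None = None) -> "ExtinctionTable":
        """Bundled (approximate, re-digitized) compilation of published spectra."""
        grid = grid or SpectralGrid.default()
        ref = importlib.resources.files("nirsim.data") / "extinction_knots.csv"
        with importlib.resources.as_file(ref) as path:
            knots = pd.read_csv(path, comment="#")
        return cls.from_knots(grid, knots)

    @classmethod
    def toy(cls, grid: SpectralGrid | None = None) -> "ExtinctionTable":
        """Fully synthetic Gaussian-band table (CCO band centered at 830 nm).

        Used by tests that must not depend on digitization fidelity.
        """
        grid = grid or SpectralGrid.default()
        wl = grid.wavelengths
        eps_hb = 2.3e-4 * (0.8 * np.exp(-0.5 * ((wl - 690) / 60.0) ** 2)
                           + 0.35 * np.exp(-0.5 * ((wl - 760) / 14.0) ** 2) + 0.16)
        eps_hbo = 2.3e-4 * (0.06 + 0.9 * (wl - 660.0) / 240.0)
        eps_cco = 1.15e-3 * (0.40 + 0.60 * np.exp(-0.5 * ((wl - 830) / 38.0) ** 2))
        mua_w = 1e-3 * (0.4 + 2.0 * np.exp(-0.5 * ((wl - 740) / 16.0) ** 2)
                        + 30.0 * np.exp(-0.5 * ((wl - 970) / 60.0) ** 2))
        return cls(grid=grid, eps_Hb=eps_hb, eps_HbO=eps_hbo,
                   eps_oxredCCO_diff=eps_cco, mua_water=mua_w)

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "wavelength_nm": self.grid.wavelengths,
            "eps_Hb": self.eps_Hb,
            "eps_HbO": self.eps_HbO,
            "eps_oxredCCO_diff": self.eps_oxredCCO_diff,
            "mua_water": self.mua_water,
        }).to_csv(path, index=False)


@dataclass(frozen=True)
class PhantomState:
    """Composition of one phantom layer at one instant.

    Deoxy and oxy hemoglobin are derived from (tHb, sO2), so
    Hb + HbO == tHb holds by construction.
    """

    tHb: float = 6.6
    sO2: float = 1.0
    d_oxCCO: float = 0.0
    water_fraction: float = 0.99
    intralipid_pct: float = 0.8

    def __post_init__(self):
        if self.tHb < 0:
            raise ValueError("tHb must be >= 0")
        if not 0.0 <= self.sO2 <= 1.0:
            raise ValueError("sO2 must lie in [0, 1]")
        if not 0.0 <= self.water_fraction <= 1.0:
            raise ValueError("water_fraction must lie in [0, 1]")

    @property
    def Hb(self) -> float:
        return self.tHb * (1.0 - self.sO2)

    @property
    def HbO(self) -> float:
        return self.tHb * self.sO2


@dataclass(frozen=True)
class OxygenationTrajectory:
    """Time-resolved sequence of phantom states with phase labels."""

    times: np.ndarray                      # s
    states: tuple
    phases: tuple                          # 'baseline' | 'deoxygenation' | 'reoxygenation'

    def __post_init__(self):
        if not (len(self.states) == len(self.phases) == np.asarray(self.times).size):
            raise ValueError("times, states and phases must have equal length")
        thb0 = self.states[0].tHb
        wf0 = self.states[0].water_fraction
        for s in self.states:
            if not (np.isclose(s.tHb, thb0) and np.isclose(s.water_fraction, wf0)):
                raise ValueError("tHb and water_fraction must be constant along a trajectory")

    def __len__(self) -> int:
        return len(self.states)


def make_mua(state: PhantomState, table: ExtinctionTable,
             grid: SpectralGrid | None = None) -> np.ndarray:
    """Absorption spectrum mu_a(lambda) in mm^-1 for a phantom state.

    mu_a = Hb*eps_Hb + HbO*eps_HbO + d_oxCCO*eps_diff + water_fraction*mua_water,
    clipped at zero (with a warning) if the CCO shift drives it negative.
    """
    if grid is not None:
        table.grid.require_match(grid)
    mua = (state.Hb * table.eps_Hb
           + state.HbO * table.eps_HbO
           + state.d_oxCCO * table.eps_oxredCCO_diff
           + state.water_fraction * table.mua_water)
    if np.any(mua < 0):
        warnings.warn("negative mu_a clipped to 0", stacklevel=2)
        mua = np.clip(mua, 0.0, None)
    return mua


def make_musp(intralipid_pct: float, grid: SpectralGrid,
              a_1pct: float = 1.1, b: float = 2.4) -> np.ndarray:
    """Reduced scattering spectrum of diluted Intralipid, mm^-1.

    Power law mus'(lambda) = a * (lambda/800 nm)^-b with the amplitude ``a``
    linear in the Intralipid volume percent (a_1pct at 1%). The default
    (a_1pct=1.1 mm^-1, b=2.4) is a van Staveren-type parameterization; 0.8%
    Intralipid gives mus'(800 nm) = 0.88 mm^-1.
    """
    if intralipid_pct <= 0:
        raise ValueError("intralipid_pct must be > 0")
    a = a_1pct * intralipid_pct / 1.0
    return a * (grid.wavelengths / 800.0) ** (-b)


def make_levels(n_levels: int, start: PhantomState, end: PhantomState):
    """Discrete oxygenation ladder: linear interpolation between two states.

    Level #1 is the baseline (``start``); sO2 and d_oxCCO are interpolated
    linearly so the earliest levels carry the smallest changes.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if not (np.isclose(start.tHb, end.tHb) and np.isclose(start.water_fraction, end.water_fraction)):
        raise ValueError("ladder endpoints must share tHb and water_fraction")
    fracs = np.linspace(0.0, 1.0, n_levels)
    return [replace(start,
                    sO2=float(start.sO2 + f * (end.sO2 - start.sO2)),
                    d_oxCCO=float(start.d_oxCCO + f * (end.d_oxCCO - start.d_oxCCO)))
            for f in fracs]


@dataclass(frozen=True)
class TrajectoryParams:
    """Parameters of a synthetic deoxygenation/reoxygenation experiment.

    Durations in seconds; the default cadence (one acquisition every 20 s)
    matches the concomitant TR/CW sampling of the phantom experiments.
    """

    baseline: PhantomState = field(default_factory=PhantomState)
    baseline_s: float = 480.0
    deoxygenation_s: float = 840.0
    plateau_s: float = 240.0
    reoxygenation_s: float = 480.0
    sample_period_s: float = 20.0
    max_d_oxCCO: float = -1.0
    cco_threshold_sO2: float = 0.4   # oxCCO departs from 0 once sO2 falls below this
    sigmoid_sharpness: float = 8.0

    def __post_init__(self):
        for name in ("baseline_s", "deoxygenation_s", "plateau_s", "reoxygenation_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sample_period_s <= 0:
            raise ValueError("sample_period_s must be > 0")


def _sigmoid_fall(t, t0, t1, sharpness):
    """Smooth 1 -> 0 transition over [t0, t1] (logistic in normalized time)."""
    if t1 <= t0:
        return np.where(t < t0, 1.0, 0.0)
    x = (t - t0) / (t1 - t0)
    s = 1.0 / (1.0 + np.exp(sharpness * (x - 0.5)))
    s0 = 1.0 / (1.0 + np.exp(-sharpness * 0.5))
    s1 = 1.0 / (1.0 + np.exp(sharpness * 0.5))
    return np.clip((s - s1) / (s0 - s1), 0.0, 1.0)


def make_trajectory(params: TrajectoryParams | None = None) -> OxygenationTrajectory:
    """Synthetic deoxygenation/reoxygenation time course.

    sO2 holds a baseline plateau, falls sigmoidally to 0 (the yeast consuming
    all dissolved oxygen), plateaus, and recovers sigmoidally on bubbled
    reoxygenation. The oxidized-CCO shift follows with a delay: it only leaves
    0 once sO2 falls below ``cco_threshold_sO2`` and returns toward 0 on
    reoxygenation.
    """
    p = params or TrajectoryParams()
    t_deox0 = p.baseline_s
    t_deox1 = t_deox0 + p.deoxygenation_s
    t_reox0 = t_deox1 + p.plateau_s
    t_reox1 = t_reox0 + p.reoxygenation_s
    times = np.arange(0.0, t_reox1 + 0.5 * p.sample_period_s, p.sample_period_s)

    so2_base = p.baseline.sO2
    if p.deoxygenation_s == 0:
        # zero-length deoxygenation: constant baseline trajectory
        so2 = np.full_like(times, so2_base)
    else:
        fall = _sigmoid_fall(times, t_deox0, t_deox1, p.sigmoid_sharpness)
        rise = 1.0 - _sigmoid_fall(times, t_reox0, t_reox1, p.sigmoid_sharpness)
        so2 = so2_base * np.where(times < t_reox0, fall, rise)

    # delayed CCO ramp driven by the depth of desaturation below the threshold
    thr = p.cco_threshold_sO2 * so2_base
    depth = np.clip((thr - so2) / max(thr, 1e-12), 0.0, 1.0)
    dcco = p.max_d_oxCCO * depth

    states, phases = [], []
    for t, s, c in zip(times, so2, dcco):
        if t < t_deox0:
            ph = "baseline"
        elif t < t_reox0:
            ph = "deoxygenation"
        else:
            ph = "reoxygenation"
        states.append(replace(p.baseline, sO2=float(np.clip(s, 0, 1)), d_oxCCO=float(c)))
        phases.append(ph)
    # baseline states identical to t=0 state by construction (constant plateau)
    return OxygenationTrajectory(times=times, states=tuple(states), phases=tuple(phases))
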