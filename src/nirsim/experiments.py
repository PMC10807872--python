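"""Simulation-study harness: oxygenation ladders and time-course experiments.

``run_ladder`` reproduces the simulation error study: an 11-level
deoxygenation ladder in a homogeneous or two-layer scene, analyzed with the
three methods (CW with true mean-TOF pathlength, TR tail fit at 50-20%, TR
tail fit at 5-1%), reporting per-level percent errors of the recovered
chromophore changes against the ground-truth inputs.

``run_timecourse`` simulates a full deoxygenation/reoxygenation experiment
sampled every 20 s with counting noise and optional compressive encoding in
the TR arm, and correlates the TR and CW chromophore time courses
(Spearman rank correlation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import cs as cs_mod
from .chromophores import (ExtinctionTable, PhantomState, SpectralGrid,
                           TrajectoryParams, make_levels, make_mua, make_musp,
                           make_trajectory)
from .constants import DEFAULT_N, DEFAULT_RHO, DEFAULT_TOP_THICKNESS, DEFAULT_IRF_FWHM_PS
from .cw import (CwConfig, PathlengthSpectrum, analyze_timecourse_cw,
                 delta_attenuation, fit_cw_step1, fit_cw_step2, pathlength_water)
from .forward import (Geometry, LayerOptics, cw_intensity, mean_tof,
                      pathlength_from_mean_tof, tpsf_homogeneous,
                      tpsf_two_layer_ladder)
from .instrument import PhotonBudget, apply_counting, convolve_irf, synth_irf
from .tr import (WINDOW_5_1, WINDOW_50_20, TrConfig, analyze_timecourse_tr,
                 fit_chromophores, mua_spectrum)

__all__ = [
    "ExperimentConfig",
    "ErrorSummary",
    "percent_error",
    "run_ladder",
    "run_timecourse",
]


def percent_error(estimate: float, truth: float) -> float:
    """Signed percent error (estimate - truth)/truth * 100.

    Division by the signed truth makes a negative error mean the change was
    underestimated in magnitude whatever the sign of the true change (the
    recovered signs track the truth in these studies). Zero truth is
    excluded (NaN).
    """
    if truth == 0 or not np.isfinite(truth):
        return np.nan
    return (estimate - truth) / truth * 100.0


@dataclass(frozen=True)
class ErrorSummary:
    """Mean +/- SD percent error of one method/chromophore over a level subset."""

    method: str                  # 'CW' | 'TR_50_20' | 'TR_5_1'
    chromophore: str             # 'dHb' | 'doxCCO'
    levels: tuple                # 1-based level numbers included
    errors: tuple                # per-level percent errors
    mean: float
    sd: float

    @classmethod
    def from_errors(cls, method, chromophore, levels, errors):
        e = np.asarray(errors, dtype=float)
        ok = np.isfinite(e)
        return cls(method=method, chromophore=chromophore,
                   levels=tuple(levels), errors=tuple(e),
                   mean=float(np.mean(e[ok])) if ok.any() else np.nan,
                   sd=float(np.std(e[ok], ddof=1)) if ok.sum() > 1 else np.nan)


@dataclass(frozen=True)
class ExperimentConfig:
    """Fully serializable description of a simulated experiment."""

    scene: str = "homogeneous"            # 'homogeneous' | 'two_layer'
    n_levels: int = 11
    baseline: PhantomState = field(default_factory=lambda: PhantomState(
        tHb=6.6, sO2=1.0, d_oxCCO=0.0, water_fraction=0.99, intralipid_pct=0.8))
    final_sO2: float = 0.0
    final_d_oxCCO: float = -1.0
    n_wavelengths: int = 170
    rho: float = DEFAULT_RHO
    top_thickness: float = DEFAULT_TOP_THICKNESS
    n_refractive: float = DEFAULT_N
    irf_fwhm: float = DEFAULT_IRF_FWHM_PS
    noise: bool = False
    counts_per_dtof: float | None = None   # None -> device default budget
    compression: float = 0.0
    seed: int = 0
    tr_fit_range: tuple = (680.0, 840.0)
    extinction: str = "compiled"          # 'compiled' | 'toy'
    trajectory: TrajectoryParams | None = None
    cw_pathlength: str = "mean_tof"       # 'mean_tof' | 'water_band_corrected'

    def to_dict(self):
        d = asdict(self)
        return d


def _build_scene(cfg: ExperimentConfig):
    grid = SpectralGrid(np.linspace(675.0, 875.0, cfg.n_wavelengths))
    table = (ExtinctionTable.compiled(grid) if cfg.extinction == "compiled"
             else ExtinctionTable.toy(grid))
    musp = make_musp(cfg.baseline.intralipid_pct, grid)
    return grid, table, musp


def _ladder_tpsfs(cfg: ExperimentConfig, grid, table, musp, geom):
    base = cfg.baseline
    end = replace(base, sO2=cfg.final_sO2, d_oxCCO=cfg.final_d_oxCCO)
    levels = make_levels(cfg.n_levels, base, end)
    muas = [make_mua(s, table) for s in levels]
    if cfg.scene == "homogeneous":
        tpsfs = [tpsf_homogeneous(
            LayerOptics(mua=m, musp=musp, n=cfg.n_refractive), geom, grid)
            for m in muas]
    elif cfg.scene == "two_layer":
        top = LayerOptics(mua=muas[0], musp=musp, n=cfg.n_refractive,
                          thickness=cfg.top_thickness)
        bottoms = [LayerOptics(mua=m, musp=musp, n=cfg.n_refractive)
                   for m in muas]
        tpsfs = tpsf_two_layer_ladder(top, bottoms, geom, grid)
    else:
        raise ValueError(f"unknown scene {cfg.scene!r}")
    return levels, tpsfs


def run_ladder(config: ExperimentConfig | None = None):
    """Run the ladder error study; returns (summaries, per-level DataFrame).

    Level #1 is the baseline; percent errors are computed for levels #2..#N
    (plus the #5..#N subset for doxCCO, where the early, smallest CCO changes
    are excluded). The CW arm integrates the *unconvolved* TPSFs and uses the
    true time-point-specific mean-TOF pathlength; the TR arms analyze the
    IRF-convolved DTOFs at both tail-window presets.
    """
    cfg = config or ExperimentConfig()
    grid, table, musp = _build_scene(cfg)
    geom = Geometry(rho=cfg.rho)
    levels, tpsfs = _ladder_tpsfs(cfg, grid, table, musp, geom)

    irf = synth_irf(cfg.irf_fwhm, geom.times)
    dtofs = [convolve_irf(t, irf) for t in tpsfs]
    if cfg.noise:
        counted = [apply_counting(d, budget=cfg.counts_per_dtof,
                                  seed=cfg.seed + 17 * i).counts.astype(float)
                   for i, d in enumerate(dtofs)]
    else:
        counted = [d.reflectance for d in dtofs]

    truth_hb = np.array([s.Hb - levels[0].Hb for s in levels])
    truth_cco = np.array([s.d_oxCCO - levels[0].d_oxCCO for s in levels])

    records = []

    # --- TR arms -----------------------------------------------------------
    for window, label in ((WINDOW_50_20, "TR_50_20"), (WINDOW_5_1, "TR_5_1")):
        spectra = [mua_spectrum(c, geom.times, grid, window, cfg.n_refractive)
                   for c in counted]
        base = spectra[0].mua
        for k in range(1, cfg.n_levels):
            cd = fit_chromophores(spectra[k].mua - base, table, cfg.tr_fit_range)
            records.append(dict(method=label, level=k + 1,
                                dHb=cd.d_Hb, doxCCO=cd.d_oxCCO,
                                truth_dHb=truth_hb[k], truth_doxCCO=truth_cco[k]))

    # --- CW arm ------------------------------------------------------------
    cw_I = np.stack([cw_intensity(t) for t in tpsfs])
    Ls = [PathlengthSpectrum(grid=grid,
                             L=pathlength_from_mean_tof(mean_tof(t), cfg.n_refractive),
                             source="mean_tof")
          for t in tpsfs]
    for k in range(1, cfg.n_levels):
        dA = delta_attenuation(cw_I[k], cw_I[0], grid)
        dhb = fit_cw_step1(dA, Ls[k], table)
        dcco, _, _ = fit_cw_step2(dA, Ls[k], table, dhb)
        records.append(dict(method="CW", level=k + 1,
                            dHb=dhb, doxCCO=dcco,
                            truth_dHb=truth_hb[k], truth_doxCCO=truth_cco[k]))

    df = pd.DataFrame(records)
    df["err_dHb"] = [percent_error(e, t) for e, t in zip(df.dHb, df.truth_dHb)]
    df["err_doxCCO"] = [percent_error(e, t)
                        for e, t in zip(df.doxCCO, df.truth_doxCCO)]

    summaries = []
    full = list(range(2, cfg.n_levels + 1))
    late = [k for k in full if k >= 5]
    for label in ("CW", "TR_50_20", "TR_5_1"):
        sub = df[df.method == label].set_index("level")
        summaries.append(ErrorSummary.from_errors(
            label, "dHb", full, sub.loc[full, "err_dHb"].to_numpy()))
        summaries.append(ErrorSummary.from_errors(
            label, "doxCCO", full, sub.loc[full, "err_doxCCO"].to_numpy()))
        if late and late != full:
            summaries.append(ErrorSummary.from_errors(
                label, "doxCCO_late", late, sub.loc[late, "err_doxCCO"].to_numpy()))
    return summaries, df


def _encode_decode_cube(cube, compression, seed, noise):
    """Round the spectral cube through the single-pixel acquisition chain.

    Compressed cubes are reconstructed with the smooth-ridge solver, whose
    deterministic distortion is consistent across acquisitions and therefore
    cancels in the downstream differential analysis.
    """
    ps = cs_mod.make_patterns(cube.shape[0], compression, seed)
    meas = cs_mod.encode(cube, ps, seed=seed if noise else None)
    if compression == 0.0:
        return cs_mod.decode_full(meas)
    return cs_mod.decode_cs(meas, cs_mod.CsSolverConfig(method="smooth_ridge"))


def run_timecourse(config: ExperimentConfig | None = None):
    """Simulate a deoxygenation/reoxygenation experiment; returns
    (tr DataFrame, cw DataFrame, spearman dict).

    The TR arm runs the acquisition chain (IRF convolution, photon counting,
    optional compressive encode/decode) and the tail-fit analysis; the CW arm
    integrates intensities and runs the two-step derivative analysis with the
    configured pathlength source. Spearman rho and p-values are computed
    between the paired dHb and doxCCO time courses.
    """
    cfg = config or ExperimentConfig()
    grid, table, musp = _build_scene(cfg)
    geom = Geometry(rho=cfg.rho)
    traj = make_trajectory(cfg.trajectory or TrajectoryParams(baseline=cfg.baseline))
    irf = synth_irf(cfg.irf_fwhm, geom.times)
    n_base = sum(1 for p in traj.phases if p == "baseline")

    tr_counts = []
    cw_I = []
    Ls = []
    muas = [make_mua(s, table) for s in traj.states]
    if cfg.scene == "two_layer":
        top = LayerOptics(mua=muas[0], musp=musp, n=cfg.n_refractive,
                          thickness=cfg.top_thickness)
        bottoms = [LayerOptics(mua=m, musp=musp, n=cfg.n_refractive) for m in muas]
        tpsfs = tpsf_two_layer_ladder(top, bottoms, geom, grid)
    else:
        tpsfs = [tpsf_homogeneous(LayerOptics(mua=m, musp=musp, n=cfg.n_refractive),
                                  geom, grid) for m in muas]
    for i, tp in enumerate(tpsfs):
        d = convolve_irf(tp, irf)
        if cfg.noise:
            cube = apply_counting(d, budget=cfg.counts_per_dtof,
                                  seed=cfg.seed + 1000 + i).counts.astype(float)
        else:
            cube = d.reflectance
        if cfg.compression > 0.0:
            cube = _encode_decode_cube(cube, cfg.compression,
                                       cfg.seed + 2000 + i, cfg.noise)
        tr_counts.append(cube)
        I = cw_intensity(tp)
        if cfg.noise:
            rng = np.random.default_rng(cfg.seed + 3000 + i)
            scale = PhotonBudget().expected_counts / I.mean()
            I = rng.poisson(I * scale) / scale
        cw_I.append(I)
        Ls.append(PathlengthSpectrum(
            grid=grid, L=pathlength_from_mean_tof(mean_tof(tp), cfg.n_refractive)))

    class _Cube:
        def __init__(self, counts):
            self.counts = counts
            self.grid = grid
            self.times = geom.times

    tr_df = analyze_timecourse_tr([_Cube(c) for c in tr_counts], table,
                                  TrConfig(baseline_span=n_base,
                                           fit_range=cfg.tr_fit_range))
    tr_df["time_s"] = traj.times
    tr_df["phase"] = traj.phases

    if cfg.cw_pathlength == "water_band_corrected":
        pls = [pathlength_water(cw_I[i] / cw_I[i].max(), table, Ls[i],
                                water_fraction=cfg.baseline.water_fraction)
               for i in range(len(cw_I))]
    else:
        pls = Ls
    cw_df = analyze_timecourse_cw(np.stack(cw_I), table, pls,
                                  CwConfig(baseline_span=n_base,
                                           water_fraction=cfg.baseline.water_fraction))
    cw_df["time_s"] = traj.times
    cw_df["phase"] = traj.phases

    spear = {}
    for col, name in (("dHb_uM", "dHb"), ("doxCCO_uM", "doxCCO")):
        ok = np.isfinite(tr_df[col]) & np.isfinite(cw_df[col])
        rho, p = spearmanr(tr_df[col][ok], cw_df[col][ok])
        spear[name] = {"rho": float(rho), "p": float(p), "n": int(ok.sum())}
    return tr_df, cw_df, spear
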