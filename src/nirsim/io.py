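"""File formats, configuration, and fixture generation.

DTOF/TPSF/IRF cubes live in a small HDF5 container: datasets /wavelengths
(nm), /time_bins (ps) and one group per acquisition holding /counts (integer
DTOFs) or /intensity (float TPSFs/IRFs), with a mandatory ``kind`` attribute
and unit/provenance metadata. Analysis outputs are plain CSV; run
configuration is YAML with a validated schema.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import yaml

from .chromophores import SpectralGrid

__all__ = [
    "DtofContainer",
    "FormatError",
    "read_container",
    "write_container",
    "load_config",
    "make_fixtures",
]

VALID_KINDS = ("dtof", "tpsf", "irf")


class FormatError(ValueError):
    """Container or config schema violation."""


@dataclass
class DtofContainer:
    """In-memory image of the HDF5 cube container."""

    wavelengths: np.ndarray                   # nm
    time_bins: np.ndarray                     # ps, bin centers
    acquisitions: list = field(default_factory=list)
    # each acquisition: dict(name, kind, data, attrs)
    meta: dict = field(default_factory=dict)

    @property
    def grid(self) -> SpectralGrid:
        return SpectralGrid(self.wavelengths)

    def add(self, name: str, kind: str, data: np.ndarray, **attrs) -> None:
        if kind not in VALID_KINDS:
            raise FormatError(f"kind must be one of {VALID_KINDS}, got {kind!r}")
        data = np.asarray(data)
        if data.shape != (self.wavelengths.size, self.time_bins.size):
            raise FormatError("data shape inconsistent with axes")
        self.acquisitions.append(
            {"name": name, "kind": kind, "data": data, "attrs": dict(attrs)})


def write_container(path, container: DtofContainer) -> None:
    """Write the container to HDF5 (lossless round trip with read_container)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("wavelengths", data=container.wavelengths)
        f["wavelengths"].attrs["units"] = "nm"
        f.create_dataset("time_bins", data=container.time_bins)
        f["time_bins"].attrs["units"] = "ps"
        f.create_dataset("meta", data=json.dumps(container.meta))
        for acq in container.acquisitions:
            g = f.create_group(acq["name"])
            dset = "counts" if np.issubdtype(acq["data"].dtype, np.integer) \
                else "intensity"
            g.create_dataset(dset, data=acq["data"])
            g.attrs["kind"] = acq["kind"]
            for k, v in acq["attrs"].items():
                if v is not None:
                    g.attrs[k] = v


def read_container(path) -> DtofContainer:
    """Read an HDF5 cube container, validating the schema."""
    with h5py.File(path, "r") as f:
        for req in ("wavelengths", "time_bins"):
            if req not in f:
                raise FormatError(f"container missing dataset '{req}'")
        c = DtofContainer(
            wavelengths=f["wavelengths"][()],
            time_bins=f["time_bins"][()],
            meta=json.loads(f["meta"][()]) if "meta" in f else {},
        )
        for name, item in f.items():
            if not isinstance(item, h5py.Group):
                continue
            if "kind" not in item.attrs:
                raise FormatError(f"acquisition group '{name}' missing 'kind' attribute")
            kind = item.attrs["kind"]
            if kind not in VALID_KINDS:
                raise FormatError(f"unknown kind {kind!r} in group '{name}'")
            dset = "counts" if "counts" in item else "intensity"
            if dset not in item:
                raise FormatError(f"group '{name}' missing counts/intensity dataset")
            attrs = {k: v for k, v in item.attrs.items() if k != "kind"}
            c.add(name, str(kind), item[dset][()], **attrs)
    return c


# --------------------------------------------------------------------------
# YAML run configuration

_SCHEMA = {
    "phantom": {"tHb", "sO2", "d_oxCCO", "water_fraction", "intralipid_pct",
                "final_sO2", "final_d_oxCCO", "n_levels", "trajectory"},
    "geometry": {"rho", "top_thickness", "n_refractive", "n_wavelengths",
                 "scene"},
    "instrument": {"irf_fwhm", "noise", "rep_rate_hz", "count_rate_cap",
                   "collection_time_s", "dark_rate"},
    "cs": {"compression", "alpha_rel", "debias"},
    "tr_analysis": {"window", "fit_range", "baseline_span"},
    "cw_analysis": {"smooth_window", "drift_term", "pathlength",
                    "water_fraction", "baseline_span"},
    "experiment": {"kind", "extinction"},
    "seeds": {"master"},
}


def load_config(path) -> dict:
    """Load and schema-validate a YAML run configuration.

    Unknown sections or keys are rejected with a message naming them.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise FormatError("config must be a YAML mapping")
    for section, content in doc.items():
        if section not in _SCHEMA:
            raise FormatError(f"unknown config section '{section}'")
        if content is None:
            continue
        if not isinstance(content, dict):
            raise FormatError(f"config section '{section}' must be a mapping")
        unknown = set(content) - _SCHEMA[section]
        if unknown:
            raise FormatError(
                f"unknown keys in section '{section}': {sorted(unknown)}")
    return doc


def config_hash(config: dict) -> str:
    """Stable short hash for provenance stamping of outputs."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def experiment_config_from_yaml(doc: dict):
    """Map a validated YAML document onto an ExperimentConfig."""
    from .chromophores import PhantomState
    from .experiments import ExperimentConfig

    ph = doc.get("phantom") or {}
    geo = doc.get("geometry") or {}
    ins = doc.get("instrument") or {}
    cs = doc.get("cs") or {}
    exp = doc.get("experiment") or {}
    cw = doc.get("cw_analysis") or {}
    seeds = doc.get("seeds") or {}
    baseline = PhantomState(
        tHb=ph.get("tHb", 6.6), sO2=ph.get("sO2", 1.0),
        d_oxCCO=ph.get("d_oxCCO", 0.0),
        water_fraction=ph.get("water_fraction", 0.99),
        intralipid_pct=ph.get("intralipid_pct", 0.8))
    return ExperimentConfig(
        scene=geo.get("scene", "homogeneous"),
        n_levels=ph.get("n_levels", 11),
        baseline=baseline,
        final_sO2=ph.get("final_sO2", 0.0),
        final_d_oxCCO=ph.get("final_d_oxCCO", -1.0),
        n_wavelengths=geo.get("n_wavelengths", 170),
        rho=geo.get("rho", 30.0),
        top_thickness=geo.get("top_thickness", 10.0),
        n_refractive=geo.get("n_refractive", 1.33),
        irf_fwhm=ins.get("irf_fwhm", 550.0),
        noise=ins.get("noise", False),
        compression=cs.get("compression", 0.0),
        seed=seeds.get("master", 0),
        extinction=exp.get("extinction", "compiled"),
        cw_pathlength=cw.get("pathlength", "mean_tof"),
    )


# --------------------------------------------------------------------------
# Fixture generation

def make_fixtures(path, seed: int = 0):
    """Generate a miniature experiment container (16 wavelengths, 512 bins,
    3 oxygenation levels) for tests and demos.

    Regeneration with the same seed is bit-identical. Returns the container
    (also written to ``path`` when given).
    """
    from .chromophores import (ExtinctionTable, PhantomState, make_levels,
                               make_mua, make_musp)
    from .forward import Geometry, LayerOptics, tpsf_homogeneous
    from .instrument import apply_counting, convolve_irf, synth_irf

    grid = SpectralGrid(np.linspace(675.0, 875.0, 16))
    times = (np.arange(512) + 0.5) * (20000.0 / 512)
    geom = Geometry(times=times)
    table = ExtinctionTable.compiled(grid)
    musp = make_musp(0.8, grid)
    levels = make_levels(3, PhantomState(tHb=6.6, sO2=1.0),
                         PhantomState(tHb=6.6, sO2=0.0, d_oxCCO=-1.0))
    irf = synth_irf(550.0, times)
    c = DtofContainer(wavelengths=grid.wavelengths, time_bins=times,
                      meta={"seed": seed, "levels": 3,
                            "truth_dHb": [s.Hb - levels[0].Hb for s in levels],
                            "truth_doxCCO": [s.d_oxCCO for s in levels]})
    c.add("irf", "irf", np.tile(irf.kernel, (grid.n, 1)), fwhm=irf.fwhm)
    for i, s in enumerate(levels):
        tp = tpsf_homogeneous(LayerOptics(mua=make_mua(s, table), musp=musp),
                              geom, grid)
        c.add(f"tpsf_{i:02d}", "tpsf", tp.reflectance)
        d = apply_counting(convolve_irf(tp, irf), seed=seed + i)
        c.add(f"dtof_{i:02d}", "dtof", d.counts, seed=seed + i,
              collection_time_s=d.collection_time_s)
    if path is not None:
        write_container(path, c)
    return c
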