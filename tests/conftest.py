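"""Shared fixtures: small grids, tables, and forward-model scenes."""

import numpy as np
import pytest

from nirsim.chromophores import (ExtinctionTable, PhantomState, SpectralGrid,
                                 make_mua, make_musp)
from nirsim.forward import Geometry, LayerOptics, tpsf_homogeneous


@pytest.fixture(scope="session")
def grid16():
    return SpectralGrid(np.linspace(675.0, 875.0, 16))


@pytest.fixture(scope="session")
def grid40():
    return SpectralGrid(np.linspace(675.0, 875.0, 40))


@pytest.fixture(scope="session")
def table16(grid16):
    return ExtinctionTable.compiled(grid16)


@pytest.fixture(scope="session")
def toy16(grid16):
    return ExtinctionTable.toy(grid16)


@pytest.fixture(scope="session")
def geom_small():
    """Coarser 1024-bin, 20 ns axis to keep forward models fast in tests."""
    times = (np.arange(1024) + 0.5) * (20000.0 / 1024)
    return Geometry(rho=30.0, times=times)


@pytest.fixture(scope="session")
def baseline_state():
    return PhantomState(tHb=6.6, sO2=1.0, d_oxCCO=0.0)


@pytest.fixture(scope="session")
def scene16(grid16, table16, baseline_state, geom_small):
    """Baseline homogeneous TPSF on the 16-point grid."""
    musp = make_musp(0.8, grid16)
    mua = make_mua(baseline_state, table16)
    optics = LayerOptics(mua=mua, musp=musp)
    return {
        "musp": musp,
        "mua": mua,
        "optics": optics,
        "tpsf": tpsf_homogeneous(optics, geom_small, grid16),
    }
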