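"""Shared fixtures: phase-function tables, white-MC records, and LUTs.

The Monte Carlo fixtures are deliberately desk-scale (1.5e5 photons, 3 ns
time cap) and session-scoped so the expensive transport runs happen once.
The 3 ns cap is ample for every reflectance evaluated here: applied
absorption kills the temporal tail orders of magnitude earlier (see
docs/methods.md).
"""

from __future__ import annotations

import numpy as np
import pytest

from sfdimc.forward import build_lut, build_white_mc
from sfdimc.phase_functions import (
    SthgParams,
    TtHGParams,
    build_inverse_cdf,
    eval_sthg,
    eval_tthg,
)

# the zinc-oxide-like two-term HG fit: forward lobe 0.983 with an isotropic
# backscatter fraction of 0.145
ZNO_TTHG = TtHGParams(alpha=0.855, gf=0.983, gb=0.0)

SCENE_FX = 1.0  # mm^-1, sub-diffuse spatial frequency used in image tests
SCENE_PITCH = 1.0 / 24.0  # mm per pixel: 24 pixels per period at fx=1


@pytest.fixture(scope="session")
def icdf_iso():
    return build_inverse_cdf(
        lambda c: np.full(np.shape(c), 1.0 / (4.0 * np.pi)), label="isotropic"
    )


@pytest.fixture(scope="session")
def icdf_tthg():
    return build_inverse_cdf(lambda c: eval_tthg(ZNO_TTHG, c), label="ttHG")


@pytest.fixture(scope="session")
def icdf_sthg_low():
    return build_inverse_cdf(
        lambda c: eval_sthg(SthgParams(0.84), c), label="stHG-Low"
    )


@pytest.fixture(scope="session")
def icdf_sthg_high():
    return build_inverse_cdf(
        lambda c: eval_sthg(SthgParams(0.983), c), label="stHG-High"
    )


@pytest.fixture(scope="session")
def wmc_tthg(icdf_tthg):
    return build_white_mc(
        icdf_tthg, g1=ZNO_TTHG.g1, n_photons=150_000, seed=101, t_max=3.0
    )


@pytest.fixture(scope="session")
def wmc_sthg_low(icdf_sthg_low):
    return build_white_mc(
        icdf_sthg_low, g1=0.84, n_photons=150_000, seed=102, t_max=3.0
    )


@pytest.fixture(scope="session")
def lut_tthg(wmc_tthg):
    return build_lut(wmc_tthg, fx=SCENE_FX, n_mua=80, n_mus=80)


@pytest.fixture(scope="session")
def lut_sthg_low(wmc_sthg_low):
    return build_lut(wmc_sthg_low, fx=SCENE_FX, n_mua=80, n_mus=80)
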