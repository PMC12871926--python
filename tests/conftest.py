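"""Shared fixtures: session-cached forward simulations (the expensive part)."""
from dataclasses import replace

import numpy as np
import pytest

from phlux import constants as C
from phlux.metrics import OocyteCondition
from phlux.protocol import build_protocol, with_bca
from phlux.sim import (ChemKinetics, MembraneParams, SimConfig, short_protocol,
                       simulate)


@pytest.fixture(scope="session")
def short_tl():
    return short_protocol()


@pytest.fixture(scope="session")
def truth_ctrl(short_tl):
    """Control condition (native permeability, no added CA), short protocol."""
    return simulate(SimConfig(timeline=short_tl))


@pytest.fixture(scope="session")
def grid_tl():
    """Medium-length protocol for metric-extraction comparisons: the CO2
    dimple segment before the mid recalibration is long enough that even the
    slow control relaxation yields a fittable post-peak record."""
    return build_protocol(mid_cal_frac=0.8)


@pytest.fixture(scope="session")
def truth_grid(grid_tl):
    """Ground-truth traces for the 2x2x2 condition grid (medium protocol).

    Keys: (hAQP5, hCAII present, bCA).
    """
    out = {}
    for aqp in (False, True):
        for ca in (False, True):
            for bca in (False, True):
                tl = with_bca(grid_tl) if bca else grid_tl
                cfg = SimConfig(
                    membrane=MembraneParams(
                        pm_co2=C.PM_CO2_BASE * (C.AQP5_PERM_FACTOR if aqp else 1.0)),
                    chem=ChemKinetics(A_i=C.hca2_dose_to_Ai(10.0) if ca else 1.0),
                    timeline=tl)
                out[(aqp, ca, bca)] = simulate(cfg)
    return out


@pytest.fixture(scope="session")
def truth_full_ctrl():
    """Control condition on the full-length default protocol."""
    return simulate(SimConfig(timeline=build_protocol()))


def condition_for(key):
    aqp, ca, bca = key
    return OocyteCondition(hAQP5=aqp, hCAII_ng=10.0 if ca else 0.0, bCA=bca)
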