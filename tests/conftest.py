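"""Shared fixtures.

The heavy simulation products (full-scale homogeneous sweeps, bilayer gate
profiles, TMPP retrievals) are session-scoped so that the several tests
interrogating different aspects of one simulated measurement share a single
run.  Everything is generated at test time from MASTER_SEED.
"""

from __future__ import annotations

import numpy as np
import pytest

from fnirsim import experiments as xp
from fnirsim.forward_models import (
    BilayerGeometry,
    OpticalProperties,
    SlabGeometry,
    TimeGrid,
    bilayer_td_reflectance_multi,
    slab_td_reflectance,
)
from fnirsim.tissue_dynamics import default_extinction_table

MASTER_SEED = 0

# baseline optical properties at 690 nm implied by the default tissue model
_TABLE = default_extinction_table()
BASE_MUA_690 = 30.0 * _TABLE.factors(690.0)[0] + 20.0 * _TABLE.factors(690.0)[1]
BASE_PROPS_690 = OpticalProperties(BASE_MUA_690, 10.0, 1.4)
BILAYER_GEOM = BilayerGeometry(10.0, 1.0, 4.0)
SLAB_GEOM = SlabGeometry(5.0)
GRID20 = TimeGrid(0.0, 5.0, 0.020)


@pytest.fixture(scope="session")
def extinction_table():
    return default_extinction_table()


@pytest.fixture(scope="session")
def h_ntot_table():
    return xp.run_case(xp.get_case("H_Ntot", MASTER_SEED))


@pytest.fixture(scope="session")
def h_tmeas_table():
    return xp.run_case(xp.get_case("H_Tmeas", MASTER_SEED))


@pytest.fixture(scope="session")
def h_fs_table():
    return xp.run_case(xp.get_case("H_fs", MASTER_SEED))


@pytest.fixture(scope="session")
def h_sdd_table():
    return xp.run_case(xp.get_case("H_SDD", MASTER_SEED))


@pytest.fixture(scope="session")
def degenerate_bilayer_curves():
    """Identical-layer bilayer curves vs slab per-bin integrals, both SDDs."""
    bil = bilayer_td_reflectance_multi(
        BASE_PROPS_690, BASE_PROPS_690, BILAYER_GEOM, (1.0, 4.0), GRID20
    )
    fine = TimeGrid(0.0, 5.0, 0.020 / 8)
    slabs = {}
    for sdd in (1.0, 4.0):
        vals = slab_td_reflectance(BASE_PROPS_690, SLAB_GEOM, sdd, fine).values
        slabs[sdd] = vals.reshape(GRID20.n_bins, 8).sum(axis=1)
    return {1.0: bil[0], 4.0: bil[1]}, slabs


@pytest.fixture(scope="session")
def gate_profiles():
    """Gate-wise 1 Hz contrast profiles at N̄tot = 1e6, 690 nm."""
    out = {}
    for case, sdd in (("B_UP", 1.0), ("B_DW", 1.0), ("B_DW", 4.0)):
        cfg = xp.get_case(case, MASTER_SEED)
        out[(case, sdd)] = xp.gate_contrast_profile(cfg, 1e6, sdd, 690.0)
    return out


@pytest.fixture(scope="session")
def tmpp_operators():
    """One baseline characterization (fit + pathlength operators) per SDD."""
    out = {}
    for sdd in (1.0, 4.0):
        fits, ops = xp.build_tmpp_operators(
            xp.get_case("B_UP", MASTER_SEED), 1e5, sdd
        )
        out[sdd] = {"fits": fits, "operators": ops}
    return out


@pytest.fixture(scope="session")
def tmpp_results(tmpp_operators):
    """TMPP retrievals at N̄tot = 1e5 for the depth-selectivity cases."""
    points = (
        ("B_UP", 1.0),
        ("B_UP", 4.0),
        ("B_DW", 1.0),
        ("B_DW", 4.0),
        ("B_UPDW", 4.0),
    )
    out = {}
    for case, sdd in points:
        out[(case, sdd)] = xp.tmpp_retrieve(
            xp.get_case(case, MASTER_SEED),
            1e5,
            sdd,
            operators=tmpp_operators[sdd]["operators"],
        )
    return out
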