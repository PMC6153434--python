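import numpy as np
import pytest

import hapabm as H
from hapabm.core import CellLineSpec, CellPopulation, MetabolismSpec, KillModel, SoluteSpec
from hapabm.pkpd import ProdrugModel


@pytest.fixture(scope="session")
def reg():
    return H.load_parameter_registry()


@pytest.fixture(scope="session")
def lines(reg):
    from hapabm.pkpd import cell_lines_from_registry
    return cell_lines_from_registry(reg)


@pytest.fixture()
def toy_chain_model():
    """Small three-species chain with one concentration-mode kill model."""
    pro = SoluteSpec("P", 400, 100, K_in=0.05, K_out=0.05, child="M1")
    m1 = SoluteSpec("M1", 350, 60, K_in=0.005, K_out=0.005,
                    k_chain=3.85e-4, child="M2")
    m2 = SoluteSpec("M2", 400, 150, K_in=0.01, K_out=0.005)
    return ProdrugModel(
        name="toy",
        solutes=(pro, m1, m2),
        metabolism={"ACT": MetabolismSpec(0.04, 0.126, "ACT"),
                    "TGT": MetabolismSpec(0.002, 0.126, "TGT")},
        kill_models=(KillModel("concentration", 9.2e-5, "M1"),),
        met_target="M1")


@pytest.fixture()
def toy_lines():
    return (CellLineSpec("ACT", "activator", 31 * 3600.0),
            CellLineSpec("TGT", "target", 31 * 3600.0))


@pytest.fixture()
def small_populated_grid(toy_lines):
    """~500-cell ball on a lattice, mixed lineages, seeded RNG."""
    grid = H.build_lattice(2500.0, 60.0)
    r = grid.radii()
    cells = CellPopulation(list(toy_lines))
    sites = np.flatnonzero(r < 50)
    rng = np.random.default_rng(0)
    cells.add_cells(sites, (rng.random(sites.size) > 0.5).astype(int),
                    np.full(sites.size, 2500.0))
    grid.occupancy[sites] = np.arange(sites.size)
    return grid, cells
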