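import warnings

import numpy as np
import pytest

from nanoqstr import RunConfig, run_pipeline
from nanoqstr import crystal, synthdata

#: Documented seed of the reference synthetic pipeline run used by the
#: statistical acceptance checks.
PIPELINE_SEED = 1


@pytest.fixture(scope="session")
def pipeline_state():
    """One full atomistic pipeline run on the default synthetic scenario.

    Draw count is reduced (6 per algorithm) and the bootstrap uses 200
    resamples to keep the run desk-sized; every other setting is the
    default study condition.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(RunConfig(seed=PIPELINE_SEED, n_draws=6, bootstrap_B=200))


@pytest.fixture(scope="session")
def sim_table():
    table, manifest = synthdata.simulate_viability()
    return table, manifest


@pytest.fixture()
def sc_cell():
    """Simple cubic one-site Fe cell, a = 2 Å."""
    return crystal.UnitCell(np.eye(3) * 2.0, ["Fe"], np.zeros((1, 3)), phase_id="sc")


@pytest.fixture()
def seven_atom_particle(sc_cell):
    """Centre atom plus its six 2 Å neighbours (diameter-4 Å carve)."""
    return crystal.carve_sphere(sc_cell, 4.0, center_policy="atom")
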