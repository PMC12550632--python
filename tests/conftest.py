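import numpy as np
import pytest

from cfmavidity import BondModel, CellParams, design_ramp, simulate_trial


@pytest.fixture(scope="session")
def cell():
    return CellParams()


@pytest.fixture(scope="session")
def ramp_protocol(cell):
    """Standard assay ramp: 4 pN/s to 480 pN starting after the 2 min gravity
    interval, then holding max speed while detachment completes."""
    return design_ramp(4.0, t_start_s=120.0, hold_duration_s=240.0, cell=cell)


@pytest.fixture(scope="session")
def lam2_trial(cell, ramp_protocol):
    """One simulated trial at moderate valency, shared across read-only tests."""
    return simulate_trial(
        BondModel(lam=2.0), ramp_protocol, cell=cell, n_cells=1000, seed=42
    )
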