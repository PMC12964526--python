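import numpy as np
import pytest

from fragiso.chem import SMX, smx_catalog
from fragiso.scan_io import RunConfig
from fragiso.simulate import SimulationConfig, simulate_bracketed_sequence


@pytest.fixture
def catalog():
    return smx_catalog()


@pytest.fixture
def molecule():
    return SMX


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def run_config():
    return RunConfig()


@pytest.fixture(scope="session")
def null_sequence():
    """One desk-scale bracketed sequence with sample identical to reference."""
    config = SimulationConfig(seed=7, scan_period_s=12.0)
    frame, truth = simulate_bracketed_sequence(config)
    return frame, truth


@pytest.fixture(scope="session")
def shifted_sequence():
    """A sequence with known F99 shifts (27 permil N, 4 permil C)."""
    config = SimulationConfig(
        seed=11,
        scan_period_s=12.0,
        true_deltas={("F99", "N"): 27.0, ("F99", "C"): 4.0},
    )
    frame, truth = simulate_bracketed_sequence(config)
    return frame, truth
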