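import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from occupre.simulate import SimulationConfig, simulate_tracks

CLASSES = ("dependent", "intermediate", "independent")


@pytest.fixture(scope="session")
def small_sim():
    """A scaled-down synthetic study for fast smoke tests: 12 elements on
    400 kb, default signal structure."""
    cfg = SimulationConfig(chrom_length=400_000, n_pres=12, seed=7)
    return simulate_tracks(cfg)


@pytest.fixture(scope="session")
def default_sim():
    """One full-scale synthetic study under default conditions."""
    return simulate_tracks(SimulationConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
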