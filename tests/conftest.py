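import numpy as np
import pytest

from motifeeg import SimConfig, reference_montage, simulate_epochset
from motifeeg.signal_io import Montage


@pytest.fixture(scope="session")
def montage():
    return reference_montage()


@pytest.fixture(scope="session")
def mini_montage():
    """Six channels with two left/right pairs; enough for pair features."""
    return Montage(("A1", "A2", "B1", "B2", "C1", "C2"),
                   (("A1", "A2"), ("B1", "B2")))


@pytest.fixture(scope="session")
def small_sets():
    """Two simulated subjects, 8 short trials each (planted defaults)."""
    return simulate_epochset(
        SimConfig(n_subjects=2, n_trials=8, duration_s=6.0, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
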