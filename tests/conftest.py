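import numpy as np
import pandas as pd
import pytest

from dtfnet.datatypes import EpochSet
from dtfnet.synth import CouplingSpec, make_band_resonant_spec, simulate_mvar

FS = 2000.0


@pytest.fixture(scope="session")
def two_channel_spec():
    """2-channel ground truth with one-way coupling 0 -> 1 (both bands)."""
    return make_band_resonant_spec(2, coupling_edges=[(0, 1, 0.35)], center_spread=0.0)


@pytest.fixture(scope="session")
def ar1_spec():
    return CouplingSpec(
        n_channels=1, order=1, coeff_tensor=np.array([[[0.5]]]), noise_cov=np.eye(1),
        sampling_rate_hz=FS,
    )


@pytest.fixture(scope="session")
def ar1_recording(ar1_spec):
    return simulate_mvar(ar1_spec, 20000, seed=42)


@pytest.fixture(scope="session")
def white_noise_recording():
    spec = CouplingSpec(
        n_channels=3, order=1, coeff_tensor=np.zeros((1, 3, 3)), noise_cov=np.eye(3),
        sampling_rate_hz=FS,
    )
    return simulate_mvar(spec, 20000, seed=7)


@pytest.fixture()
def small_epochs():
    """A tiny labelled EpochSet (white noise) for container/IO tests."""
    rng = np.random.default_rng(0)
    data = rng.standard_normal((6, 200, 3))
    labels = pd.DataFrame(
        {
            "group": ["control", "control", "pro", "pro", "PRO", "PRO"],
            "day": [1, 1, 1, 1, 1, 1],
            "subject": [0, 0, 0, 0, 0, 0],
            "section": [0, 1, 0, 1, 0, 1],
        }
    )
    return EpochSet(data, FS, labels, event_index=100)
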