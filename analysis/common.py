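"""Shared plumbing for the numbered analysis scripts.

The study epochs are cached under scratch/ (large, regenerable binaries);
every script regenerates them from the seed if the cache is missing, so the
chain can be run in any order.
"""

from __future__ import annotations

from pathlib import Path

from dtfnet.datatypes import EpochSet
from dtfnet.io import read_epochs_hdf5, write_epochs_hdf5
from dtfnet.synth import default_base_spec, simulate_experiment
from dtfnet.experiments import study_design

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

DEFAULT_SEED = 7
N_CHANNELS = 16


def study_epochs(seed: int = DEFAULT_SEED, attenuated: bool = True) -> EpochSet:
    """Load the cached study for this seed, simulating it if necessary."""
    SCRATCH.mkdir(exist_ok=True)
    tag = "dosed" if attenuated else "null"
    cache = SCRATCH / f"study_{tag}_seed{seed}.h5"
    if cache.exists():
        return read_epochs_hdf5(cache)
    design = study_design(seed, attenuated=attenuated)
    epochs = simulate_experiment(design, default_base_spec(N_CHANNELS))
    write_epochs_hdf5(epochs, cache)
    return epochs


def results_dir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
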