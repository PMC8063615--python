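import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from icmprofile import SimConfig, Spectrum, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_config():
    """One animal per group, one ejaculate, reduced spot count: fast but
    preserves the acquisition hierarchy."""
    return SimConfig(
        n_fertile=1,
        n_subfertile=1,
        n_ejaculates=1,
        n_spots=4,
        n_acquisitions_per_spot=3,
        mz_range=(1000.0, 15000.0),
        mz_step=1.0,
        n_base_peaks=20,
        n_differential=2,
        differential_fc=(2.0, 0.5),
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return simulate_dataset(tiny_config)


def make_spectrum(mz=None, intensity=None, **meta) -> Spectrum:
    if intensity is None and mz is None:
        mz = np.arange(1000.0, 1100.0)
    if intensity is None:
        intensity = np.ones_like(np.asarray(mz, dtype=float))
    if mz is None:
        mz = np.arange(1000.0, 1000.0 + len(intensity))
    return Spectrum(mz=np.asarray(mz, float), intensity=np.asarray(intensity, float), meta=meta)
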