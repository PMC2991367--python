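"""Shared fixtures: one small synthetic study per session.

Everything derives from one root seed so the suite is fully reproducible;
the library/noise/bank triple is the expensive part and is built once.
"""

import numpy as np
import pytest

from matchedpsc import (
    DetectionConfig,
    synth_noise_library,
    synth_template_library,
    train_bank_from_library,
)

ROOT_SEED = 0


@pytest.fixture(scope="session")
def study():
    """(template library, noise library, trained bank) from the root seed."""
    root = np.random.default_rng(ROOT_SEED)
    lib_rng, noise_rng = root.spawn(2)
    library = synth_template_library(10, rng=lib_rng)
    noise = synth_noise_library(20, rng=noise_rng)
    bank = train_bank_from_library(library)
    return library, noise, bank


@pytest.fixture(scope="session")
def library(study):
    return study[0]


@pytest.fixture(scope="session")
def noise(study):
    return study[1]


@pytest.fixture(scope="session")
def bank(study):
    return study[2]


@pytest.fixture(scope="session")
def det_config(noise):
    """Detection settings for SNR-9 trials (spontaneous-level cutoff)."""
    return DetectionConfig(amplitude_cutoff=noise.amplitude_cutoff(9.0, n_sd=1.0))
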