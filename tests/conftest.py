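import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from nodulefuse.synthetic import SynthConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but non-trivial synthetic dataset shared across tests."""
    config = SynthConfig(n_nodule=24, n_nonnodule=12, seed=7)
    stacks, manifest = generate_dataset(config)
    return config, stacks, manifest
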