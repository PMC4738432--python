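import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))   # make oracles importable

from grassflam import synthdata


@pytest.fixture(scope="session")
def small_spec():
    return synthdata.GeneratorSpec(seed=5, n_species=6, n_individuals=3)


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    """A 6-species x 3-individual synthetic study shared across tests."""
    return synthdata.gen_study(small_spec)


@pytest.fixture(scope="session")
def noiseless_bundle():
    spec = synthdata.GeneratorSpec(
        seed=9, n_species=5, n_individuals=2,
        mass_loss_noise_sd_g=0.0, leaf_noise_cv=0.0, profile_noise_cv=0.0,
    )
    return synthdata.gen_study(spec)


@pytest.fixture(scope="session")
def tree25():
    return synthdata.gen_tree(25, seed=17)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
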