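import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from soltemp.synthetic_traj import (
    AB42_SEQUENCE,
    SynthConfig,
    build_peptide_topology,
    generate_ensemble,
)


@pytest.fixture(scope="session")
def peptide_topology():
    return build_peptide_topology(AB42_SEQUENCE)


@pytest.fixture(scope="session")
def small_ensemble():
    """A modest planted ensemble shared by the analysis tests."""
    config = SynthConfig(n_frames=120, seed=7)
    return generate_ensemble(config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
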