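import numpy as np
import pytest

from cofoldeval import synthetic_data as sd


@pytest.fixture(scope="session")
def receptor():
    return sd.make_receptor(seed=3)


@pytest.fixture(scope="session")
def pose_spec():
    return sd.PoseSpec()


@pytest.fixture(scope="session")
def small_library():
    """Four-scaffold synthetic library (40 ligands), shared across tests."""
    return sd.make_ligand_library(sd.LibrarySpec(n_ligands=40, n_scaffolds=4), seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
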