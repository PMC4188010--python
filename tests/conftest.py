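import numpy as np
import pytest

from droptex.filterbank import build_filter_bank
from droptex.pipeline import build_reference_dictionary
from droptex.segmentation import build_background
from droptex.synthetic import generate_empty_plate

MASTER_SEED = 1


@pytest.fixture(scope="session")
def bank():
    return build_filter_bank(0.5)


@pytest.fixture(scope="session")
def background():
    """Background model built from a small synthetic empty plate."""
    return build_background(generate_empty_plate(3, seed=MASTER_SEED))


@pytest.fixture(scope="session")
def reference_dictionary():
    """The default 300-entry dictionary from the seeded synthetic sets.

    Built once per session; several minutes of VB-GMM clustering.
    """
    return build_reference_dictionary(seed=MASTER_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(MASTER_SEED)
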