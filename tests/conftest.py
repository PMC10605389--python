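import numpy as np
import pytest
from hypothesis import settings

from immunoscore import make_signature

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_signature():
    """A compact well-conditioned signature: 60 genes x 6 types, 2 T subsets."""
    return make_signature(n_genes=60, n_cell_types=6, n_t_cell_types=2, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
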