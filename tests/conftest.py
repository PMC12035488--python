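import numpy as np
import pytest

from mrsisr.phantom import Grade, generate_subject
from mrsisr.synthesis import build_dataset


@pytest.fixture(scope="session")
def small_cohort():
    """Two small phantom subjects (one per grade), three slices each."""
    return [generate_subject(11, Grade.LGG, n_slices=3),
            generate_subject(12, Grade.HGG, n_slices=3)]


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    return build_dataset(small_cohort, mode="deterministic", seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
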