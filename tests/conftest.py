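import numpy as np
import pytest

from fcscaffold.synthetic import CohortSpec, ModuleSpec


def random_correlation_like(rng: np.random.Generator, n: int) -> np.ndarray:
    """A random symmetric weight matrix with distinct off-diagonal entries."""
    w = rng.random((n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return w


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """Tiny cohort: two chain modules over 7 ROIs, fast to sample."""
    return CohortSpec(
        modules=[
            ModuleSpec("A", [0, 1, 2, 3], "chain"),
            ModuleSpec("B", [4, 5, 6], "chain"),
        ],
        n_subjects=5,
        n_timepoints=60,
        r_within=0.6,
        r_between=0.1,
        subject_noise_sd=0.05,
        seed=7,
    )


@pytest.fixture
def four_node_w():
    """The worked 4-node weight matrix with two reciprocated pairs."""
    return np.array(
        [
            [0.0, 0.9, 0.2, 0.3],
            [0.9, 0.0, 0.4, 0.1],
            [0.2, 0.4, 0.0, 0.8],
            [0.3, 0.1, 0.8, 0.0],
        ]
    )
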