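import warnings

import numpy as np
import pytest

import petresponse as pr


@pytest.fixture(scope="session")
def default_cohort():
    """The default 2/6/27/28 cohort at seed 0."""
    return pr.generate_cohort(pr.CohortConfig(rng_seed=0))


@pytest.fixture(scope="session")
def default_dataset(default_cohort):
    """Extracted 63 x 350 dataset of the default cohort (shared: ~7 s)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        samples = pr.build_dataset(default_cohort)
    return samples


@pytest.fixture(scope="session")
def default_xy(default_dataset):
    return pr.feature_matrix(default_dataset)


def random_roi(rng: np.random.Generator, size: int = 12, n_levels: int = 16):
    """A random quantized ROI with a random (non-empty, >=3x3 bbox) mask."""
    img = rng.random((size, size))
    mask = np.zeros((size, size), dtype=bool)
    r0, c0 = rng.integers(0, size - 4, size=2)
    h, w = rng.integers(4, size - max(r0, c0), size=2)
    mask[r0 : r0 + h, c0 : c0 + w] = True
    # poke random holes but keep plenty of pixels
    holes = rng.random((size, size)) < 0.2
    mask &= ~holes
    if mask.sum() < 8:
        mask[r0 : r0 + 3, c0 : c0 + 3] = True
    return img, mask
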