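import numpy as np
import pytest

from gliomics.synthetic import SyntheticCohortSpec, gen_study


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale cohort spec: tumors fit comfortably in a 48-cube."""
    return SyntheticCohortSpec(
        n_patients=6, volume_shape=(48, 48, 48),
        ncr_radius=(2.5, 4.0), et_radius=(5.0, 7.0), ed_radius=(8.0, 11.0),
        seed=42,
    )


@pytest.fixture(scope="session")
def study(small_spec):
    return gen_study(small_spec, 0, mutated=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_level_volume(rng, max_side=6, n_levels=4, fill=0.7):
    """Small random discretized ROI: levels 1..n_levels, 0 = background."""
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    levels = rng.integers(1, n_levels + 1, size=shape).astype(np.int32)
    levels[rng.random(shape) > fill] = 0
    if not (levels > 0).any():
        levels[tuple(rng.integers(0, s) for s in shape)] = 1
    return levels
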