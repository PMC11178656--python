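import numpy as np
import pytest

from gliorad import CohortSpec, FrameSchedule


@pytest.fixture(scope="session")
def fet_schedule() -> FrameSchedule:
    return FrameSchedule.fet_standard()


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """A desk-scale cohort: 12 subjects on a 48^3 grid."""
    return CohortSpec(n_subjects=12, grid_shape=(48, 48, 48), seed=7)


@pytest.fixture(scope="session")
def noisefree_spec() -> CohortSpec:
    """Noise-free generator settings for exact kinetic-contract checks."""
    return CohortSpec(
        n_subjects=4,
        grid_shape=(48, 48, 48),
        noise_sd={"fet_dynamic": 0.0, "tspo": 0.0, "t1ce": 0.0, "t2": 0.0},
        seed=3,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_level_grid(rng, shape=(6, 6, 6), n_levels=4, mask_frac=0.7) -> np.ndarray:
    """A random discretized ROI: levels 1..n_levels inside, 0 outside."""
    levels = rng.integers(1, n_levels + 1, size=shape)
    mask = rng.random(shape) < mask_frac
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    return np.where(mask, levels, 0)
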