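import numpy as np
import pytest

from ratssm.data import GrayMatterStack
from ratssm.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (strong effect, seed 0), imaging only."""
    stack, _, subjects, truth = generate_cohort(CohortConfig(),
                                                include_behavior=False)
    return stack, subjects, truth


@pytest.fixture(scope="session")
def full_cohort():
    """Default cohort including swim-path behavior."""
    return generate_cohort(CohortConfig(seed=0))


def random_stack(n_subjects=8, shape=(5, 5, 4), seed=0, scale_sd=0.2):
    """Small random strictly positive stack for algebraic tests."""
    rng = np.random.default_rng(seed)
    mask = np.ones(shape, dtype=bool)
    n_vox = int(np.prod(shape))
    data = np.exp(rng.normal(0, 0.3, (n_subjects, n_vox))
                  + rng.normal(0, scale_sd, n_subjects)[:, None])
    half = n_subjects // 2
    return GrayMatterStack(
        data=data, mask=mask, voxel_size_um=(150.0,) * 3,
        subject_ids=[f"s{i}" for i in range(n_subjects)],
        group_labels=["young"] * half + ["aged"] * (n_subjects - half),
    )


@pytest.fixture
def small_stack():
    return random_stack()
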