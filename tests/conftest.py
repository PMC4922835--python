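import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small in-memory cohort shared by evaluation tests."""
    from dcorconn.fixtures import CohortSpec, generate_cohort_blocks, stack_from_blocks

    spec = CohortSpec(
        n_participants=6,
        session_lengths=(80, 60),
        n_rois=6,
        voxels_per_roi=16,
        inhomogeneity=0.5,
        seed=99,
    )
    cohort = generate_cohort_blocks(spec)
    stack = stack_from_blocks(cohort, measures=("pcor", "mvdcor"))
    return cohort, stack
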