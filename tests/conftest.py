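"""Shared fixtures: kernels and the two expensive study results.

The slab interface study and the synthetic cohort are computed once per
session and shared between the unit/property tests and the acceptance
tests; both are fully deterministic (fixed seeds / no randomness).
"""

import numpy as np
import pytest

from y90dose import (
    CohortSpec,
    SlabSpec,
    VoxelGrid,
    analyze_cohort,
    build_voxel_kernel,
    generate_cohort,
    load_dpk,
    run_interface_study,
)


@pytest.fixture(scope="session")
def dpk():
    return load_dpk()


@pytest.fixture(scope="session")
def kern48(dpk):
    return build_voxel_kernel(dpk, voxel_mm=4.8)


@pytest.fixture(scope="session")
def interface_result(dpk, kern48):
    return run_interface_study(SlabSpec(), dpk=dpk, kernel=kern48)


@pytest.fixture(scope="session")
def cohort_bundles():
    bundles, manifest = generate_cohort(CohortSpec(master_seed=7))
    return bundles, manifest


@pytest.fixture(scope="session")
def cohort_result(cohort_bundles, dpk, kern48):
    bundles, _ = cohort_bundles
    return analyze_cohort(bundles, dpk=dpk, kernel=kern48)


def uniform_grid(n: int, value: float, spacing: float = 4.8) -> VoxelGrid:
    return VoxelGrid(np.full((n, n, n), float(value)), (spacing,) * 3)


@pytest.fixture
def uniform_maker():
    return uniform_grid
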