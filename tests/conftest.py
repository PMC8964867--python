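import numpy as np
import pytest

from atrophybench import (CohortSpec, GridSpec, build_region_atlas,
                          build_template, derive_gm_mask,
                          generate_reference_cohort, select_reference_subjects)


@pytest.fixture(scope="session")
def grid32():
    return GridSpec(shape=(32, 32, 32), voxel_size=(4.0, 4.0, 4.0))


@pytest.fixture(scope="session")
def atlas32(grid32):
    return build_region_atlas(grid32)


@pytest.fixture(scope="session")
def small_cohort_spec():
    # narrow, uniform age band so every test stratum is well populated
    return CohortSpec(n_subjects=120, age_range=(60.0, 70.0), age_mean=None,
                      sex_ratio=0.5, subject_sd=0.05, noise_sd=0.02, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_cohort_spec, grid32):
    return generate_reference_cohort(small_cohort_spec, grid32)


@pytest.fixture(scope="session")
def template_f65(small_cohort):
    selected = select_reference_subjects(small_cohort, "F", 65.0, 2.0)
    return build_template(selected, "F", 65.0, 2.0, min_n=5)


@pytest.fixture(scope="session")
def mask_f65(template_f65):
    return derive_gm_mask(template_f65)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
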