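import numpy as np
import pytest

from atrophybench import (CohortSpec, PerturbationFailure, PerturbationSpec,
                          apply_perturbation, generate_patient_scan,
                          generate_reference_cohort, mean_model,
                          simulate_repeat, zscore_map)
from atrophybench.grid import ellipsoid_profile


def _noise_free_spec(**kwargs):
    base = dict(n_subjects=2, age_range=(60.0, 70.0), age_mean=None,
                subject_sd=0.0, noise_sd=0.0, seed=3)
    base.update(kwargs)
    return CohortSpec(**base)


class TestReferenceCohort:
    def test_all_randomness_off_same_stratum_gives_identical_volumes(self, grid32):
        spec = _noise_free_spec(age_range=(65.0, 65.0), sex_ratio=1.0)
        cohort = generate_reference_cohort(spec, grid32)
        assert np.array_equal(cohort[0].volume, cohort[1].volume)
        assert np.array_equal(cohort[0].volume, mean_model(spec, grid32, 65.0, "F"))

    def test_ages_respect_range(self, grid32):
        spec = CohortSpec(n_subjects=100, age_range=(18.0, 77.0), seed=1,
                          subject_sd=0.0, noise_sd=0.0)
        ages = [s.age for s in generate_reference_cohort(spec, grid32)]
        assert all(18.0 <= a <= 77.0 for a in ages)

    def test_seed_determinism_bit_identical(self, grid32):
        spec = CohortSpec(n_subjects=5, seed=1)
        c1 = generate_reference_cohort(spec, grid32)
        c2 = generate_reference_cohort(spec, grid32)
        for s1, s2 in zip(c1, c2):
            assert s1.age == s2.age and s1.sex == s2.sex
            assert np.array_equal(s1.volume, s2.volume)

    def test_age_slope_reduces_gm_with_age(self, grid32):
        spec = _noise_free_spec(age_slope_amplitude=0.003)
        brain = ellipsoid_profile(grid32) > 0
        old = mean_model(spec, grid32, 70.0, "F")
        young = mean_model(spec, grid32, 20.0, "F")
        assert old[brain].mean() < young[brain].mean()

    def test_degenerate_grid_rejected(self):
        from atrophybench import GridSpec
        with pytest.raises(ValueError):
            GridSpec(shape=(6, 32, 32))


class TestPatientScan:
    def test_empty_regions_equals_mean_model(self, grid32, atlas32, template_f65):
        spec = _noise_free_spec()
        scan = generate_patient_scan(65.0, "F", {}, template_f65, atlas32,
                                     cohort=spec)
        assert np.array_equal(scan.volume, mean_model(spec, grid32, 65.0, "F"))

    def test_unknown_region_raises(self, atlas32, template_f65):
        with pytest.raises(KeyError, match="unknown"):
            generate_patient_scan(65.0, "F", {"amygdala": 2.0},
                                  template_f65, atlas32)

    def test_zero_effect_leaves_region_untouched(self, atlas32, template_f65):
        ref = generate_patient_scan(65.0, "F", {}, template_f65, atlas32)
        scan = generate_patient_scan(65.0, "F", {"temporal": 0.0},
                                     template_f65, atlas32)
        assert np.array_equal(scan.volume, ref.volume)

    def test_template_based_planting_recovers_exact_z(self, atlas32, template_f65,
                                                      mask_f65):
        # base = template mean, so the planted z-effect is exact by construction
        scan = generate_patient_scan(65.0, "F", {"temporal": 3.0},
                                     template_f65, atlas32)
        zm = zscore_map(scan, template_f65, mask_f65)
        region = atlas32["temporal"] & mask_f65.mask
        assert np.allclose(zm.z[region], -3.0)
        outside = mask_f65.mask & ~atlas32["temporal"]
        assert np.allclose(zm.z[outside], 0.0)


class TestRepeat:
    def test_zero_sd_is_identity(self, grid32, small_cohort):
        scan = small_cohort[0]
        rep = simulate_repeat(scan, 0.0, 8.0, seed=4, grid=grid32)
        assert np.array_equal(rep.volume, scan.volume)
        assert rep.condition == "repeat"

    def test_difference_sd_matches_repeat_sd(self, grid32, small_cohort):
        scan = small_cohort[0]
        brain = ellipsoid_profile(grid32) > 0.2  # away from the clip-at-0 edge
        rep = simulate_repeat(scan, 0.03, 8.0, seed=4, grid=grid32)
        diff = rep.volume - scan.volume
        assert diff[brain].std() == pytest.approx(0.03, rel=0.10)

    def test_seeds_differ(self, grid32, small_cohort):
        scan = small_cohort[0]
        r1 = simulate_repeat(scan, 0.02, 8.0, seed=1, grid=grid32)
        r2 = simulate_repeat(scan, 0.02, 8.0, seed=2, grid=grid32)
        assert not np.array_equal(r1.volume, r2.volume)


class TestPerturbation:
    def test_identity_spec_is_bitwise_identity(self, atlas32, small_cohort):
        scan = small_cohort[0]
        out = apply_perturbation(scan, PerturbationSpec(name="identity"), atlas32)
        assert np.array_equal(out.volume, scan.volume)
        assert out.condition == "perturbed:identity"

    def test_certain_failure(self, atlas32, small_cohort):
        pert = PerturbationSpec(name="crash", failure_prob=1.0)
        for seed in range(5):
            out = apply_perturbation(small_cohort[0], pert.with_seed(seed), atlas32)
            assert isinstance(out, PerturbationFailure)
            assert out.perturbation == "crash"

    def test_deterministic_given_seed(self, atlas32, small_cohort):
        pert = PerturbationSpec(name="p", bias_amplitude=0.02,
                                bias_center="frontobasal", jitter_mm=0.5, seed=9)
        a = apply_perturbation(small_cohort[0], pert, atlas32)
        b = apply_perturbation(small_cohort[0], pert, atlas32)
        assert np.array_equal(a.volume, b.volume)

    def test_erosion_reduces_region_density(self, atlas32, small_cohort):
        pert = PerturbationSpec(name="erode", erosion_region="temporal",
                                erosion_fraction=0.3)
        out = apply_perturbation(small_cohort[0], pert, atlas32)
        region = atlas32["temporal"]
        assert np.allclose(out.volume[region], 0.7 * small_cohort[0].volume[region])
        assert np.array_equal(out.volume[~region], small_cohort[0].volume[~region])

    def test_sharp_face_bias_leaves_brain_bitwise_unchanged(self, atlas32,
                                                            small_cohort):
        # Gaussian tail underflows to exactly 0 far from the face slab
        pert = PerturbationSpec(name="face", bias_amplitude=0.1,
                                bias_center="face_exterior", bias_decay=0.2)
        out = apply_perturbation(small_cohort[0], pert, atlas32)
        brain = ellipsoid_profile(atlas32.grid) > 0
        assert np.array_equal(out.volume[brain], small_cohort[0].volume[brain])
        assert not np.array_equal(out.volume, small_cohort[0].volume)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PerturbationSpec(failure_prob=1.5)
        with pytest.raises(ValueError):
            PerturbationSpec(global_scale=0.0)
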