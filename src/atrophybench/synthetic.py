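"""Synthetic GM-density phantoms: reference cohorts, patients, repeats, perturbations.

Every generator here is a pure function of its parameters and seed.  Volumes
represent spatially normalized, modulated and smoothed gray-matter density
maps, i.e. the product of a VBM-style preprocessing chain — generation
happens directly in the common analysis space, there is no segmentation or
registration stage to emulate.

The subject model is additive::

    GM(v) = base(v) - slope(v) * (age - 40) + sex_offset(v)
            + smooth subject field + smooth scan noise,   clipped at 0

with ``base`` a unit-shaped ellipsoidal profile, the age-decline and sex
fields sharing that spatial shape, and the random fields built by Gaussian
smoothing of white noise rescaled to a target point SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import shift as ndi_shift

from .grid import GridSpec, RegionAtlas, ellipsoid_profile, smooth_noise_field

__all__ = [
    "REFERENCE_AGE",
    "SubjectScan",
    "CohortSpec",
    "PerturbationSpec",
    "PerturbationFailure",
    "mean_model",
    "generate_reference_cohort",
    "generate_patient_scan",
    "simulate_repeat",
    "apply_perturbation",
    "default_perturbation_suite",
]

#: Centering constant for the linear age-decline term (years).
REFERENCE_AGE = 40.0

#: Peak GM density of the baseline profile (unitless density).
BASE_PEAK = 0.8


@dataclass
class SubjectScan:
    """A single subject's GM density volume plus demographics.

    ``condition`` is one of ``fullface``, ``repeat`` or ``perturbed:<name>``.
    """

    volume: np.ndarray
    age: float
    sex: str
    subject_id: str
    condition: str = "fullface"

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if not np.all(np.isfinite(self.volume)):
            raise ValueError("scan volume contains non-finite values")
        if self.volume.min() < 0:
            raise ValueError("GM density must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic reference cohort.

    Defaults emulate, at reduced n, a large adult normative cohort:
    ages 18-77 with mean ~46.3 and SD ~17.1 years (truncated normal),
    65% female.  ``age_slope_amplitude`` is peak GM density lost per year;
    ``subject_sd`` and ``noise_sd`` are point SDs of the smooth
    between-subject and within-scan fields.
    """

    n_subjects: int = 200
    age_range: tuple[float, float] = (18.0, 77.0)
    sex_ratio: float = 0.65          # fraction female
    age_slope_amplitude: float = 0.003
    subject_sd: float = 0.05
    noise_sd: float = 0.02
    smoothness_fwhm: float = 8.0     # mm
    seed: int = 0
    age_mean: float | None = 46.3    # None -> uniform over age_range
    age_sd: float = 17.1
    sex_offset: float = 0.02         # density offset of the M mean relative to F

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ValueError("sex_ratio must lie in [0, 1]")
        if self.subject_sd < 0 or self.noise_sd < 0:
            raise ValueError("SDs must be >= 0")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be (min, max)")


@dataclass(frozen=True)
class PerturbationSpec:
    """A parameterized image modification emulating a defacing-style operator.

    Applied in order: multiplicative ``global_scale``; additive Gaussian bias
    ``bias_amplitude * exp(-d^2 / (2*bias_decay^2))`` centered on
    ``bias_center`` (a region label or a voxel coordinate triple, distances in
    mm); sub-voxel translation by ``jitter_mm`` along a seeded random
    direction; density reduction by ``erosion_fraction`` inside
    ``erosion_region``.  With probability ``failure_prob`` the operator
    "crashes" and a typed failure signal is returned instead of a scan.
    """

    name: str = "perturbation"
    bias_amplitude: float = 0.0      # GM density units
    bias_center: str | tuple[float, float, float] = "face_exterior"
    bias_decay: float = 10.0         # mm (Gaussian SD)
    global_scale: float = 1.0
    jitter_mm: float = 0.0
    erosion_region: str | None = None
    erosion_fraction: float = 0.3
    failure_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.failure_prob <= 1.0):
            raise ValueError("failure_prob must lie in [0, 1]")
        if self.global_scale <= 0:
            raise ValueError("global_scale must be > 0")
        if self.bias_decay <= 0:
            raise ValueError("bias_decay must be > 0")

    def with_seed(self, seed: int) -> "PerturbationSpec":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class PerturbationFailure:
    """Typed outcome signalling that a perturbation 'crashed' on a scan."""

    subject_id: str
    perturbation: str
    stage: str = "perturbation"


def mean_model(spec: CohortSpec, grid: GridSpec, age: float, sex: str) -> np.ndarray:
    """Noise-free cohort mean GM density for a given age and sex."""
    if sex not in ("F", "M"):
        raise ValueError(f"sex must be 'F' or 'M', got {sex!r}")
    profile = ellipsoid_profile(grid)
    vol = BASE_PEAK * profile
    vol = vol - spec.age_slope_amplitude * profile * (age - REFERENCE_AGE)
    if sex == "M":
        vol = vol - spec.sex_offset * profile
    return np.clip(vol, 0.0, None)


def _draw_age(rng: np.random.Generator, spec: CohortSpec) -> float:
    lo, hi = spec.age_range
    if spec.age_mean is None:
        return float(rng.uniform(lo, hi))
    # truncated normal by rejection; deterministic given the rng state
    for _ in range(10_000):
        a = rng.normal(spec.age_mean, spec.age_sd)
        if lo <= a <= hi:
            return float(a)
    raise RuntimeError("age sampling failed to hit the requested range")


def generate_reference_cohort(spec: CohortSpec, grid: GridSpec) -> list[SubjectScan]:
    """Generate a reference cohort of healthy subjects.

    Each scan is the age/sex mean model plus a smooth subject-specific field
    (point SD ``subject_sd``) and smooth scan noise (point SD ``noise_sd``),
    clipped at zero.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    cohort: list[SubjectScan] = []
    for i in range(spec.n_subjects):
        age = _draw_age(rng, spec)
        sex = "F" if rng.random() < spec.sex_ratio else "M"
        vol = mean_model(spec, grid, age, sex)
        if spec.subject_sd > 0:
            vol = vol + smooth_noise_field(rng, grid, spec.smoothness_fwhm, spec.subject_sd)
        if spec.noise_sd > 0:
            vol = vol + smooth_noise_field(rng, grid, spec.smoothness_fwhm, spec.noise_sd)
        vol = np.clip(vol, 0.0, None)
        cohort.append(
            SubjectScan(volume=vol, age=age, sex=sex, subject_id=f"ref{i:04d}")
        )
    return cohort


def generate_patient_scan(
    age: float,
    sex: str,
    atrophy_regions: dict[str, float],
    template,
    atlas: RegionAtlas,
    *,
    cohort: CohortSpec | None = None,
    noise_sd: float = 0.0,
    smoothness_fwhm: float = 8.0,
    seed: int = 0,
    subject_id: str = "patient",
) -> SubjectScan:
    """Generate a patient scan with planted regional atrophy.

    The planted effect is expressed in z-score units by construction: inside
    each named region the GM density is reduced by ``effect * sd_map`` of the
    supplied normative template, so z-scoring against that stratum recovers a
    region mean of about ``-effect``.

    The anatomical base is the analytic cohort mean model for the patient's
    age and sex when ``cohort`` is given (the realistic end-to-end setting,
    where the template is itself an estimate), else the template's own mean
    map (in which case recovery is exact in the noise-free case).
    """
    for region in atrophy_regions:
        if region not in atlas:
            raise KeyError(f"unknown atrophy region {region!r}")
    grid = atlas.grid
    if cohort is not None:
        base = mean_model(cohort, grid, age, sex)
    else:
        base = np.asarray(template.mean_map, dtype=float).copy()
    vol = base.copy()
    for region, effect in atrophy_regions.items():
        mask = atlas[region]
        vol[mask] -= float(effect) * np.asarray(template.sd_map)[mask]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vol = vol + smooth_noise_field(rng, grid, smoothness_fwhm, noise_sd)
    vol = np.clip(vol, 0.0, None)
    return SubjectScan(volume=vol, age=age, sex=sex, subject_id=subject_id,
                       condition="fullface")


def simulate_repeat(
    scan: SubjectScan,
    repeat_sd: float,
    smoothness_fwhm: float,
    seed: int,
    grid: GridSpec | None = None,
) -> SubjectScan:
    """Simulate a within-session repeat acquisition of the same subject.

    Adds a spatially smoothed zero-mean noise field of point SD ``repeat_sd``
    (independent of the scan's own noise) and relabels the condition.
    """
    if repeat_sd < 0:
        raise ValueError("repeat_sd must be >= 0")
    if grid is None:
        grid = GridSpec(shape=scan.volume.shape,
                        voxel_size=(4.0,) * 3)
    if repeat_sd == 0:
        vol = scan.volume.copy()
    else:
        rng = np.random.default_rng(seed)
        vol = scan.volume + smooth_noise_field(rng, grid, smoothness_fwhm, repeat_sd)
        vol = np.clip(vol, 0.0, None)
    return SubjectScan(volume=vol, age=scan.age, sex=scan.sex,
                       subject_id=scan.subject_id, condition="repeat")


def _bias_center_mm(
    center: str | tuple[float, float, float], atlas: RegionAtlas
) -> np.ndarray:
    if isinstance(center, str):
        c_vox = atlas.centroid(center)
    else:
        c_vox = np.asarray(center, dtype=float)
    return c_vox * np.asarray(atlas.grid.voxel_size)


def apply_perturbation(
    scan: SubjectScan,
    pert: PerturbationSpec,
    atlas: RegionAtlas,
) -> SubjectScan | PerturbationFailure:
    """Apply a defacing-emulating perturbation to a scan.

    Returns a new scan labelled ``perturbed:<name>``, or a
    :class:`PerturbationFailure` with probability ``failure_prob``.
    Deterministic given ``pert.seed``.  Identity parameters (scale 1,
    amplitude 0, jitter 0, no erosion, failure 0) return the volume
    bit-for-bit unchanged.
    """
    rng = np.random.default_rng(pert.seed)
    if rng.random() < pert.failure_prob:
        return PerturbationFailure(subject_id=scan.subject_id, perturbation=pert.name)

    grid = atlas.grid
    vol = scan.volume.copy()
    if pert.global_scale != 1.0:
        vol = vol * pert.global_scale
    if pert.bias_amplitude != 0.0:
        center_mm = _bias_center_mm(pert.bias_center, atlas)
        idx = np.indices(grid.shape, dtype=float)
        d2 = np.zeros(grid.shape)
        for ax in range(3):
            d2 += (idx[ax] * grid.voxel_size[ax] - center_mm[ax]) ** 2
        # far tails underflow to exactly 0.0, so a sharply localized bias
        # leaves distant voxels bit-identical
        vol = vol + pert.bias_amplitude * np.exp(-d2 / (2.0 * pert.bias_decay**2))
    if pert.jitter_mm != 0.0:
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        shift_vox = direction * pert.jitter_mm / np.asarray(grid.voxel_size)
        vol = ndi_shift(vol, shift_vox, order=1, mode="nearest")
    if pert.erosion_region is not None:
        region = atlas[pert.erosion_region]
        vol[region] *= 1.0 - pert.erosion_fraction
    vol = np.clip(vol, 0.0, None)
    return SubjectScan(volume=vol, age=scan.age, sex=scan.sex,
                       subject_id=scan.subject_id,
                       condition=f"perturbed:{pert.name}")


def default_perturbation_suite(seed: int = 0) -> list[PerturbationSpec]:
    """Illustrative perturbation presets spanning mild to severe impact.

    These emulate the qualitative failure patterns reported for defacing
    tools — localized frontobasal/temporal bias near the face, slight global
    intensity change, occasional crashes — without modelling any specific
    tool.
    """
    return [
        PerturbationSpec(name="gentle_mask", bias_amplitude=0.004,
                         bias_center="frontobasal", bias_decay=15.0, seed=seed),
        PerturbationSpec(name="frontal_bias", bias_amplitude=0.02,
                         bias_center="frontobasal", bias_decay=20.0, seed=seed + 1),
        PerturbationSpec(name="temporal_erosion", bias_amplitude=0.01,
                         bias_center="temporal", bias_decay=15.0,
                         erosion_region="temporal", erosion_fraction=0.05,
                         seed=seed + 2),
        PerturbationSpec(name="global_reface", global_scale=1.02,
                         bias_amplitude=0.03, bias_center="frontal",
                         bias_decay=30.0, jitter_mm=0.4,
                         failure_prob=0.02, seed=seed + 3),
    ]
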