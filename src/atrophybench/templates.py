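"""Sex- and age-windowed normative mean/SD templates and the GM analysis mask.

For a target subject, reference subjects of the same sex whose age lies in
the closed interval [target - window, target + window] (window default
2 years) contribute to a voxel-wise mean map and sample-SD map.  The analysis
mask restricts all downstream statistics to voxels with appreciable mean GM
density and a non-degenerate SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import SubjectScan

__all__ = [
    "NormativeTemplate",
    "AnalysisMask",
    "InsufficientReferenceError",
    "select_reference_subjects",
    "build_template",
    "derive_gm_mask",
    "DEFAULT_WINDOW",
    "DEFAULT_MIN_N",
    "DEFAULT_MEAN_THRESHOLD",
    "DEFAULT_SD_FLOOR",
]

DEFAULT_WINDOW = 2.0
DEFAULT_MIN_N = 10
DEFAULT_MEAN_THRESHOLD = 0.2
DEFAULT_SD_FLOOR = 1e-6


class InsufficientReferenceError(ValueError):
    """Raised when a (sex, age) stratum has too few reference subjects."""


@dataclass
class NormativeTemplate:
    """Voxel-wise mean and SD of a reference stratum.

    ``sex`` and ``target_age`` identify the stratum; ``window`` is the
    half-width (years) of the inclusive age window; ``n_ref`` the number of
    contributing subjects.
    """

    mean_map: np.ndarray
    sd_map: np.ndarray
    sex: str
    target_age: float
    window: float = DEFAULT_WINDOW
    n_ref: int = 0

    def __post_init__(self) -> None:
        self.mean_map = np.asarray(self.mean_map, dtype=float)
        self.sd_map = np.asarray(self.sd_map, dtype=float)
        if self.mean_map.shape != self.sd_map.shape:
            raise ValueError("mean and SD maps must share a shape")
        if np.any(self.sd_map < 0):
            raise ValueError("SD map must be non-negative")


@dataclass
class AnalysisMask:
    """Boolean analysis mask with provenance of the thresholds that made it."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.n_voxels < 1:
            raise ValueError("analysis mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def select_reference_subjects(
    cohort: list[SubjectScan],
    sex: str,
    target_age: float,
    window: float = DEFAULT_WINDOW,
) -> list[SubjectScan]:
    """Subjects of matching sex with age in [target-window, target+window].

    Window endpoints are inclusive; ages are compared as floats.  May return
    an empty list.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    lo, hi = target_age - window, target_age + window
    return [s for s in cohort if s.sex == sex and lo <= s.age <= hi]


def build_template(
    selected: list[SubjectScan],
    sex: str,
    target_age: float,
    window: float = DEFAULT_WINDOW,
    min_n: int = DEFAULT_MIN_N,
) -> NormativeTemplate:
    """Voxel-wise mean and sample SD (n-1 denominator) over selected subjects.

    Raises :class:`InsufficientReferenceError` naming the stratum when fewer
    than ``min_n`` subjects are available, and always when n < 2 (the sample
    SD is undefined for a single subject).
    """
    n = len(selected)
    if n < max(min_n, 2):
        raise InsufficientReferenceError(
            f"stratum sex={sex}, age={target_age:g}±{window:g}: "
            f"{n} reference subject(s), need >= {max(min_n, 2)}"
        )
    # canonical order: exact invariance under permutation of the input list
    ordered = sorted(selected, key=lambda s: s.subject_id)
    stack = np.stack([s.volume for s in ordered], axis=0)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    return NormativeTemplate(mean_map=mean, sd_map=sd, sex=sex,
                             target_age=float(target_age), window=float(window),
                             n_ref=n)


def derive_gm_mask(
    template: NormativeTemplate,
    mean_threshold: float = DEFAULT_MEAN_THRESHOLD,
    sd_floor: float = DEFAULT_SD_FLOOR,
) -> AnalysisMask:
    """Analysis mask: voxels with mean above threshold and SD above the floor.

    Voxels at or below the SD floor are excluded rather than z-scored, which
    keeps every z-map finite on the mask.
    """
    if mean_threshold < 0 or sd_floor < 0:
        raise ValueError("thresholds must be >= 0")
    mask = (template.mean_map > mean_threshold) & (template.sd_map > sd_floor)
    if not mask.any():
        raise ValueError(
            f"empty analysis mask (mean_threshold={mean_threshold}, sd_floor={sd_floor})"
        )
    return AnalysisMask(
        mask=mask,
        provenance={
            "mean_threshold": float(mean_threshold),
            "sd_floor": float(sd_floor),
            "template_sex": template.sex,
            "template_target_age": template.target_age,
            "template_n_ref": template.n_ref,
        },
    )
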