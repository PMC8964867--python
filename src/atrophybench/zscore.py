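"""Voxel-wise z-score atrophy maps.

z(v) = (scan(v) - mean(v)) / sd(v) on the analysis mask; negative values
indicate GM density below the age/sex reference.  Off-mask voxels carry NaN
(a missing-value marker, never 0) so they cannot silently dilute downstream
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import SubjectScan
from .templates import AnalysisMask, NormativeTemplate

__all__ = ["ZScoreMap", "zscore_map", "classify_normal_range",
           "NORMAL_RANGE_LO", "NORMAL_RANGE_HI"]

#: z-scores within [-2.5, 2.5] are regarded as volume change within expected limits.
NORMAL_RANGE_LO = -2.5
NORMAL_RANGE_HI = 2.5


@dataclass
class ZScoreMap:
    """Voxel-wise atrophy z-scores; NaN outside the analysis mask."""

    z: np.ndarray
    mask: np.ndarray
    subject_id: str
    condition: str
    template_sex: str = ""
    template_target_age: float = float("nan")

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.z.shape != self.mask.shape:
            raise ValueError("z and mask shapes differ")

    def values(self) -> np.ndarray:
        """z-scores at mask voxels as a flat array."""
        return self.z[self.mask]


def zscore_map(
    scan: SubjectScan,
    template: NormativeTemplate,
    mask: AnalysisMask,
    *,
    allow_stratum_mismatch: bool = False,
) -> ZScoreMap:
    """z-score a scan against its sex/age normative template on the mask.

    The template must match the scan's grid and stratum (same sex, scan age
    within the template's window of its target age) unless
    ``allow_stratum_mismatch`` is set.
    """
    if scan.volume.shape != template.mean_map.shape:
        raise ValueError(
            f"grid mismatch: scan {scan.volume.shape} vs template {template.mean_map.shape}"
        )
    if mask.mask.shape != scan.volume.shape:
        raise ValueError("mask shape does not match the scan grid")
    if not allow_stratum_mismatch:
        if scan.sex != template.sex:
            raise ValueError(
                f"stratum mismatch: scan sex {scan.sex} vs template {template.sex}"
            )
        if abs(scan.age - template.target_age) > template.window:
            raise ValueError(
                f"stratum mismatch: scan age {scan.age:g} outside "
                f"{template.target_age:g}±{template.window:g}"
            )
    m = mask.mask
    z = np.full(scan.volume.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z[m] = (scan.volume[m] - template.mean_map[m]) / template.sd_map[m]
    if not np.all(np.isfinite(z[m])):
        raise ValueError("non-finite z-scores inside the analysis mask "
                         "(SD floor violated?)")
    return ZScoreMap(z=z, mask=m, subject_id=scan.subject_id,
                     condition=scan.condition, template_sex=template.sex,
                     template_target_age=template.target_age)


def classify_normal_range(
    zmap: ZScoreMap,
    lo: float = NORMAL_RANGE_LO,
    hi: float = NORMAL_RANGE_HI,
) -> np.ndarray:
    """Boolean field: True where lo <= z <= hi (volume change within expected limits).

    Off-mask voxels are False; interpret the result only on the mask.
    """
    if lo >= hi:
        raise ValueError("lo must be < hi")
    out = np.zeros(zmap.z.shape, dtype=bool)
    m = zmap.mask
    out[m] = (zmap.z[m] >= lo) & (zmap.z[m] <= hi)
    return out
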