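"""Impact metrics: z-map RMSE, cross-subject deviation maps, RMSE summaries.

The RMSE between two z-score maps of the same subject, over the GM analysis
mask, is the per-case impact statistic; its distribution across subjects is
summarized the way a test-retest benchmark table reports it (mean ± SD,
range, IQR, failure bookkeeping).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .templates import AnalysisMask
from .zscore import ZScoreMap

__all__ = ["ImpactRecord", "DeviationMap", "RmseSummary",
           "rmse", "deviation_map", "summarize_rmse"]


@dataclass
class ImpactRecord:
    """Per-subject, per-condition-pair RMSE with processing status.

    ``status`` is ``"ok"`` or ``"failed:<stage>"``; a failed record carries
    no RMSE and is excluded from statistics but counted separately.
    """

    subject_id: str
    condition_a: str
    condition_b: str
    rmse: float | None = None
    status: str = "ok"

    def __post_init__(self) -> None:
        if self.status == "ok":
            if self.rmse is None or self.rmse < 0:
                raise ValueError("ok record requires rmse >= 0")
        elif self.rmse is not None:
            raise ValueError("failed record must not carry an RMSE")

    @property
    def ok(self) -> bool:
        return self.status == "ok"


@dataclass
class DeviationMap:
    """Per-voxel aggregated z-score deviation over subjects (NaN off-mask)."""

    map: np.ndarray
    n_subjects: int
    absolute_first: bool = False


@dataclass
class RmseSummary:
    """Distributional summary of per-subject RMSE values."""

    mean: float
    sd: float
    min: float
    q25: float
    q75: float
    max: float
    n_ok: int
    n_failed: int
    sd_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "mean": self.mean, "sd": self.sd, "min": self.min,
            "q25": self.q25, "q75": self.q75, "max": self.max,
            "n_ok": self.n_ok, "n_failed": self.n_failed,
            "sd_defined": self.sd_defined,
        }


def _check_pair(a: ZScoreMap, b: ZScoreMap, mask: AnalysisMask) -> np.ndarray:
    m = mask.mask
    if a.z.shape != b.z.shape or a.z.shape != m.shape:
        raise ValueError("z-maps and mask must share a grid")
    if not (np.array_equal(a.mask, m) and np.array_equal(b.mask, m)):
        raise ValueError("z-maps were not computed on the given analysis mask")
    return m


def rmse(zmap_a: ZScoreMap, zmap_b: ZScoreMap, mask: AnalysisMask) -> float:
    """Root-mean-square of the voxel-wise z-score difference over the mask."""
    m = _check_pair(zmap_a, zmap_b, mask)
    if not m.any():
        raise ValueError("empty analysis mask")
    d = zmap_a.z[m] - zmap_b.z[m]
    return float(np.sqrt(np.mean(d * d)))


def deviation_map(
    pairs: list[tuple[ZScoreMap, ZScoreMap]],
    mask: AnalysisMask,
    *,
    absolute_first: bool = False,
) -> DeviationMap:
    """Aggregate spatial deviation between two conditions across subjects.

    Default is |mean over subjects of (z_a - z_b)| per voxel — the absolute
    value of the signed mean difference, which preserves the sign structure
    of systematic bias before collapsing it.  ``absolute_first=True`` instead
    averages |z_a - z_b| per subject (mean of absolute differences), which
    cannot cancel between subjects.
    """
    if not pairs:
        raise ValueError("deviation_map requires at least one pair of z-maps")
    m = mask.mask
    acc = np.zeros(m.shape, dtype=float)
    for a, b in pairs:
        _check_pair(a, b, mask)
        d = a.z - b.z
        acc += np.abs(d) if absolute_first else d
    out = np.full(m.shape, np.nan)
    if absolute_first:
        out[m] = acc[m] / len(pairs)
    else:
        out[m] = np.abs(acc[m]) / len(pairs)
    return DeviationMap(map=out, n_subjects=len(pairs), absolute_first=absolute_first)


def summarize_rmse(records: list[ImpactRecord]) -> RmseSummary:
    """Mean ± SD, range and IQR of the RMSE values of the ok records.

    Failed records are counted in ``n_failed`` and excluded from every
    statistic.  With a single ok record the SD is undefined and reported as
    0 with ``sd_defined=False``.  Percentiles use linear interpolation
    between order statistics.
    """
    ok = [r.rmse for r in records if r.ok]
    n_failed = sum(1 for r in records if not r.ok)
    if not ok:
        raise ValueError("no successfully processed records to summarize")
    vals = np.asarray(ok, dtype=float)
    sd_defined = vals.size > 1
    return RmseSummary(
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if sd_defined else 0.0,
        min=float(vals.min()),
        q25=float(np.percentile(vals, 25)),
        q75=float(np.percentile(vals, 75)),
        max=float(vals.max()),
        n_ok=int(vals.size),
        n_failed=int(n_failed),
        sd_defined=sd_defined,
    )
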