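"""Outlier criteria for per-subject RMSE values.

Two criteria are provided:

* **Iterative Grubbs's test** (maximum normalized residual / extreme
  studentized deviate).  Grubbs's test detects a single outlier; it is
  applied iteratively, removing each detected outlier and retesting until no
  more are found or fewer than 3 observations remain.
* **Benchmark percentile rule**: any value strictly greater than the p-th
  percentile (default 75th) of a test-retest benchmark sample is flagged.

The two-sided Grubbs statistic is G = max_i |x_i - mean| / s with s the
sample SD; the level-alpha critical value is

    ((n-1)/sqrt(n)) * sqrt( t^2 / (n - 2 + t^2) )

with t the upper alpha/(2n) quantile of Student's t with n-2 degrees of
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["GrubbsResult", "OutlierReport", "grubbs_statistic",
           "grubbs_critical", "iterative_grubbs", "benchmark_outliers",
           "DEFAULT_ALPHA", "DEFAULT_PERCENTILE"]

DEFAULT_ALPHA = 0.05
DEFAULT_PERCENTILE = 75.0


@dataclass
class GrubbsResult:
    """One application of the (two-sided) Grubbs statistic."""

    G: float
    candidate_index: int
    critical_value: float
    n: int
    alpha: float

    @property
    def is_outlier(self) -> bool:
        return self.G > self.critical_value


@dataclass
class OutlierReport:
    """Flagged observations under one criterion."""

    method: str                      # "grubbs" or "benchmark_percentile"
    flagged_ids: list = field(default_factory=list)
    n_total: int = 0
    parameters: dict = field(default_factory=dict)
    warning: str | None = None

    @property
    def n_flagged(self) -> int:
        return len(self.flagged_ids)


def grubbs_statistic(values: Sequence[float], alpha: float = DEFAULT_ALPHA) -> GrubbsResult:
    """Two-sided Grubbs statistic and the index of the extreme observation.

    Ties at the maximum absolute deviation resolve to the lowest index.
    Requires n >= 3 and a strictly positive sample SD.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError(f"Grubbs's test requires n >= 3, got {n}")
    s = x.std(ddof=1)
    if s <= 0:
        raise ValueError("Grubbs's test undefined for zero sample SD")
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))        # argmax returns the lowest tied index
    g = float(dev[idx] / s)
    return GrubbsResult(G=g, candidate_index=idx,
                        critical_value=grubbs_critical(n, alpha),
                        n=n, alpha=alpha)


def grubbs_critical(n: int, alpha: float = DEFAULT_ALPHA) -> float:
    """Two-sided Grubbs critical value at significance ``alpha``."""
    if n < 3:
        raise ValueError("n must be >= 3")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    t = stats.t.isf(alpha / (2.0 * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t)))


def iterative_grubbs(
    values: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
    ids: Sequence | None = None,
) -> OutlierReport:
    """Iteratively remove Grubbs outliers until none remain.

    Each iteration flags the extreme observation if G exceeds the critical
    value, removes it and retests; iteration stops when the test accepts or
    fewer than 3 observations remain.  ``flagged_ids`` lists labels (defaults
    to input indices) in removal order.  With n < 3 initially the report is
    empty and carries a warning instead of raising.
    """
    x = list(np.asarray(values, dtype=float))
    labels = list(ids) if ids is not None else list(range(len(x)))
    if len(labels) != len(x):
        raise ValueError("ids length must match values length")
    report = OutlierReport(method="grubbs", n_total=len(x),
                           parameters={"alpha": float(alpha), "sided": "two-sided"})
    if len(x) < 3:
        report.warning = f"n={len(x)} < 3: Grubbs's test not applicable"
        return report
    while len(x) >= 3:
        try:
            res = grubbs_statistic(x, alpha)
        except ValueError:           # zero SD after removals: nothing left to flag
            break
        if not res.is_outlier:
            break
        report.flagged_ids.append(labels.pop(res.candidate_index))
        x.pop(res.candidate_index)
    return report


def benchmark_outliers(
    records,
    benchmark: Sequence[float],
    percentile: float = DEFAULT_PERCENTILE,
) -> OutlierReport:
    """Flag RMSE values strictly above a benchmark percentile.

    ``records`` may be :class:`~atrophybench.metrics.ImpactRecord` objects
    (failed ones are ignored) or plain numbers.  The threshold is the
    ``percentile``-th percentile of the benchmark sample, computed with
    linear interpolation between order statistics; values exactly equal to
    the threshold are not flagged ("higher than" is strict).
    """
    bench = np.asarray(benchmark, dtype=float)
    if bench.size == 0:
        raise ValueError("benchmark sample must be non-empty")
    threshold = float(np.percentile(bench, percentile))

    pairs = []
    for i, r in enumerate(records):
        if hasattr(r, "status"):
            if r.ok:
                pairs.append((r.subject_id, float(r.rmse)))
        else:
            pairs.append((i, float(r)))
    flagged = [label for label, v in pairs if v > threshold]
    return OutlierReport(
        method="benchmark_percentile",
        flagged_ids=flagged,
        n_total=len(pairs),
        parameters={"percentile": float(percentile),
                    "threshold": threshold,
                    "n_benchmark": int(bench.size)},
    )
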