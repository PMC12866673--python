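"""Overlap classification, on-target bases (OTB) and Monte Carlo summaries.

For a target region T and a read R (both 0-based, half-open):

* overlap (OTB contribution) = max(0, min(T_end, R_end) - max(T_start, R_start))
* *full* overlap: the read contains the target (R_start <= T_start and
  T_end <= R_end); *partial*: positive overlap without containment.

A read is counted only if its overlap is at least ``min_overlap`` bases.
OTB_r is the summed overlap over counted reads in one iteration; across M
iterations the estimate is the per-iteration mean, reported with SD, SE and
both normal-approximation and empirical-percentile confidence intervals.
The optional *scaling* divides OTB_r by the target length, turning it into a
mean local depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .genome_model import TargetEntry

__all__ = [
    "OverlapRecord",
    "SummaryStats",
    "classify_overlap",
    "otb_for_target",
    "otb_for_targets_arrays",
    "summarize",
    "expected_coverage",
]


@dataclass(frozen=True)
class OverlapRecord:
    label: str
    barcode: int
    full_overlaps: int
    partial_overlaps: int
    otb: int
    scaled: Optional[float] = None

    @property
    def n_counted(self) -> int:
        return self.full_overlaps + self.partial_overlaps


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    se: float
    ci_low: float
    ci_high: float
    pct_low: float
    pct_high: float
    m: int


def classify_overlap(
    read: tuple[int, int], target: tuple[int, int]
) -> tuple[str, int]:
    """Classify one read-target pair; returns (class, overlap bases).

    Half-open semantics: intervals that merely touch do not overlap.
    """
    r_start, r_end = read
    t_start, t_end = target
    if r_start >= r_end or t_start >= t_end:
        raise ValueError("intervals must satisfy start < end")
    otb = max(0, min(t_end, r_end) - max(t_start, r_start))
    if otb == 0:
        return "none", 0
    if r_start <= t_start and t_end <= r_end:
        return "full", otb
    return "partial", otb


def otb_for_target(
    read_starts: np.ndarray,
    read_ends: np.ndarray,
    target: TargetEntry,
    min_overlap: int = 1,
    scaling: bool = False,
) -> OverlapRecord:
    """OTB and overlap tallies for one target against same-barcode reads."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    read_starts = np.asarray(read_starts)
    read_ends = np.asarray(read_ends)
    ov = np.minimum(read_ends, target.end) - np.maximum(read_starts, target.start)
    counted = ov >= min_overlap
    full = counted & (read_starts <= target.start) & (target.end <= read_ends)
    otb = int(ov[counted].sum())
    n_full = int(full.sum())
    n_partial = int(counted.sum()) - n_full
    scaled = otb / target.length if scaling else None
    return OverlapRecord(target.label, target.barcode, n_full, n_partial, otb, scaled)


def otb_for_targets_arrays(
    read_starts: np.ndarray,
    read_ends: np.ndarray,
    read_barcodes: np.ndarray,
    targets: Sequence[TargetEntry],
    min_overlap: int = 1,
    scaling: bool = False,
) -> list[OverlapRecord]:
    """Per-target records, restricting each target to its own barcode's reads."""
    read_barcodes = np.asarray(read_barcodes)
    out = []
    for t in targets:
        sel = read_barcodes == t.barcode
        out.append(
            otb_for_target(read_starts[sel], read_ends[sel], t, min_overlap, scaling)
        )
    return out


def summarize(values: Sequence[float], ci_level: float = 0.95) -> SummaryStats:
    """Cross-iteration mean/SD/SE plus normal and percentile CIs.

    Sample SD (ddof=1); M=1 degenerates to SD=SE=0 with a point CI.
    """
    vals = np.asarray(list(values), dtype=float)
    m = len(vals)
    if m == 0:
        raise ValueError("summarize requires at least one value")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if m > 1 else 0.0
    se = sd / np.sqrt(m)
    z = sps.norm.ppf(0.5 + ci_level / 2.0)
    alpha = 1.0 - ci_level
    pct_low, pct_high = np.quantile(vals, [alpha / 2.0, 1.0 - alpha / 2.0])
    return SummaryStats(
        mean=mean,
        sd=sd,
        se=float(se),
        ci_low=mean - z * se,
        ci_high=mean + z * se,
        pct_low=float(pct_low),
        pct_high=float(pct_high),
        m=m,
    )


def expected_coverage(
    mean_length: float, n_reads: float, genome_length: float
) -> float:
    """Global depth of coverage: mean read length x read count / haploid size."""
    if mean_length <= 0 or n_reads <= 0 or genome_length <= 0:
        raise ValueError("all arguments must be positive")
    return mean_length * n_reads / genome_length
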