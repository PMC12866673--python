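"""Build a genome-spanning weighted blocking mask from an empirical coverage track.

Uniform read placement is an idealisation: mappability, GC content and
chromatin state produce systematic local coverage bias in real long-read
data.  This module turns an observed per-base coverage track (BEDGRAPH)
into per-bin blocking probabilities so that simulations can reproduce the
bias:

1. tile each chromosome with fixed-size bins (last bin may be short) and
   compute the base-weighted mean coverage per bin, positions absent from
   the track counting as zero;
2. winsorize the bin means at chosen quantiles (default 10th/90th) to damp
   outliers;
3. log10-transform (with a small floor for zero-coverage bins) and
   percentile-scale to x in [0, 1] via average ranks;
4. map x through a decreasing logistic, P(block) = 1 / (1 + e^{k (x - m)}),
   so poorly covered bins (low x) block strongly and well-covered bins
   hardly at all; m is the midpoint (P = 0.5 at x = m) and k the steepness.

The result is a BED5-style weighted mask consumable by the simulation
engine's masking step.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .sim_engine import MaskSet

__all__ = [
    "MaskBuilderConfig",
    "bin_coverage",
    "winsorize",
    "transform_scale",
    "blocking_probability",
    "build_weighted_mask",
    "write_mask_bed",
]


@dataclass(frozen=True)
class MaskBuilderConfig:
    bin_size: int = 100_000
    winsor_low: float = 0.10
    winsor_high: float = 0.90
    midpoint: float = 0.5
    steepness: float = 10.0
    epsilon: float = 1e-6

    def __post_init__(self):
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if not (0 < self.winsor_low < self.winsor_high < 1):
            raise ValueError("require 0 < winsor_low < winsor_high < 1")
        if not (0 < self.midpoint < 1):
            raise ValueError("midpoint must be in (0, 1)")
        if self.steepness <= 0:
            raise ValueError("steepness must be > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


def bin_coverage(
    track: pd.DataFrame,
    chrom_sizes: Sequence[tuple[str, int]],
    bin_size: int,
) -> pd.DataFrame:
    """Tile chromosomes with bins and average the track over each bin.

    ``track`` has columns (chrom, start, end, value); intervals may not
    overlap.  Returns a DataFrame (chrom, start, end, mean_coverage) whose
    bins tile every chromosome gaplessly.
    """
    sizes = dict((str(c), int(l)) for c, l in chrom_sizes)
    track = track.copy()
    if (track["value"] < 0).any():
        raise ValueError("track values must be non-negative")
    for chrom, grp in track.groupby("chrom"):
        if chrom not in sizes:
            raise ValueError(f"track chromosome {chrom!r} not in genome")
        if (grp["end"] > sizes[chrom]).any() or (grp["start"] < 0).any():
            raise ValueError(f"track interval outside chromosome {chrom!r}")
        g = grp.sort_values("start")
        if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping track intervals on {chrom!r}")

    rows = []
    for chrom, length in sizes.items():
        n_bins = (length + bin_size - 1) // bin_size
        sums = np.zeros(n_bins)
        sub = track[track["chrom"] == chrom]
        for start, end, value in zip(sub["start"], sub["end"], sub["value"]):
            if value == 0:
                continue
            first, last = start // bin_size, (end - 1) // bin_size
            for b in range(first, last + 1):
                lo = max(start, b * bin_size)
                hi = min(end, (b + 1) * bin_size)
                sums[b] += value * (hi - lo)
        for b in range(n_bins):
            lo = b * bin_size
            hi = min(length, lo + bin_size)
            rows.append(
                {
                    "chrom": chrom,
                    "start": lo,
                    "end": hi,
                    "mean_coverage": sums[b] / (hi - lo),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_coverage"])


def winsorize(
    values: Sequence[float], q_low: float = 0.10, q_high: float = 0.90
) -> np.ndarray:
    """Clip values into [quantile(q_low), quantile(q_high)].

    Quantiles are order statistics ('lower'/'higher' interpolation), so the
    clip bounds are actual data values and winsorization is exactly
    idempotent.
    """
    if q_low >= q_high:
        raise ValueError("q_low must be < q_high")
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("winsorize requires at least one value")
    lo = np.quantile(vals, q_low, method="lower")
    hi = np.quantile(vals, q_high, method="higher")
    return np.clip(vals, lo, hi)


def transform_scale(values: Sequence[float], epsilon: float = 1e-6) -> np.ndarray:
    """log10 (with floor epsilon) then percentile-scale to [0, 1].

    Percentile scaling uses average ranks: x = (rank - 1) / (n - 1); a
    single value maps to 0.5, as do all members of an all-tied vector.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("transform_scale requires at least one value")
    logged = np.log10(np.maximum(vals, epsilon))
    if vals.size == 1:
        return np.array([0.5])
    ranks = rankdata(logged, method="average")
    return (ranks - 1.0) / (vals.size - 1.0)


def blocking_probability(
    x: Union[float, np.ndarray], m: float, k: float = 10.0
) -> Union[float, np.ndarray]:
    """Decreasing logistic map from scaled coverage x to blocking probability.

    P = 1 / (1 + e^{k (x - m)}): 0.5 at x = m, near 1 for x << m (poorly
    covered -> block), near 0 for x >> m.
    """
    if k <= 0:
        raise ValueError("steepness k must be > 0")
    x = np.asarray(x, dtype=float)
    p = 1.0 / (1.0 + np.exp(k * (x - m)))
    return float(p) if p.ndim == 0 else p


def build_weighted_mask(
    track: pd.DataFrame,
    chrom_sizes: Sequence[tuple[str, int]],
    config: MaskBuilderConfig = MaskBuilderConfig(),
) -> tuple[MaskSet, pd.DataFrame]:
    """Full pipeline: bin -> winsorize -> log10/percentile -> logistic.

    Returns the MaskSet plus the per-bin table (chrom, start, end,
    mean_coverage, x, weight).
    """
    bins = bin_coverage(track, chrom_sizes, config.bin_size)
    w = winsorize(bins["mean_coverage"], config.winsor_low, config.winsor_high)
    x = transform_scale(w, config.epsilon)
    weight = blocking_probability(x, config.midpoint, config.steepness)
    bins = bins.assign(x=x, weight=np.atleast_1d(weight))
    mask = MaskSet(
        tuple(
            (str(r.chrom), int(r.start), int(r.end), float(r.weight))
            for r in bins.itertuples()
        )
    )
    return mask, bins


def write_mask_bed(bins: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write the weighted mask as BED5 (name = bin index, 6-decimal weight)."""
    with open(path, "w") as fh:
        for i, r in enumerate(bins.itertuples()):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\tbin_{i:06d}\t{r.weight:.6f}\n"
            )
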