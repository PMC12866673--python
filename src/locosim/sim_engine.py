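"""Monte Carlo core: sample read lengths, place reads, mask, stop at coverage.

One iteration repeats {sample a length from the read-length distribution,
assign a barcode, place the read uniformly within that barcode's genome,
check it against (weighted) masked regions} until the accumulated yield
reaches ``C * G`` bases, where ``G`` is the length of ONE pre-insertion
genome copy — coverage therefore keeps its conventional x-of-one-genome
meaning and governs TOTAL yield across barcodes.  Whether mask-rejected
reads count toward the yield is the *consuming* policy: consuming=True
mimics wasted sequencing capacity (rejected reads burn yield), while
consuming=False keeps sampling until the accepted yield alone reaches the
target.

Masks carry per-interval blocking weights in [0, 1]; a read overlapping
masked intervals is rejected with probability equal to the maximum weight
among the intervals it touches (deterministic, order-independent
combination).  Rejected reads are re-drawn from scratch.

Iterations are independent: iteration j of coverage index ci uses a child
seed spawned from (master seed, ci, j), so results are identical for any
worker count.
"""

from __future__ import annotations

from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .coverage_stats import OverlapRecord, otb_for_targets_arrays, summarize
from .genome_model import (
    GenomeLayout,
    InsertionSpec,
    TargetSet,
    build_layout,
    make_roi_targets,
    place_insertions,
)
from .read_lengths import ReadLengthModel

__all__ = [
    "SimulationConfig",
    "PlacedRead",
    "MaskSet",
    "BoundMask",
    "assign_barcode",
    "place_read",
    "mask_decision",
    "run_iteration",
    "run_simulation",
    "IterationResult",
    "SimulationResult",
]

# consecutive-rejection limit before declaring the mask impassable
REJECTION_GUARD = 1_000_000


@dataclass(frozen=True)
class PlacedRead:
    barcode: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MaskSet:
    """Chromosome-local blocking intervals, each with weight in [0, 1]."""

    intervals: tuple[tuple[str, int, int, float], ...]
    consuming: bool = True

    def __post_init__(self):
        for chrom, start, end, w in self.intervals:
            if start >= end:
                raise ValueError(f"mask interval {chrom}:{start}-{end} is empty")
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"mask weight {w} outside [0, 1]")

    def bind(self, layout: GenomeLayout) -> "BoundMask":
        """Resolve intervals onto the unified axis, replicated per barcode.

        Mask coordinates live in the reference (pre-insertion) frame; they
        are not shifted by I-mode insertions.
        """
        tree = IntervalTree()
        offsets = layout.global_offsets
        for chrom, start, end, w in self.intervals:
            if chrom not in offsets:
                raise ValueError(f"mask chromosome {chrom!r} not in genome")
            if end > layout.chrom_length(chrom) or start < 0:
                raise ValueError(
                    f"mask interval {chrom}:{start}-{end} outside chromosome bounds"
                )
            for span_start, _ in layout.barcode_spans:
                g = span_start + offsets[chrom]
                tree.addi(g + start, g + end, w)
        return BoundMask(tree)


class BoundMask:
    """MaskSet resolved to global coordinates (one tree for all barcodes)."""

    def __init__(self, tree: IntervalTree):
        self.tree = tree

    def max_weight(self, start: int, end: int) -> float:
        hits = self.tree.overlap(start, end)
        return max((iv.data for iv in hits), default=0.0)

    def max_weights(self, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        return np.fromiter(
            (self.max_weight(int(s), int(e)) for s, e in zip(starts, ends)),
            dtype=float,
            count=len(starts),
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Fully resolved simulation inputs (see locosim.config for file loading)."""

    chrom_sizes: tuple[tuple[str, int], ...]
    coverages: tuple[float, ...]
    read_model: ReadLengthModel
    mode: str = "ROI"
    n_barcodes: int = 1
    barcode_weights: Optional[tuple[float, ...]] = None
    rois: tuple[tuple[str, int, int, str], ...] = ()
    insertions: Optional[InsertionSpec] = None
    masks: Optional[MaskSet] = None
    consuming: bool = True
    iterations: int = 100
    seed: int = 0
    min_overlap: int = 1
    scaling: bool = False
    workers: int = 1
    ci_level: float = 0.95
    raw: Optional[dict] = field(default=None, compare=False)

    def __post_init__(self):
        if self.mode not in ("ROI", "I"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.coverages or any(c <= 0 for c in self.coverages):
            raise ValueError("every coverage target must be > 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.barcode_weights is not None:
            if len(self.barcode_weights) != self.n_barcodes:
                raise ValueError("barcode_weights must match n_barcodes")
            if any(w < 0 for w in self.barcode_weights):
                raise ValueError("barcode_weights must be non-negative")
            if sum(self.barcode_weights) <= 0:
                raise ValueError("barcode_weights must sum to a positive value")
        if self.mode == "I" and self.insertions is None:
            raise ValueError("I mode requires an insertion spec")

    def normalized_weights(self) -> np.ndarray:
        if self.barcode_weights is None:
            return np.full(self.n_barcodes, 1.0 / self.n_barcodes)
        w = np.asarray(self.barcode_weights, dtype=float)
        return w / w.sum()


def assign_barcode(weights: Sequence[float], rng: np.random.Generator) -> int:
    """Categorical barcode draw from (unnormalised) non-negative weights."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must sum to a positive value")
    return int(rng.choice(len(w), p=w / total))


def place_read(
    layout: GenomeLayout, barcode: int, length: int, rng: np.random.Generator
) -> PlacedRead:
    """Place a read uniformly, wholly inside the barcode's genome span."""
    g_b = layout.barcode_lengths[barcode]
    if length > g_b:
        raise ValueError(
            f"read length {length} exceeds barcode genome length {g_b}"
        )
    span_start = layout.barcode_spans[barcode][0]
    start = span_start + int(rng.integers(0, g_b - length + 1))
    return PlacedRead(barcode, start, start + length)


def mask_decision(
    read: PlacedRead, masks: Optional[BoundMask], rng: np.random.Generator
) -> bool:
    """True = accept.  Reject with probability max weight among overlapped."""
    if masks is None:
        return True
    w = masks.max_weight(read.start, read.end)
    if w <= 0.0:
        return True
    if w >= 1.0:
        return False
    return bool(rng.random() >= w)


@dataclass
class IterationResult:
    coverage: float
    iteration: int
    records: list[OverlapRecord]
    n_sampled: int
    n_accepted: int
    yield_total: int           # sum of yield-counted lengths
    last_counted_length: int   # final counted read's length (stopping check)
    accepted_starts: Optional[np.ndarray] = None
    accepted_ends: Optional[np.ndarray] = None
    accepted_barcodes: Optional[np.ndarray] = None


def run_iteration(
    config: SimulationConfig,
    layout: GenomeLayout,
    targets: TargetSet,
    model: ReadLengthModel,
    masks: Optional[BoundMask],
    rng: np.random.Generator,
    coverage: Optional[float] = None,
    iteration: int = 0,
    keep_reads: bool = False,
) -> IterationResult:
    """One Monte Carlo iteration at a single coverage target.

    Reads are drawn in chunks for speed; the yield cut is exact: the final
    counted read is the first whose addition reaches ``C*G``, and every read
    sampled after it is discarded, so
    ``yield_total >= C*G > yield_total - last_counted_length``.
    """
    cov = float(coverage if coverage is not None else config.coverages[0])
    need = cov * layout.reference_length
    weights = config.normalized_weights()
    span_starts = np.array([s for s, _ in layout.barcode_spans], dtype=np.int64)
    g_b = np.asarray(layout.barcode_lengths, dtype=np.int64)

    acc_starts: list[np.ndarray] = []
    acc_ends: list[np.ndarray] = []
    acc_bc: list[np.ndarray] = []
    yield_total = 0
    n_sampled = 0
    n_accepted = 0
    last_counted = 0
    consec_rejects = 0

    mean_est = model.expected_length
    chunk = int(np.clip(1.2 * need / mean_est, 256, 262_144))

    while yield_total < need:
        lengths = model.sample(rng, chunk)
        barcodes = rng.choice(config.n_barcodes, size=chunk, p=weights)
        max_start = g_b[barcodes] - lengths
        if np.any(max_start < 0):
            bad = int(lengths[max_start < 0][0])
            raise ValueError(
                f"read length {bad} exceeds barcode genome length"
            )
        starts = span_starts[barcodes] + np.floor(
            rng.random(chunk) * (max_start + 1)
        ).astype(np.int64)
        ends = starts + lengths

        if masks is not None:
            w_star = masks.max_weights(starts, ends)
            accepted = rng.random(chunk) >= w_star
        else:
            accepted = np.ones(chunk, dtype=bool)

        counted = lengths if config.consuming else np.where(accepted, lengths, 0)
        cum = yield_total + np.cumsum(counted)
        crossing = np.nonzero(cum >= need)[0]
        if crossing.size:
            cut = int(crossing[0]) + 1  # keep reads up to the crossing one
        else:
            cut = chunk

        lengths, barcodes = lengths[:cut], barcodes[:cut]
        starts, ends, accepted = starts[:cut], ends[:cut], accepted[:cut]
        counted = counted[:cut]

        n_sampled += cut
        n_accepted += int(accepted.sum())
        yield_total += int(counted.sum())
        nz = np.nonzero(counted)[0]
        if nz.size:
            last_counted = int(counted[nz[-1]])
        acc_starts.append(starts[accepted])
        acc_ends.append(ends[accepted])
        acc_bc.append(barcodes[accepted])

        if not config.consuming:
            # track the run of consecutive rejections across chunk edges
            rej = ~accepted
            if rej.all():
                consec_rejects += cut
            else:
                last_acc = int(np.nonzero(accepted)[0][-1])
                consec_rejects = cut - 1 - last_acc
            if consec_rejects >= REJECTION_GUARD and yield_total < need:
                raise RuntimeError(
                    f"{consec_rejects} consecutive reads rejected by masks "
                    "with consuming=False: the mask blocks effectively the "
                    "whole genome and the coverage target cannot be reached"
                )

    r_starts = np.concatenate(acc_starts) if acc_starts else np.empty(0, np.int64)
    r_ends = np.concatenate(acc_ends) if acc_ends else np.empty(0, np.int64)
    r_bc = np.concatenate(acc_bc) if acc_bc else np.empty(0, np.int64)

    records = otb_for_targets_arrays(
        r_starts, r_ends, r_bc, targets.entries, config.min_overlap, config.scaling
    )
    res = IterationResult(
        coverage=cov,
        iteration=iteration,
        records=records,
        n_sampled=n_sampled,
        n_accepted=n_accepted,
        yield_total=yield_total,
        last_counted_length=last_counted,
    )
    if keep_reads:
        res.accepted_starts, res.accepted_ends, res.accepted_barcodes = (
            r_starts, r_ends, r_bc,
        )
    return res


def _iteration_rng(seed: int, cov_index: int, iteration: int) -> np.random.Generator:
    """Deterministic child RNG: identical for any worker count."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(cov_index, iteration))
    )


def _iteration_task(
    config: SimulationConfig, cov_index: int, iteration: int
) -> IterationResult:
    rng = _iteration_rng(config.seed, cov_index, iteration)
    layout = build_layout(config.chrom_sizes, config.n_barcodes)
    if config.mode == "I":
        # insertions are independent per iteration: placed from the child seed
        targets, lengths = place_insertions(layout, config.insertions, rng)
        layout = layout.with_barcode_lengths(lengths)
    else:
        targets = make_roi_targets(layout, config.rois)
    masks = config.masks.bind(layout) if config.masks is not None else None
    try:
        return run_iteration(
            config,
            layout,
            targets,
            config.read_model,
            masks,
            rng,
            coverage=config.coverages[cov_index],
            iteration=iteration,
        )
    except Exception as exc:
        raise RuntimeError(
            f"iteration {iteration} (coverage {config.coverages[cov_index]}) failed: {exc}"
        ) from exc


@dataclass
class SimulationResult:
    iterations: pd.DataFrame
    summary: pd.DataFrame


_ITER_COLUMNS = [
    "coverage", "iteration", "barcode", "target_label",
    "full_overlaps", "partial_overlaps", "otb",
]


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Run M iterations per coverage target; deterministic for any workers.

    Returns per-iteration records (one row per coverage x iteration x
    barcode x target) and cross-iteration summary statistics per
    (coverage, target label), with OTB summed over barcodes per iteration
    before summarising.
    """
    tasks = [
        (ci, j)
        for ci in range(len(config.coverages))
        for j in range(config.iterations)
    ]
    if config.workers > 1:
        with ProcessPoolExecutor(max_workers=config.workers) as ex:
            results = list(
                ex.map(
                    _iteration_task,
                    [config] * len(tasks),
                    [t[0] for t in tasks],
                    [t[1] for t in tasks],
                    chunksize=max(1, len(tasks) // (4 * config.workers)),
                )
            )
    else:
        results = [_iteration_task(config, ci, j) for ci, j in tasks]

    rows = []
    for res in results:
        for rec in res.records:
            row = {
                "coverage": res.coverage,
                "iteration": res.iteration,
                "barcode": rec.barcode,
                "target_label": rec.label,
                "full_overlaps": rec.full_overlaps,
                "partial_overlaps": rec.partial_overlaps,
                "otb": rec.otb,
            }
            if config.scaling:
                row["scaled"] = rec.scaled
            rows.append(row)
    iter_df = pd.DataFrame(
        rows, columns=_ITER_COLUMNS + (["scaled"] if config.scaling else [])
    )

    summary_rows = []
    if len(iter_df):
        # per-iteration totals per label (summing over barcodes)
        per_iter = (
            iter_df.groupby(["coverage", "target_label", "iteration"], sort=True)
            .agg(
                otb=("otb", "sum"),
                full_overlaps=("full_overlaps", "sum"),
                partial_overlaps=("partial_overlaps", "sum"),
            )
            .reset_index()
        )
        label_lengths = _label_lengths(config)
        for (cov, label), grp in per_iter.groupby(["coverage", "target_label"], sort=True):
            s = summarize(grp["otb"].to_numpy(), config.ci_level)
            row = {
                "coverage": cov,
                "target_label": label,
                "mean_otb": s.mean,
                "sd": s.sd,
                "se": s.se,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "pct_low": s.pct_low,
                "pct_high": s.pct_high,
                "mean_full": float(grp["full_overlaps"].mean()),
                "mean_partial": float(grp["partial_overlaps"].mean()),
                "m": s.m,
            }
            total_len = label_lengths.get(label)
            row["scaled_mean"] = s.mean / total_len if total_len else float("nan")
            summary_rows.append(row)
    summary_df = pd.DataFrame(
        summary_rows,
        columns=[
            "coverage", "target_label", "mean_otb", "sd", "se", "ci_low",
            "ci_high", "pct_low", "pct_high", "mean_full", "mean_partial",
            "m", "scaled_mean",
        ],
    )
    return SimulationResult(iterations=iter_df, summary=summary_df)


def _label_lengths(config: SimulationConfig) -> dict[str, int]:
    """Total target length per label for scaled (per-base depth) reporting.

    ROI labels are replicated on every barcode, so the per-iteration OTB sum
    is divided by length x n_barcodes.  In I mode the per-label divisor is a
    single insert length (scaled OTB is then depth summed over the copies
    that carry the insertion).
    """
    if config.mode == "ROI":
        return {
            label: (end - start) * config.n_barcodes
            for _, start, end, label in config.rois
        }
    L = config.insertions.insert_length if config.insertions else 0
    return _InsertLengths(L) if L else {}


class _InsertLengths(dict):
    """dict reporting the same divisor for every insertion label."""

    def __init__(self, length: int):
        super().__init__()
        self._length = length

    def get(self, key, default=None):
        return self._length
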