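"""Concatenated, barcode-replicated genome coordinate systems and target regions.

A multi-chromosome reference is flattened onto a single 0-based, half-open
coordinate axis by concatenating chromosomes in input order.  To model mixed
samples (clonal mixtures, mosaicism), the concatenated genome is replicated
once per *barcode*: each barcode owns a disjoint span of the unified axis and
represents one genome copy in the pool.  No sequence is ever materialised —
barcodes are purely coordinate spans.

Target regions come in two flavours:

* **ROI mode** — user-supplied BED intervals, identical (in chromosome-local
  coordinates) across all barcodes.
* **Insertion (I) mode** — synthetic elements (e.g. viral integrations,
  vector insertions) placed randomly or semi-randomly per barcode, each
  lengthening that barcode's genome by the insert length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GenomeLayout",
    "TargetEntry",
    "TargetSet",
    "InsertionSpec",
    "build_layout",
    "make_roi_targets",
    "draw_insertion_count",
    "place_insertions",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome sizes, concatenated offsets and per-barcode spans.

    ``barcode_lengths`` defaults to the reference length ``G`` for every
    barcode; insertion placement returns inflated per-barcode lengths which
    are attached via :meth:`with_barcode_lengths`.
    """

    chromosomes: tuple[tuple[str, int], ...]
    n_barcodes: int
    barcode_lengths: tuple[int, ...] = field(default=())

    def __post_init__(self):
        if not self.chromosomes:
            raise ValueError("at least one chromosome is required")
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome name")
        for name, length in self.chromosomes:
            if length < 1:
                raise ValueError(f"non-positive length for chromosome {name!r}")
        if self.n_barcodes < 1:
            raise ValueError("n_barcodes must be >= 1")
        if not self.barcode_lengths:
            object.__setattr__(
                self, "barcode_lengths", (self.reference_length,) * self.n_barcodes
            )
        if len(self.barcode_lengths) != self.n_barcodes:
            raise ValueError("barcode_lengths must match n_barcodes")
        if any(l < self.reference_length for l in self.barcode_lengths):
            raise ValueError("barcode genome length below reference length")

    @property
    def reference_length(self) -> int:
        """G: total length of one (pre-insertion) genome copy, in bases."""
        return sum(l for _, l in self.chromosomes)

    @property
    def global_offsets(self) -> dict[str, int]:
        """Start of each chromosome on the concatenated axis of one copy."""
        offsets: dict[str, int] = {}
        pos = 0
        for name, length in self.chromosomes:
            offsets[name] = pos
            pos += length
        return offsets

    @property
    def barcode_spans(self) -> tuple[tuple[int, int], ...]:
        """Disjoint (start, end) half-open spans, one per barcode."""
        starts = np.concatenate([[0], np.cumsum(self.barcode_lengths)[:-1]])
        return tuple(
            (int(s), int(s + l)) for s, l in zip(starts, self.barcode_lengths)
        )

    def with_barcode_lengths(self, lengths: Sequence[int]) -> "GenomeLayout":
        return GenomeLayout(self.chromosomes, self.n_barcodes, tuple(int(l) for l in lengths))

    # -- coordinate mapping (pre-insertion frame) -------------------------

    def global_to_local(self, pos: int) -> tuple[int, str, int]:
        """Map a unified-axis coordinate to (barcode, chromosome, local pos).

        Defined on the pre-insertion frame only (all spans of width G).
        """
        G = self.reference_length
        if any(l != G for l in self.barcode_lengths):
            raise ValueError("global_to_local is defined on the pre-insertion frame")
        if not (0 <= pos < G * self.n_barcodes):
            raise ValueError(f"coordinate {pos} outside the unified axis")
        barcode, within = divmod(pos, G)
        for name, length in self.chromosomes:
            if within < length:
                return int(barcode), name, int(within)
            within -= length
        raise AssertionError("unreachable")

    def local_to_global(self, barcode: int, chrom: str, pos: int) -> int:
        if not (0 <= barcode < self.n_barcodes):
            raise ValueError(f"unknown barcode {barcode}")
        offsets = self.global_offsets
        if chrom not in offsets:
            raise ValueError(f"unknown chromosome {chrom!r}")
        length = dict(self.chromosomes)[chrom]
        if not (0 <= pos < length):
            raise ValueError(f"position {pos} outside chromosome {chrom!r}")
        return self.barcode_spans[barcode][0] + offsets[chrom] + pos

    def chrom_length(self, chrom: str) -> int:
        try:
            return dict(self.chromosomes)[chrom]
        except KeyError:
            raise ValueError(f"unknown chromosome {chrom!r}") from None


@dataclass(frozen=True)
class TargetEntry:
    barcode: int
    label: str
    start: int  # global, 0-based
    end: int    # global, half-open

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty/inverted target {self.label!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TargetSet:
    entries: tuple[TargetEntry, ...]
    mode: str  # "I" | "ROI"

    def __post_init__(self):
        if self.mode not in ("I", "ROI"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def for_barcode(self, barcode: int) -> tuple[TargetEntry, ...]:
        return tuple(e for e in self.entries if e.barcode == barcode)


@dataclass(frozen=True)
class InsertionSpec:
    """How many synthetic insertions to place, how long, and where."""

    n_insertions: int
    insert_length: int
    poisson: bool = False
    placement: str = "random"  # "random" | "semi_random"
    candidate_sites: Optional[tuple[tuple[str, int, int], ...]] = None
    site_weights: Optional[tuple[float, ...]] = None

    def __post_init__(self):
        if self.n_insertions < 0:
            raise ValueError("n_insertions must be >= 0")
        if self.insert_length < 1:
            raise ValueError("insert_length must be >= 1")
        if self.placement not in ("random", "semi_random"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.placement == "semi_random":
            if not self.candidate_sites:
                raise ValueError("semi_random placement requires candidate_sites")
            if self.site_weights is not None:
                if len(self.site_weights) != len(self.candidate_sites):
                    raise ValueError("site_weights must match candidate_sites")
                if any(w < 0 for w in self.site_weights):
                    raise ValueError("site_weights must be non-negative")
                if sum(self.site_weights) <= 0:
                    raise ValueError("site_weights must sum to a positive value")


def build_layout(
    chrom_sizes: Sequence[tuple[str, int]], n_barcodes: int
) -> GenomeLayout:
    """Build the concatenated, barcode-replicated coordinate system."""
    return GenomeLayout(tuple((str(n), int(l)) for n, l in chrom_sizes), int(n_barcodes))


def make_roi_targets(
    layout: GenomeLayout, rois: Sequence[tuple[str, int, int, str]]
) -> TargetSet:
    """Replicate user-defined ROIs onto every barcode.

    ``rois`` are (chrom, start, end, label) in chromosome-local, 0-based
    half-open coordinates.  All barcodes share the same local coordinates.
    """
    entries = []
    for chrom, start, end, label in rois:
        if start >= end:
            raise ValueError(f"ROI {label!r}: start >= end")
        if start < 0 or end > layout.chrom_length(chrom):
            raise ValueError(
                f"ROI {label!r} ({chrom}:{start}-{end}) outside chromosome bounds"
            )
        for b in range(layout.n_barcodes):
            g = layout.local_to_global(b, chrom, start)
            entries.append(TargetEntry(b, str(label), g, g + (end - start)))
    return TargetSet(tuple(entries), "ROI")


def draw_insertion_count(spec: InsertionSpec, rng: np.random.Generator) -> int:
    """Number of insertions for one barcode: fixed, or Poisson around n_I."""
    if spec.poisson:
        return int(rng.poisson(spec.n_insertions))
    return spec.n_insertions


def shift_for_insertion(
    intervals: list[list[int]], p: int, length: int
) -> None:
    """Shift every interval at current position >= p downstream by ``length``.

    An interval straddling p (start < p < end) is extended: the insertion
    lands inside it.  Mutates ``intervals`` in place.
    """
    for iv in intervals:
        if iv[0] >= p:
            iv[0] += length
            iv[1] += length
        elif iv[1] > p:  # p strictly inside
            iv[1] += length


def _choose_sites(
    sites: Sequence[tuple[int, int]],
    weights: Optional[Sequence[float]],
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pick candidate-site indices, length-proportional by default."""
    if weights is None:
        w = np.array([e - s for s, e in sites], dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("candidate sites have zero total weight")
    return rng.choice(len(sites), size=n, p=w / total)

_MAX_REDRAWS = 1000


def _place_one_barcode(
    layout: GenomeLayout, spec: InsertionSpec, rng: np.random.Generator
) -> tuple[list[tuple[int, int]], int]:
    """Place insertions for a single barcode in its local (0..G_b) frame.

    Returns the insertion intervals (current frame, sorted by start) and the
    final genome length.  Each insertion shifts everything downstream of it,
    including previously placed insertions and candidate sites, so the
    original-frame geometry is preserved.
    """
    G = layout.reference_length
    n = draw_insertion_count(spec, rng)
    L = spec.insert_length
    placed: list[list[int]] = []
    cur_len = G

    if spec.placement == "semi_random":
        offsets = layout.global_offsets
        sites = [
            [offsets[c] + s, offsets[c] + e] for c, s, e in spec.candidate_sites or ()
        ]
        for c, s, e in spec.candidate_sites or ():
            if s < 0 or e > layout.chrom_length(c) or s >= e:
                raise ValueError(f"candidate site {c}:{s}-{e} outside chromosome bounds")
        site_idx = _choose_sites(
            [(s, e) for s, e in sites], spec.site_weights, n, rng
        )
    else:
        sites = []
        site_idx = np.zeros(n, dtype=int)

    for k in range(n):
        for _ in range(_MAX_REDRAWS):
            if spec.placement == "semi_random":
                s, e = sites[site_idx[k]]
                p = int(rng.integers(s, e + 1))
            else:
                p = int(rng.integers(0, cur_len + 1))
            if not any(a < p < b for a, b in placed):
                break
        else:
            raise RuntimeError(
                f"could not find a collision-free insertion point after "
                f"{_MAX_REDRAWS} redraws"
            )
        shift_for_insertion(placed, p, L)
        if spec.placement == "semi_random":
            shift_for_insertion(sites, p, L)
        placed.append([p, p + L])
        cur_len += L

    placed.sort()
    return [(a, b) for a, b in placed], cur_len


def place_insertions(
    layout: GenomeLayout, spec: InsertionSpec, rng: np.random.Generator
) -> tuple[TargetSet, tuple[int, ...]]:
    """Place insertions independently per barcode.

    Returns the insertion targets (global coordinates on the inflated unified
    axis) and the per-barcode genome lengths; build the inflated layout with
    ``layout.with_barcode_lengths(lengths)``.
    """
    per_barcode = [
        _place_one_barcode(layout, spec, rng) for _ in range(layout.n_barcodes)
    ]
    lengths = tuple(l for _, l in per_barcode)
    span_starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    entries = []
    for b, (intervals, _) in enumerate(per_barcode):
        for k, (s, e) in enumerate(intervals):
            entries.append(
                TargetEntry(b, f"insertion_{k}", int(span_starts[b] + s), int(span_starts[b] + e))
            )
    return TargetSet(tuple(entries), "I"), lengths
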