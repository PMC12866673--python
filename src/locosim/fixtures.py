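"""Deterministic synthetic fixtures: toy genomes, ROIs, reads, coverage tracks.

These generators stand in for real references and sequencing runs so every
part of the pipeline is exercisable without downloads.  All outputs are
plain text (chrom-sizes TSV, BED, FASTQ, BEDGRAPH) and fully determined by
the seed.  Reads receive random A/C/G/T content purely so the FASTQ is
well-formed — only the record lengths carry information downstream.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .read_lengths import ReadLengthModel

__all__ = [
    "generate_genome",
    "generate_rois",
    "generate_reads",
    "generate_coverage_track",
    "generate_fixture",
]

PathLike = Union[str, Path]
_BASES = np.frombuffer(b"ACGT", dtype="S1")


def generate_genome(
    outdir: PathLike,
    n_chromosomes: int = 2,
    chrom_length: int = 1_000_000,
    seed: int = 0,
) -> Path:
    """Write a chrom-sizes TSV with equal-length chromosomes."""
    if n_chromosomes < 1 or chrom_length < 1:
        raise ValueError("n_chromosomes and chrom_length must be >= 1")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "genome.chrom.sizes"
    with open(path, "w") as fh:
        for i in range(n_chromosomes):
            fh.write(f"chr{i + 1}\t{chrom_length}\n")
    return path


def generate_rois(
    outdir: PathLike,
    chrom_sizes: Sequence[tuple[str, int]],
    n_rois: int = 5,
    min_length: int = 5_000,
    max_length: int = 20_000,
    seed: int = 0,
) -> Path:
    """Write a BED4 of labelled, non-overlapping random target regions."""
    if not (1 <= min_length <= max_length):
        raise ValueError("require 1 <= min_length <= max_length")
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "rois.bed"
    placed: dict[str, list[tuple[int, int]]] = {}
    rows = []
    for k in range(n_rois):
        for _ in range(1000):
            chrom, length = chrom_sizes[rng.integers(0, len(chrom_sizes))]
            size = int(rng.integers(min_length, max_length + 1))
            if size > length:
                continue
            start = int(rng.integers(0, length - size + 1))
            end = start + size
            if all(e <= start or end <= s for s, e in placed.get(chrom, [])):
                placed.setdefault(chrom, []).append((start, end))
                rows.append((chrom, start, end, f"roi_{k}"))
                break
        else:
            raise RuntimeError("could not place non-overlapping ROIs; genome too small")
    rows.sort()
    with open(path, "w") as fh:
        for chrom, start, end, name in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
    return path


def generate_reads(
    outdir: PathLike,
    n_reads: int = 1000,
    mean_length: float = 10_000.0,
    sigma: float = 0.5,
    seed: int = 0,
) -> Path:
    """Write a FASTQ whose read lengths follow the requested log-normal."""
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    model = ReadLengthModel(kind="parametric", mean_length=mean_length, sigma=sigma)
    lengths = model.sample(rng, n_reads)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "reads.fastq"
    with open(path, "w") as fh:
        for i, L in enumerate(lengths):
            seq = _BASES[rng.integers(0, 4, size=int(L))].tobytes().decode()
            fh.write(f"@read_{i}\n{seq}\n+\n{'I' * int(L)}\n")
    return path


def generate_coverage_track(
    outdir: PathLike,
    chrom_sizes: Sequence[tuple[str, int]],
    segment_length: int = 100_000,
    mean_coverage: float = 25.0,
    holes: Optional[Sequence[tuple[str, int, int]]] = None,
    seed: int = 0,
) -> Path:
    """Write a piecewise-constant BEDGRAPH ('bga'-style, zero-inclusive).

    Segment values are gamma-distributed around ``mean_coverage``;
    ``holes`` intervals are forced to zero coverage, emulating mappability
    dropouts.
    """
    if segment_length < 1 or mean_coverage <= 0:
        raise ValueError("segment_length must be >= 1 and mean_coverage > 0")
    rng = np.random.default_rng(seed)
    holes = list(holes or [])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "coverage.bedgraph"
    with open(path, "w") as fh:
        for chrom, length in chrom_sizes:
            # breakpoints: segment grid plus hole boundaries
            cuts = set(range(0, length, segment_length)) | {length}
            for h_chrom, h_start, h_end in holes:
                if h_chrom == chrom:
                    if h_start < 0 or h_end > length or h_start >= h_end:
                        raise ValueError(f"invalid hole {h_chrom}:{h_start}-{h_end}")
                    cuts.update((h_start, h_end))
            edges = sorted(cuts)
            seg_values = {}
            for start, end in zip(edges[:-1], edges[1:]):
                seg = start // segment_length
                if seg not in seg_values:
                    # shape 4 gamma: right-skewed but rarely near zero
                    seg_values[seg] = rng.gamma(4.0, mean_coverage / 4.0)
                value = seg_values[seg]
                for h_chrom, h_start, h_end in holes:
                    if h_chrom == chrom and h_start <= start and end <= h_end:
                        value = 0.0
                fh.write(f"{chrom}\t{start}\t{end}\t{value:.4f}\n")
    return path


def generate_fixture(
    kind: str, params: Optional[dict] = None, seed: int = 0, outdir: PathLike = "."
) -> Path:
    """Dispatch by fixture kind: genome | rois | reads | coverage_track.

    For 'rois' and 'coverage_track', ``params['genome']`` may be a
    chrom-sizes file path instead of an in-memory ``chrom_sizes`` list.
    """
    params = dict(params or {})
    if "genome" in params:
        from .bedio import read_chrom_sizes

        params["chrom_sizes"] = read_chrom_sizes(params.pop("genome"))
    if kind == "genome":
        return generate_genome(outdir, seed=seed, **params)
    if kind == "rois":
        return generate_rois(outdir, seed=seed, **params)
    if kind == "reads":
        return generate_reads(outdir, seed=seed, **params)
    if kind == "coverage_track":
        return generate_coverage_track(outdir, seed=seed, **params)
    raise ValueError(f"unknown fixture kind {kind!r}")
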