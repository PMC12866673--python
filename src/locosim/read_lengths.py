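"""Read-length distributions: mean-parameterised log-normal or empirical.

Long-read length distributions are long-tailed and well described by a
log-normal.  The parametric model is parameterised by the *arithmetic mean*
read length: for ``L ~ LogNormal(mu, sigma^2)`` we set
``mu = ln(mean) - sigma^2 / 2`` so that ``E[L] = mean`` exactly — the
coverage stopping rule accumulates raw base yield, so preserving the mean
(rather than the median) keeps yield accounting consistent.

Alternatively, an empirical distribution is taken from the record lengths of
a FASTA/FASTQ file (plain or gzipped); sampling is uniform with replacement.
Sequence content is discarded immediately — only lengths matter here.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
from Bio import SeqIO

__all__ = [
    "ReadLengthModel",
    "lognormal_params",
    "empirical_model_from_reads",
    "sample_read_length",
]

DEFAULT_SIGMA = 1.0


def lognormal_params(mean_length: float, sigma: float) -> tuple[float, float]:
    """(mu, sigma) of the underlying normal for a given arithmetic mean."""
    if mean_length <= 0:
        raise ValueError("mean_length must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    mu = float(np.log(mean_length) - sigma**2 / 2.0)
    return mu, float(sigma)


@dataclass(frozen=True)
class ReadLengthModel:
    kind: str  # "parametric" | "empirical"
    mean_length: Optional[float] = None
    sigma: Optional[float] = None
    lengths: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.kind == "parametric":
            if self.mean_length is None or self.mean_length <= 0:
                raise ValueError("parametric model requires a positive mean_length")
            if self.sigma is None:
                object.__setattr__(self, "sigma", DEFAULT_SIGMA)
            if self.sigma < 0:
                raise ValueError("sigma must be non-negative")
        elif self.kind == "empirical":
            if self.lengths is None or len(self.lengths) == 0:
                raise ValueError("empirical model requires at least one read length")
            if np.any(np.asarray(self.lengths) < 1):
                raise ValueError("read lengths must be >= 1")
        else:
            raise ValueError(f"unknown model kind {self.kind!r}")

    @property
    def mu(self) -> float:
        """Underlying-normal mean (parametric models only)."""
        return lognormal_params(self.mean_length, self.sigma)[0]

    @property
    def expected_length(self) -> float:
        if self.kind == "parametric":
            return float(self.mean_length)
        return float(np.mean(self.lengths))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw ``size`` integer read lengths (all >= 1)."""
        if self.kind == "parametric":
            if self.sigma == 0:
                vals = np.full(size, self.mean_length)
            else:
                vals = rng.lognormal(self.mu, self.sigma, size=size)
            return np.maximum(np.rint(vals), 1).astype(np.int64)
        idx = rng.integers(0, len(self.lengths), size=size)
        return np.asarray(self.lengths, dtype=np.int64)[idx]


def _open_maybe_gzip(path: Union[str, Path]):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


_FASTA_EXT = {".fa", ".fasta", ".fna"}
_FASTQ_EXT = {".fq", ".fastq"}


def _guess_format(path: Path) -> str:
    suffixes = [s.lower() for s in path.suffixes]
    if suffixes and suffixes[-1] == ".gz":
        suffixes = suffixes[:-1]
    if suffixes and suffixes[-1] in _FASTQ_EXT:
        return "fastq"
    if suffixes and suffixes[-1] in _FASTA_EXT:
        return "fasta"
    # fall back to sniffing the first character
    with _open_maybe_gzip(path) as fh:
        first = fh.read(1)
    if first == "@":
        return "fastq"
    if first == ">":
        return "fasta"
    raise ValueError(f"cannot determine FASTA/FASTQ format of {path}")


def empirical_model_from_reads(path: Union[str, Path]) -> ReadLengthModel:
    """Read-length multiset from a FASTA/FASTQ file (plain or gzipped)."""
    path = Path(path)
    fmt = _guess_format(path)
    lengths = []
    with _open_maybe_gzip(path) as fh:
        for record in SeqIO.parse(fh, fmt):
            n = len(record.seq)
            if n < 1:
                raise ValueError(f"record {record.id!r} has an empty sequence")
            lengths.append(n)
    if not lengths:
        raise ValueError(f"no records found in {path}")
    return ReadLengthModel(kind="empirical", lengths=np.asarray(lengths, dtype=np.int64))


def sample_read_length(model: ReadLengthModel, rng: np.random.Generator) -> int:
    """Draw a single read length from the model."""
    return int(model.sample(rng, 1)[0])
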