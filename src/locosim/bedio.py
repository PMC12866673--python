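"""Readers/writers for chrom-sizes, BED, BEDGRAPH and the run's TSV tables.

All genomic intervals are 0-based, half-open (BED-native) and pass through
unchanged.  Output tables are TSV with a single commented provenance line.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import pandas as pd

from . import __version__

__all__ = [
    "read_chrom_sizes",
    "read_bed",
    "read_bedgraph",
    "write_tsv",
    "read_tsv",
]

PathLike = Union[str, Path]


def read_chrom_sizes(path: PathLike) -> list[tuple[str, int]]:
    """Two-column TSV (name, length)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected 2 tab-separated columns")
            name, length = parts[0], parts[1]
            try:
                length = int(length)
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-integer length {length!r}") from None
            if length < 1:
                raise ValueError(f"{path}:{ln}: non-positive length for {name!r}")
            out.append((name, length))
    if not out:
        raise ValueError(f"{path}: no chromosomes found")
    names = [n for n, _ in out]
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate chromosome name")
    return out


def read_bed(path: PathLike, min_columns: int = 3) -> pd.DataFrame:
    """BED3+ with optional label (col 4) and weight in [0,1] (col 5).

    Returns columns (chrom, start, end, name, weight); missing labels get
    'region_<i>' and missing weights 1.0.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < min_columns:
                raise ValueError(
                    f"{path}:{ln}: expected >= {min_columns} tab-separated columns"
                )
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-numeric coordinates") from None
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{ln}: invalid interval {start}-{end}")
            name = parts[3] if len(parts) > 3 and parts[3] else f"region_{len(rows)}"
            weight = 1.0
            if len(parts) > 4 and parts[4] != "":
                try:
                    weight = float(parts[4])
                except ValueError:
                    raise ValueError(f"{path}:{ln}: non-numeric weight") from None
                if not (0.0 <= weight <= 1.0):
                    raise ValueError(f"{path}:{ln}: weight {weight} outside [0, 1]")
            rows.append(
                {"chrom": chrom, "start": start, "end": end, "name": name, "weight": weight}
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "weight"])


def read_bedgraph(path: PathLike) -> pd.DataFrame:
    """BEDGRAPH (chrom, start, end, value) -> DataFrame."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 tab-separated columns")
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError:
                raise ValueError(f"{path}:{ln}: malformed BEDGRAPH record") from None
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{ln}: invalid interval {start}-{end}")
            rows.append({"chrom": parts[0], "start": start, "end": end, "value": value})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_tsv(df: pd.DataFrame, path: PathLike, comment: str = "") -> None:
    """TSV with one commented provenance line before the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# locosim {__version__}{' ' + comment if comment else ''}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
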