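"""Single-file YAML configuration for simulation runs.

Keys are validated strictly: unknown keys and invalid values raise errors
that name the offending key.  File paths inside a config are resolved
relative to the config file's directory.

Schema (defaults in brackets)::

    genome: chrom.sizes            # required; 2-column TSV (name, length)
    mode: ROI                      # ROI | I            [ROI]
    coverages: [10]                # required; positive reals
    read_length:
      mean: 10000                  # parametric model, with
      sigma: 1.0                   #   sigma of the underlying normal [1.0]
      reads: null                  # or: FASTA/FASTQ for an empirical model
    barcodes:
      n: 1                         # [1]
      weights: null                # optional; length n, non-negative
    rois: targets.bed              # ROI mode: BED3+ with labels
    insertions:                    # I mode
      n: 1
      poisson: false               # [false]
      length: 1000
      placement: random            # random | semi_random [random]
      candidate_sites: null        # BED3+; optional col 5 = site weight
    mask:
      path: null                   # BED3 (weight 1.0) or BED5 with weights
      consuming: true              # [true]
    iterations: 100                # [100]
    seed: 0                        # [0]
    min_overlap: 1                 # [1]
    scaling: false                 # [false]
    workers: 1                     # [1]
    ci_level: 0.95                 # [0.95]
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import yaml

from .bedio import read_bed, read_chrom_sizes
from .genome_model import InsertionSpec
from .read_lengths import DEFAULT_SIGMA, ReadLengthModel, empirical_model_from_reads
from .sim_engine import MaskSet, SimulationConfig

__all__ = ["load_config", "write_config", "config_from_dict"]

PathLike = Union[str, Path]

_TOP_KEYS = {
    "genome", "mode", "coverages", "read_length", "barcodes", "rois",
    "insertions", "mask", "iterations", "seed", "min_overlap", "scaling",
    "workers", "ci_level",
}
_READ_KEYS = {"mean", "sigma", "reads"}
_BARCODE_KEYS = {"n", "weights"}
_INSERT_KEYS = {"n", "poisson", "length", "placement", "candidate_sites", "site_weights"}
_MASK_KEYS = {"path", "consuming"}


def _check_keys(d: dict, allowed: set, section: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {section}: {sorted(unknown)}")


def _resolve(base: Path, p: Optional[str]) -> Optional[Path]:
    if p is None:
        return None
    q = Path(p)
    return q if q.is_absolute() else base / q


def config_from_dict(raw: dict[str, Any], base_dir: PathLike = ".") -> SimulationConfig:
    """Build a validated SimulationConfig from a parsed config mapping."""
    base = Path(base_dir)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")

    if "genome" not in raw:
        raise ValueError("missing required key 'genome'")
    chrom_sizes = tuple(read_chrom_sizes(_resolve(base, raw["genome"])))

    if "coverages" not in raw:
        raise ValueError("missing required key 'coverages'")
    cov = raw["coverages"]
    if not isinstance(cov, (list, tuple)):
        cov = [cov]
    try:
        coverages = tuple(float(c) for c in cov)
    except (TypeError, ValueError):
        raise ValueError("key 'coverages': values must be numeric") from None
    if any(c <= 0 for c in coverages):
        raise ValueError("key 'coverages': every coverage must be > 0")

    mode = str(raw.get("mode", "ROI"))
    if mode not in ("ROI", "I"):
        raise ValueError(f"key 'mode': must be ROI or I, got {mode!r}")

    rl = raw.get("read_length") or {}
    _check_keys(rl, _READ_KEYS, "read_length")
    if rl.get("reads") is not None:
        read_model = empirical_model_from_reads(_resolve(base, rl["reads"]))
    else:
        if rl.get("mean") is None:
            raise ValueError("key 'read_length.mean': required without 'reads'")
        mean = float(rl["mean"])
        if mean <= 0:
            raise ValueError("key 'read_length.mean': must be > 0")
        sigma = float(rl.get("sigma", DEFAULT_SIGMA))
        if sigma < 0:
            raise ValueError("key 'read_length.sigma': must be >= 0")
        read_model = ReadLengthModel(kind="parametric", mean_length=mean, sigma=sigma)

    bc = raw.get("barcodes") or {}
    _check_keys(bc, _BARCODE_KEYS, "barcodes")
    n_barcodes = int(bc.get("n", 1))
    if n_barcodes < 1:
        raise ValueError("key 'barcodes.n': must be >= 1")
    weights = bc.get("weights")
    if weights is not None:
        weights = tuple(float(w) for w in weights)

    rois: tuple = ()
    insertions = None
    if mode == "ROI":
        if raw.get("rois") is None:
            raise ValueError("key 'rois': required in ROI mode")
        bed = read_bed(_resolve(base, raw["rois"]))
        rois = tuple(
            (r.chrom, int(r.start), int(r.end), str(r.name)) for r in bed.itertuples()
        )
    else:
        ins = raw.get("insertions")
        if ins is None:
            raise ValueError("key 'insertions': required in I mode")
        _check_keys(ins, _INSERT_KEYS, "insertions")
        if "n" not in ins or "length" not in ins:
            raise ValueError("keys 'insertions.n' and 'insertions.length' are required")
        sites = None
        site_weights = ins.get("site_weights")
        if ins.get("candidate_sites") is not None:
            bed = read_bed(_resolve(base, ins["candidate_sites"]))
            sites = tuple((r.chrom, int(r.start), int(r.end)) for r in bed.itertuples())
            if site_weights is None and (bed["weight"] != 1.0).any():
                site_weights = tuple(float(w) for w in bed["weight"])
        if site_weights is not None:
            site_weights = tuple(float(w) for w in site_weights)
        insertions = InsertionSpec(
            n_insertions=int(ins["n"]),
            insert_length=int(ins["length"]),
            poisson=bool(ins.get("poisson", False)),
            placement=str(ins.get("placement", "random")),
            candidate_sites=sites,
            site_weights=site_weights,
        )

    mask_cfg = raw.get("mask") or {}
    _check_keys(mask_cfg, _MASK_KEYS, "mask")
    consuming = bool(mask_cfg.get("consuming", True))
    masks = None
    if mask_cfg.get("path") is not None:
        bed = read_bed(_resolve(base, mask_cfg["path"]))
        masks = MaskSet(
            tuple(
                (r.chrom, int(r.start), int(r.end), float(r.weight))
                for r in bed.itertuples()
            ),
            consuming=consuming,
        )

    iterations = int(raw.get("iterations", 100))
    if iterations < 1:
        raise ValueError("key 'iterations': must be >= 1")
    workers = int(raw.get("workers", 1))
    if workers < 1:
        raise ValueError("key 'workers': must be >= 1")
    min_overlap = int(raw.get("min_overlap", 1))
    if min_overlap < 1:
        raise ValueError("key 'min_overlap': must be >= 1")
    ci_level = float(raw.get("ci_level", 0.95))
    if not (0 < ci_level < 1):
        raise ValueError("key 'ci_level': must be in (0, 1)")

    return SimulationConfig(
        chrom_sizes=chrom_sizes,
        coverages=coverages,
        read_model=read_model,
        mode=mode,
        n_barcodes=n_barcodes,
        barcode_weights=weights,
        rois=rois,
        insertions=insertions,
        masks=masks,
        consuming=consuming,
        iterations=iterations,
        seed=int(raw.get("seed", 0)),
        min_overlap=min_overlap,
        scaling=bool(raw.get("scaling", False)),
        workers=workers,
        ci_level=ci_level,
        raw=_normalise_raw(raw),
    )


def _normalise_raw(raw: dict) -> dict:
    # plain-python echo of the config for manifests and round-tripping
    return yaml.safe_load(yaml.safe_dump(raw))


def load_config(path: PathLike) -> SimulationConfig:
    """Parse and validate a YAML config file."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raise ValueError(f"{path}: empty config")
    return config_from_dict(raw, base_dir=path.parent)


def write_config(config: SimulationConfig, path: PathLike) -> None:
    """Write the config echo back to YAML (paths as originally given).

    ``load_config(write_config(c)) `` reproduces ``c`` provided the
    referenced files are still reachable from the new location.
    """
    if config.raw is None:
        raise ValueError("config has no raw echo to serialise")
    with open(path, "w") as fh:
        yaml.safe_dump(config.raw, fh, sort_keys=False)
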