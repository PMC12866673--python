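"""Agreement statistics between simulated and observed local coverage.

* Lin's concordance correlation coefficient (CCC) — agreement along the
  identity line, computed with population (1/n) moments:
  ``2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)``.
* Bland–Altman analysis — bias and ±1.96 SD limits of agreement on pairwise
  differences, optionally after a cube-root transform (OTB counts are
  heavily right-skewed; the cube root symmetrises them while handling
  zeros).
* Two-sided empirical p-values of an observed value against a Monte Carlo
  sample, using the add-one estimator (r + 1) / (M + 1) so p > 0 and the
  test is valid, followed by Benjamini–Hochberg FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ccc",
    "bland_altman",
    "BlandAltmanResult",
    "empirical_pvalue",
    "bh_adjust",
    "agreement_report",
]


def ccc(x: Sequence[float], y: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least two observations")
    mx, my = x.mean(), y.mean()
    sx2 = np.mean((x - mx) ** 2)
    sy2 = np.mean((y - my) ** 2)
    sxy = np.mean((x - mx) * (y - my))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise ValueError("CCC undefined: both vectors constant with equal means")
    return float(2.0 * sxy / denom)


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd: float
    limit_low: float
    limit_high: float
    outliers: tuple[int, ...]
    differences: np.ndarray
    means: np.ndarray


def bland_altman(
    x: Sequence[float], y: Sequence[float], transform: str = "cbrt"
) -> BlandAltmanResult:
    """Bland–Altman agreement on (optionally cube-root transformed) pairs.

    Differences d = t(x) - t(y); limits = bias ± 1.96 SD(d); indices with
    |d - bias| > 1.96 SD are flagged as outliers.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    if transform == "cbrt":
        tx, ty = np.cbrt(x), np.cbrt(y)
    elif transform == "identity":
        tx, ty = x, y
    else:
        raise ValueError(f"unknown transform {transform!r}")
    d = tx - ty
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half = 1.96 * sd
    outliers = tuple(int(i) for i in np.nonzero(np.abs(d - bias) > half)[0])
    return BlandAltmanResult(
        bias=bias,
        sd=sd,
        limit_low=bias - half,
        limit_high=bias + half,
        outliers=outliers,
        differences=d,
        means=(tx + ty) / 2.0,
    )


def empirical_pvalue(observed: float, simulated: Sequence[float]) -> float:
    """Two-sided empirical p-value with the add-one (r+1)/(M+1) estimator."""
    sims = np.asarray(simulated, dtype=float)
    if sims.size == 0:
        raise ValueError("need at least one simulated value")
    m = sims.size
    p_low = (np.count_nonzero(sims <= observed) + 1) / (m + 1)
    p_high = (np.count_nonzero(sims >= observed) + 1) / (m + 1)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def agreement_report(
    observed: pd.DataFrame,
    simulated: pd.DataFrame,
    transform: str = "cbrt",
) -> tuple[pd.DataFrame, float, BlandAltmanResult]:
    """Per-target agreement between observed values and a Monte Carlo sample.

    ``observed``: columns (target, observed).  ``simulated``: columns
    (target, value) with one row per iteration.  Returns a per-target table
    with the simulation mean, raw and BH-adjusted empirical p-values and a
    Bland–Altman outlier flag, plus the overall CCC (observed vs simulation
    means) and the Bland–Altman result.
    """
    obs = observed.set_index("target")["observed"]
    sim_groups = {t: g["value"].to_numpy() for t, g in simulated.groupby("target")}
    missing = [t for t in obs.index if t not in sim_groups]
    if missing:
        raise ValueError(f"no simulated values for targets: {missing}")
    sim_means = np.array([sim_groups[t].mean() for t in obs.index])
    p_raw = np.array([empirical_pvalue(obs[t], sim_groups[t]) for t in obs.index])
    p_adj = bh_adjust(p_raw)
    overall_ccc = ccc(obs.to_numpy(), sim_means)
    ba = bland_altman(obs.to_numpy(), sim_means, transform=transform)
    table = pd.DataFrame(
        {
            "target": obs.index,
            "observed": obs.to_numpy(),
            "sim_mean": sim_means,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "ba_outlier": [i in ba.outliers for i in range(len(obs))],
        }
    )
    return table, overall_ccc, ba
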