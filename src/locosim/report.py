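"""Render a brief analysis report from a run's per-iteration and summary TSVs.

The report is a deterministic markdown document (byte-stable for identical
inputs; no timestamps) plus one PNG boxplot panel per coverage level
showing the distribution of per-iteration OTB across targets.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .bedio import read_tsv  # noqa: E402

__all__ = ["render_report"]

PathLike = Union[str, Path]


def render_report(
    iterations_tsv: PathLike,
    summary_tsv: PathLike,
    outdir: PathLike,
    config_echo: Optional[dict] = None,
) -> Path:
    """Write report.md (+ figures) into ``outdir``; returns the report path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    iters = read_tsv(iterations_tsv)
    summary = read_tsv(summary_tsv)
    report = outdir / "report.md"

    lines = ["# Local coverage simulation report", ""]
    if config_echo:
        lines += ["## Configuration", "", "```yaml"]
        lines += json.dumps(config_echo, indent=2, sort_keys=True, default=str).splitlines()
        lines += ["```", ""]

    if iters.empty:
        lines += ["**no targets** — the simulation produced no target records.", ""]
        report.write_text("\n".join(lines))
        return report

    n_panels = 0
    figure_lines = []
    for cov, grp in iters.groupby("coverage", sort=True):
        per_iter = (
            grp.groupby(["target_label", "iteration"])["otb"].sum().reset_index()
        )
        labels = sorted(per_iter["target_label"].unique())
        data = [
            per_iter.loc[per_iter["target_label"] == lab, "otb"].to_numpy()
            for lab in labels
        ]
        fig, ax = plt.subplots(figsize=(max(4, 1.2 * len(labels)), 4))
        ax.boxplot(data, tick_labels=labels)
        ax.set_ylabel("on-target bases per iteration")
        ax.set_title(f"OTB distribution at {cov}x")
        ax.tick_params(axis="x", rotation=45)
        fig.tight_layout()
        fname = f"otb_coverage_{cov}.png"
        fig.savefig(outdir / fname, dpi=100)
        plt.close(fig)
        n_panels += 1
        figure_lines.append(f"![OTB at {cov}x]({fname})")

    lines += [f"Panels: {n_panels}", ""]
    lines += ["## Summary statistics", "", "```"]
    lines.append(summary.round(2).to_string(index=False))
    lines.append("```")
    lines += ["", "## OTB distributions", ""] + figure_lines

    if summary["coverage"].nunique() > 1:
        fig, ax = plt.subplots(figsize=(5, 4))
        for lab, grp in summary.groupby("target_label"):
            g = grp.sort_values("coverage")
            ax.errorbar(
                g["coverage"], g["mean_otb"], yerr=1.96 * g["se"], marker="o", label=lab
            )
        ax.set_xlabel("whole-genome coverage (x)")
        ax.set_ylabel("mean OTB")
        ax.legend(fontsize="small")
        fig.tight_layout()
        fig.savefig(outdir / "otb_vs_coverage.png", dpi=100)
        plt.close(fig)
        lines += ["", "## Coverage trend", "", "![trend](otb_vs_coverage.png)"]

    lines.append("")
    report.write_text("\n".join(lines))
    return report
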