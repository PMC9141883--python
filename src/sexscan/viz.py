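"""Genome-scan plots and the Markdown run report.

Three-panel scan plots: per-site F_ST on top, the male-pool alternate-allele
frequency at XY-patterned sites in the middle, and the female-pool
alternate-allele frequency at ZW-patterned sites at the bottom.  Whole-genome
plots concatenate chromosomes in table order with alternating shading;
single-chromosome plots use Mb coordinates.  Rendering is pure — the input
track is never mutated.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .seqio import ChromTable

__all__ = [
    "PlotStyle",
    "genome_scan_plot",
    "single_chrom_plot",
    "top_window_barplot",
    "write_report",
]


class PlotStyle:
    """Figure styling defaults (sizes, colors); the science fixes none."""

    fst_color = "#444444"
    xy_color = "#1f77b4"
    zw_color = "#d62728"
    shade_color = "#dddddd"
    point_size = 2.0
    figsize = (12.0, 6.0)
    dpi = 150


def _panels(
    track: pd.DataFrame, x: pd.Series, axes, style: PlotStyle
) -> None:
    fst = track.dropna(subset=["fst"])
    axes[0].scatter(x[fst.index], fst["fst"], s=style.point_size, c=style.fst_color)
    axes[0].set_ylabel("$F_{ST}$")
    axes[0].set_ylim(-0.02, 1.02)
    xy = track[track["pattern"] == "XY"]
    axes[1].scatter(x[xy.index], xy["male_freq"], s=style.point_size, c=style.xy_color)
    axes[1].set_ylabel("Y-allele freq\n(male pool)")
    axes[1].set_ylim(-0.02, 1.02)
    zw = track[track["pattern"] == "ZW"]
    axes[2].scatter(x[zw.index], zw["female_freq"], s=style.point_size, c=style.zw_color)
    axes[2].set_ylabel("W-allele freq\n(female pool)")
    axes[2].set_ylim(-0.02, 1.02)


def genome_scan_plot(
    track: pd.DataFrame,
    chroms: ChromTable,
    out: str | Path,
    style: PlotStyle = PlotStyle(),
) -> None:
    """Three stacked panels over the concatenated genome.

    ``track`` is the per-site table (chrom, pos, fst, pattern, female_freq,
    male_freq); chromosomes are laid out in ``chroms`` order with
    alternating background shading.
    """
    if track.empty:
        raise ValueError("empty track")
    offsets = {}
    cum = 0
    for name, length in chroms:
        offsets[name] = cum
        cum += length
    track = track[track["chrom"].isin(offsets)]
    x = track["chrom"].map(offsets) + track["pos"]
    fig, axes = plt.subplots(
        3, 1, sharex=True, figsize=style.figsize, constrained_layout=True
    )
    for i, (name, length) in enumerate(chroms):
        if i % 2:
            for ax in axes:
                ax.axvspan(offsets[name], offsets[name] + length, color=style.shade_color, zorder=0)
    _panels(track, x, axes, style)
    mids = [offsets[name] + length / 2 for name, length in chroms]
    axes[2].set_xticks(mids)
    axes[2].set_xticklabels(chroms.names, rotation=90, fontsize=7)
    axes[2].set_xlim(0, cum)
    axes[2].set_xlabel("chromosome")
    fig.savefig(out, dpi=style.dpi)
    plt.close(fig)


def single_chrom_plot(
    track: pd.DataFrame,
    chroms: ChromTable,
    chrom: str,
    out: str | Path,
    style: PlotStyle = PlotStyle(),
) -> None:
    """The same three panels restricted to one chromosome, x-axis in Mb."""
    if chrom not in chroms:
        raise KeyError(f"unknown chromosome: {chrom!r}")
    sub = track[track["chrom"] == chrom]
    fig, axes = plt.subplots(
        3, 1, sharex=True, figsize=style.figsize, constrained_layout=True
    )
    x = sub["pos"] / 1e6
    _panels(sub, x, axes, style)
    axes[2].set_xlim(0, chroms.length(chrom) / 1e6)
    axes[2].set_xlabel(f"{chrom} position (Mb)")
    fig.savefig(out, dpi=style.dpi)
    plt.close(fig)


def top_window_barplot(
    summaries: Mapping[str, pd.DataFrame],
    out: str | Path,
    style: PlotStyle = PlotStyle(),
) -> None:
    """Per-chromosome totals of top-window SNPs, XY and ZW side by side.

    ``summaries`` maps pattern name ("XY", "ZW") to a per-chromosome summary
    table; bar heights are the ``total_patterned_snps`` column, unscaled.
    """
    if not summaries:
        raise ValueError("at least one summary required")
    first = next(iter(summaries.values()))
    chroms = list(first["chrom"])
    idx = np.arange(len(chroms))
    width = 0.8 / len(summaries)
    colors = {"XY": style.xy_color, "ZW": style.zw_color}
    fig, ax = plt.subplots(figsize=(10, 4), constrained_layout=True)
    for k, (pattern, df) in enumerate(summaries.items()):
        totals = df.set_index("chrom").reindex(chroms)["total_patterned_snps"].fillna(0)
        ax.bar(
            idx + k * width,
            totals.to_numpy(),
            width,
            label=f"{pattern}-patterned",
            color=colors.get(pattern),
        )
    ax.set_xticks(idx + width * (len(summaries) - 1) / 2)
    ax.set_xticklabels(chroms, rotation=90, fontsize=7)
    ax.set_ylabel("SNPs in top windows")
    ax.legend()
    fig.savefig(out, dpi=style.dpi)
    plt.close(fig)


def write_report(
    out_path: str | Path,
    config_echo: Mapping[str, object],
    summaries: Mapping[str, pd.DataFrame],
    regions: Sequence = (),
    figures: Sequence[str] = (),
) -> None:
    """Write a Markdown run report: inputs, thresholds, regions, summaries."""
    lines = ["# sexscan run report", "", "## Configuration", ""]
    for key, value in config_echo.items():
        lines.append(f"- **{key}**: {value}")
    if regions:
        lines += ["", "## Candidate regions", ""]
        lines.append("| chrom | start | end | pattern | windows | SNPs |")
        lines.append("|---|---|---|---|---|---|")
        for r in regions:
            lines.append(
                f"| {r.chrom} | {r.start} | {r.end} | {r.pattern} | {r.n_windows} | {r.total_snps} |"
            )
    for pattern, df in summaries.items():
        lines += ["", f"## Top-window summary ({pattern}-patterned)", ""]
        cols = list(df.columns)
        lines.append("| " + " | ".join(cols) + " |")
        lines.append("|" + "---|" * len(cols))
        for _, row in df.iterrows():
            cells = [
                f"{v:.3g}" if isinstance(v, float) else str(v) for v in row.tolist()
            ]
            lines.append("| " + " | ".join(cells) + " |")
    if figures:
        lines += ["", "## Figures", ""]
        lines += [f"- {f}" for f in figures]
    Path(out_path).write_text("\n".join(lines) + "\n")
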