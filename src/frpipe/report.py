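"""Fragment-recruitment plots and composition figures.

Every figure writes a TSV "twin" holding exactly the plotted numbers, so
tests can check plot content without parsing images. Recruitment plots
scatter one dot per recruited read (concatenated genome position vs.
percent identity, y-axis floored at the 60% consideration threshold) with
the ten section boundaries as gridlines and an annotation box reporting
read count, ANI and RSD. Composition figures stack the per-method genus
percentages with the reserved Minorities / Higher than genus / Unassigned /
No hits categories and overlay per-method read counts as dot markers.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .io import contig_offsets
from .recruitment import N_SECTIONS, RecruitmentProfile


def frp_points(
    best: pd.DataFrame, genome_id: str, contig_table: pd.DataFrame
) -> pd.DataFrame:
    """(position, identity) pairs for one genome's recruited reads."""
    offsets = contig_offsets(contig_table)
    off_map = dict(zip(offsets["contig_id"], offsets["offset"]))
    sub = best[best["genome_id"] == genome_id]
    if sub.empty:
        return pd.DataFrame(columns=["read_id", "position", "identity"])
    off = sub["subject_contig"].map(off_map).to_numpy(dtype=float)
    lo = np.minimum(sub["sstart"], sub["send"]).to_numpy(dtype=float)
    hi = np.maximum(sub["sstart"], sub["send"]).to_numpy(dtype=float)
    return pd.DataFrame({
        "read_id": sub["qseqid"].to_numpy(),
        "position": off + (lo - 1 + hi) / 2.0,
        "identity": sub["pident"].to_numpy(dtype=float),
    })


def render_frp(
    profile: RecruitmentProfile,
    points: pd.DataFrame,
    total_length: int,
    out_png: str | Path,
    out_tsv: str | Path | None = None,
    dpi: int = 120,
) -> dict[str, Path]:
    """Render one fragment recruitment plot plus its data twin."""
    out_png = Path(out_png)
    out_tsv = Path(out_tsv) if out_tsv else out_png.with_suffix(".tsv")
    if len(points) != profile.n_reads:
        raise ValueError(
            f"{profile.genome_id}: {len(points)} points vs profile n_reads "
            f"{profile.n_reads}"
        )
    points.to_csv(out_tsv, sep="\t", index=False)

    fig, ax = plt.subplots(figsize=(8, 3.2))
    width = total_length // N_SECTIONS
    for i in range(1, N_SECTIONS):
        ax.axvline(i * width, color="0.85", lw=0.6, zorder=0)
    if profile.n_reads == 0:
        ax.text(0.5, 0.5, "no recruited reads", transform=ax.transAxes,
                ha="center", va="center", fontsize=12, color="0.4")
    else:
        ax.plot(points["position"], points["identity"], ".", ms=2.5,
                alpha=0.5, color="tab:blue")
    star = " *" if profile.two_clouds else ""
    ann = (
        f"n = {profile.n_reads}\n"
        f"ANI = {profile.ani:.2f}\nRSD = {profile.rsd:.3f}{star}"
        if profile.n_reads else "n = 0"
    )
    ax.text(0.99, 0.03, ann, transform=ax.transAxes, ha="right", va="bottom",
            fontsize=8, bbox=dict(fc="white", alpha=0.8, ec="0.6"))
    ax.set_xlim(0, total_length)
    ax.set_ylim(60, 100.5)
    ax.set_xlabel("genome position (bp, contigs concatenated)")
    ax.set_ylabel("% identity")
    ax.set_title(profile.genome_id, fontsize=10)
    fig.tight_layout()
    fig.savefig(out_png, dpi=dpi)
    plt.close(fig)
    return {"png": out_png, "tsv": out_tsv}


def render_composition(
    composition: pd.DataFrame,
    read_counts: dict[str, int] | None,
    out_png: str | Path,
    out_tsv: str | Path | None = None,
    dpi: int = 120,
    title: str = "",
) -> dict[str, Path]:
    """Stacked-bar composition per method with read-count markers.

    ``composition`` is long format (method, label, percent); per-method
    percentages must not exceed 100 by more than rounding.
    """
    out_png = Path(out_png)
    out_tsv = Path(out_tsv) if out_tsv else out_png.with_suffix(".tsv")
    sums = composition.groupby("method")["percent"].sum()
    bad = sums[sums > 100.01]
    if not bad.empty:
        raise ValueError(f"composition sums exceed 100%: {bad.to_dict()}")
    composition.to_csv(out_tsv, sep="\t", index=False)

    methods = list(dict.fromkeys(composition["method"]))
    labels = list(dict.fromkeys(composition["label"]))
    cmap = plt.get_cmap("tab20")
    colors = {lab: cmap(i % 20) for i, lab in enumerate(labels)}

    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(methods), 4.5))
    bottoms = dict.fromkeys(methods, 0.0)
    for lab in labels:
        heights = []
        for m in methods:
            row = composition[(composition["method"] == m) & (composition["label"] == lab)]
            heights.append(float(row["percent"].sum()))
        ax.bar(methods, heights, bottom=[bottoms[m] for m in methods],
               label=lab, color=colors[lab], edgecolor="white", lw=0.3)
        for m, h in zip(methods, heights):
            bottoms[m] += h
    if read_counts:
        ax2 = ax.twinx()
        ax2.plot(methods, [read_counts.get(m, 0) for m in methods], "o",
                 color="tab:orange", ms=7)
        ax2.set_ylabel("reads used", color="tab:orange")
    ax.set_ylabel("% of reads")
    ax.set_ylim(0, 100)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=6, loc="center left", bbox_to_anchor=(1.12, 0.5))
    fig.tight_layout()
    fig.savefig(out_png, dpi=dpi)
    plt.close(fig)
    return {"png": out_png, "tsv": out_tsv}
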