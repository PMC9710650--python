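"""Matplotlib renderers for the exploratory results.

Each function takes a result object from :mod:`proteoflow.exploratory`
and returns one or more figures; the pipeline collects them into one PDF
per analysis.  Rendering is intentionally plain — every number shown here
is also written to the sibling CSV, which is the authoritative output.
"""

from __future__ import annotations

import numpy as np
import matplotlib
import matplotlib.pyplot as plt
from matplotlib.patches import Circle

# figures are batched per analysis before being written to the PDF
matplotlib.rcParams["figure.max_open_warning"] = 0

from . import exploratory as ex

_VENN2_CENTERS = [(-0.35, 0.0), (0.35, 0.0)]
_VENN3_CENTERS = [(-0.35, -0.2), (0.35, -0.2), (0.0, 0.4)]


def fig_detection_counts(result: ex.DetectionCountsResult) -> list[plt.Figure]:
    figs = []
    for group, hist in result.histograms.items():
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.bar(hist.index.astype(int), hist.to_numpy(), color="#4878d0")
        ax.set_xlabel("detected in # samples")
        ax.set_ylabel("proteins")
        ax.set_title(f"Detection counts — {group} (total {result.totals[group]})")
        figs.append(fig)
    return figs


def fig_detected_per_sample(result: ex.DetectedPerSampleResult) -> list[plt.Figure]:
    frame = result.per_sample
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(frame)), 4))
    ax.bar(frame["sample"], frame["detected"], color="#4878d0")
    for group, avg in result.group_averages.items():
        members = frame.index[frame["group"] == group]
        ax.hlines(avg, members.min() - 0.4, members.max() + 0.4,
                  colors="gray", linestyles="dashed")
    ax.set_ylabel("detected proteins")
    ax.set_title("Detected proteins per sample (group average dashed)")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    return [fig]


def _draw_classic_venn(ax, result: ex.VennResult) -> None:
    names = result.set_names
    centers = _VENN2_CENTERS if len(names) == 2 else _VENN3_CENTERS
    if len(names) == 1:
        centers = [(0.0, 0.0)]
    colors = ["#4878d0", "#ee854a", "#6acc64"]
    for (x, y), name, color in zip(centers, names, colors):
        ax.add_patch(Circle((x, y), 0.55, alpha=0.35, color=color))
        ax.annotate(name, (x, y + 0.62), ha="center")
    # region labels at centroid of involved circles
    for members, proteins in result.regions.items():
        pts = [centers[names.index(m)] for m in members]
        cx = float(np.mean([p[0] for p in pts]))
        cy = float(np.mean([p[1] for p in pts]))
        # pull exclusive regions outwards a little
        if len(members) == 1 and len(names) > 1:
            cx *= 1.45
            cy = cy * 1.45 - (0.12 if len(names) == 3 else 0)
        ax.annotate(str(len(proteins)), (cx, cy), ha="center", va="center")
    ax.set_xlim(-1.3, 1.3)
    ax.set_ylim(-1.3, 1.3)
    ax.set_aspect("equal")
    ax.axis("off")


def _draw_bar_venn(ax_bar, ax_matrix, result: ex.VennResult) -> None:
    items = sorted(
        result.regions.items(), key=lambda kv: len(kv[1]), reverse=True
    )
    sizes = [len(v) for _, v in items]
    ax_bar.bar(range(len(items)), sizes, color="#4878d0")
    ax_bar.set_ylabel("intersection size")
    ax_bar.set_xticks([])
    names = result.set_names
    for col, (members, _) in enumerate(items):
        for row, name in enumerate(names):
            filled = name in members
            ax_matrix.plot(
                col, row, "o",
                color="#333333" if filled else "#dddddd", markersize=6,
            )
    ax_matrix.set_yticks(range(len(names)), names)
    ax_matrix.set_xticks([])
    ax_matrix.set_ylim(-0.5, len(names) - 0.5)
    ax_matrix.invert_yaxis()


def fig_venn(result: ex.VennResult, title: str) -> list[plt.Figure]:
    if result.style == "classic":
        fig, ax = plt.subplots(figsize=(5, 5))
        _draw_classic_venn(ax, result)
        ax.set_title(title)
    else:
        fig, (ax_bar, ax_matrix) = plt.subplots(
            2, 1, figsize=(8, 5), height_ratios=[3, 1], sharex=False
        )
        _draw_bar_venn(ax_bar, ax_matrix, result)
        ax_bar.set_title(title)
        fig.tight_layout()
    return [fig]


def fig_pca(result: ex.PCAResult) -> list[plt.Figure]:
    fig, ax = plt.subplots(figsize=(6, 5))
    coords = result.coordinates
    for group, sub in coords.groupby("group"):
        ax.scatter(sub["PC1"], sub.get("PC2", 0.0), label=str(group), s=40)
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0] * 100:.1f}%)")
    if len(evr) > 1:
        ax.set_ylabel(f"PC2 ({evr[1] * 100:.1f}%)")
    ax.legend(title="group", fontsize=8)
    ax.set_title(f"PCA overview ({result.n_proteins} complete proteins)")
    return [fig]


def fig_intensity_histogram(result: ex.IntensityHistogramResult, group: str) -> list[plt.Figure]:
    fig, ax = plt.subplots(figsize=(6, 4))
    centers = 0.5 * (result.bin_edges[:-1] + result.bin_edges[1:])
    for sample in result.counts.columns:
        ax.plot(centers, result.counts[sample], drawstyle="steps-mid", label=sample)
    ax.axvline(result.group_mean_intensity, color="gray", linestyle="dashed")
    ax.set_xlabel("log2 intensity")
    ax.set_ylabel("proteins")
    ax.set_title(f"Intensity histogram — {group}")
    ax.legend(fontsize=7)
    return [fig]


def fig_relative_sd(result: ex.RelativeSDResult, group: str) -> list[plt.Figure]:
    fig, ax = plt.subplots(figsize=(6, 4))
    frame = result.frame_
    ax.scatter(frame["mean_log2_intensity"], frame["rsd_percent"], s=6, alpha=0.5)
    shades = {10: "#c6dbef", 20: "#6baed6", 30: "#2171b5"}
    for cutoff, color in shades.items():
        ax.axhline(cutoff, color=color)
        ax.annotate(
            f"<{cutoff}%: {result.counts_below.get(cutoff, 0)}",
            (0.02, cutoff), xycoords=("axes fraction", "data"),
            va="bottom", fontsize=8, color=color,
        )
    ax.set_xlabel("mean log2 intensity")
    ax.set_ylabel("relative SD (%)")
    ax.set_title(f"Relative SD — {group}")
    return [fig]


def fig_scatter(result: ex.ScatterResult, title: str) -> list[plt.Figure]:
    figs = []
    for pair in result.pairs:
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(pair.pairs["x"], pair.pairs["y"], s=6, alpha=0.5)
        lo = min(pair.pairs[["x", "y"]].min()) if len(pair.pairs) else 0
        hi = max(pair.pairs[["x", "y"]].max()) if len(pair.pairs) else 1
        ax.plot([lo, hi], [lo, hi], color="gray", linewidth=0.8)
        ax.set_xlabel(f"{pair.name_x} (unique: {len(pair.unique_x)})")
        ax.set_ylabel(f"{pair.name_y} (unique: {len(pair.unique_y)})")
        ax.set_title(f"{title}: {pair.name_x} vs {pair.name_y} (r²={pair.r_squared:.3f})")
        figs.append(fig)
    if len(result.correlation) > 1:
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(result.correlation.to_numpy(), vmin=0, vmax=1, cmap="viridis")
        ax.set_xticks(range(len(result.correlation)), result.correlation.columns,
                      rotation=90, fontsize=7)
        ax.set_yticks(range(len(result.correlation)), result.correlation.index, fontsize=7)
        fig.colorbar(im, label="r²")
        ax.set_title(f"{title}: correlation heatmap")
        fig.tight_layout()
        figs.append(fig)
    return figs


def fig_rank(result: ex.RankResult, group: str) -> list[plt.Figure]:
    fig, ax = plt.subplots(figsize=(6, 4))
    frame = result.frame_
    plain = frame[frame["pathway"] == ""]
    ax.scatter(plain["rank_percent"], plain["mean_log2_intensity"], s=4,
               color="#cccccc", label="_")
    for pathway, sub in frame[frame["pathway"] != ""].groupby("pathway"):
        ax.scatter(sub["rank_percent"], sub["mean_log2_intensity"], s=14, label=pathway)
    for i, (_, row) in enumerate(result.pathway_stats.iterrows()):
        ax.annotate(
            f"{row['pathway']}: median {row['median_rank_percent']:.1f}%, "
            f"n={row['detected']}",
            (0.02, 0.02 + 0.05 * i), xycoords="axes fraction", fontsize=7,
        )
    ax.set_xlabel("rank (%)  —  0% = highest intensity")
    ax.set_ylabel("mean log2 intensity")
    ax.set_title(f"Rank plot — {group}")
    if len(result.pathway_stats):
        ax.legend(fontsize=7)
    return [fig]


def fig_pathway(result: ex.PathwayAnalysisResult) -> list[plt.Figure]:
    figs = []
    frame = result.intensities
    for (pathway, protein), sub in frame.groupby(["pathway", "protein"]):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        groups = list(dict.fromkeys(sub["group"]))
        for i, group in enumerate(groups):
            vals = sub.loc[sub["group"] == group, "log2_intensity"].dropna()
            ax.scatter([i] * len(vals), vals, s=18)
        ax.set_xticks(range(len(groups)), groups, rotation=45, fontsize=7)
        ax.set_ylabel("log2 intensity")
        pv = result.p_values
        sig = pv[(pv["pathway"] == pathway) & (pv["protein"] == protein)]
        note = "; ".join(
            f"{r.group_a} vs {r.group_b}: p={r.p_value:.2g}" for r in sig.itertuples()
        )
        ax.set_title(f"{pathway} / {protein}\n{note}", fontsize=8)
        fig.tight_layout()
        figs.append(fig)
    return figs


def fig_go(result: ex.GOAnalysisResult) -> list[plt.Figure]:
    figs = []
    frame = result.frame_
    for term, sub in frame.groupby("go_term"):
        fig, ax = plt.subplots(figsize=(6, 0.6 * len(sub) + 1.5))
        y = np.arange(len(sub))
        ax.barh(y, sub["detected_in_term"], color="#4878d0")
        ax.set_yticks(y, sub["group"], fontsize=8)
        for yi, (count, p) in enumerate(zip(sub["detected_in_term"], sub["p_value"])):
            ax.annotate(f" p={p:.2g}", (count, yi), va="center", fontsize=7)
        sizes = sub.iloc[0]
        ax.set_title(
            f"{term} (measured {sizes['measured_in_term']}, "
            f"list {sizes['term_size']})",
            fontsize=9,
        )
        ax.set_xlabel("detected proteins in term")
        fig.tight_layout()
        figs.append(fig)
    return figs


def fig_volcano(result: ex.VolcanoResult, alpha: float = 0.05) -> list[plt.Figure]:
    fig, ax = plt.subplots(figsize=(7, 5))
    stats = result.stats
    if len(stats):
        sig = stats["adjusted_p_value"] < alpha
        ax.scatter(stats.loc[~sig, "log2_fc"], stats.loc[~sig, "neg_log10_p"],
                   s=6, color="#999999", alpha=0.6)
        ax.scatter(stats.loc[sig, "log2_fc"], stats.loc[sig, "neg_log10_p"],
                   s=8, color="#d65f5f")
        for protein in result.annotations:
            row = stats[stats["protein"] == protein]
            if len(row):
                ax.annotate(protein, (row["log2_fc"].iloc[0], row["neg_log10_p"].iloc[0]),
                            fontsize=6)
        xmax = float(np.nanmax(np.abs(stats["log2_fc"]))) if len(stats) else 1.0
    else:
        xmax = 1.0
    # unique proteins shown at the flanks at their group intensity
    for sign, unique in ((-1, result.unique_b), (1, result.unique_a)):
        if len(unique):
            x = sign * (xmax * 1.15) * np.ones(len(unique))
            y = (unique["mean_log2_intensity"] - unique["mean_log2_intensity"].min())
            span = float(y.max()) or 1.0
            ax.scatter(x, y / span * 3.0, s=8, marker="<" if sign < 0 else ">",
                       color="#4878d0")
    ax.set_xlabel(f"log2 fold change ({result.group_a} − {result.group_b})")
    ax.set_ylabel("−log10 p-value")
    ax.set_title(
        f"Volcano: {result.group_a} vs {result.group_b} "
        f"(unique: {len(result.unique_a)} / {len(result.unique_b)})"
    )
    return [fig]
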