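"""Plot-ready computations for QC and exploratory analyses.

Each operation here computes the *data* behind one analysis of the
pipeline — detection counts, Venn regions, PCA coordinates, relative
standard deviations, rank percentiles, enrichment tables, volcano
statistics — at a chosen level of the analysis design.  Rendering to PDF
lives in :mod:`proteoflow.plots`; every result carries a ``to_frame``
method so the exact plotted numbers can be written to CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from . import stats_inference as si
from .design_tree import GroupAssignment
from .errors import InsufficientDataError, ProteoflowError
from .io_maxquant import IntensityTable
from .thresholding import Category, ThresholdPolicy, categorize

MAX_VENN_SETS = 6
CLASSIC_VENN_SETS = 3


# ---------------------------------------------------------------------------
# detection counts


@dataclass
class DetectionCountsResult:
    """Per group: histogram over "detected in exactly k samples"."""

    histograms: dict[str, pd.Series]  # group -> counts indexed by k = 1..n_g
    totals: dict[str, int]  # group -> proteins detected at least once

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group, hist in self.histograms.items():
            for k, count in hist.items():
                rows.append({"group": group, "times_detected": k, "proteins": count})
            rows.append(
                {"group": group, "times_detected": "total", "proteins": self.totals[group]}
            )
        return pd.DataFrame(rows)


def detection_counts(groups: GroupAssignment, table: IntensityTable) -> DetectionCountsResult:
    """How often proteins are detected within each group's samples.

    Proteins never detected in a group are excluded from its histogram and
    total.
    """
    histograms, totals = {}, {}
    for group, samples in groups.groups.items():
        counts = table.detection_counts(samples)
        detected = counts[counts > 0]
        hist = detected.value_counts().reindex(range(1, len(samples) + 1), fill_value=0)
        hist.index.name = "times_detected"
        histograms[group] = hist
        totals[group] = int(len(detected))
    return DetectionCountsResult(histograms=histograms, totals=totals)


@dataclass
class DetectedPerSampleResult:
    per_sample: pd.DataFrame  # columns: sample, group, detected
    group_totals: dict[str, int]
    group_averages: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        frame = self.per_sample.copy()
        frame["group_total"] = frame["group"].map(self.group_totals)
        frame["group_average"] = frame["group"].map(self.group_averages)
        return frame


def detected_per_sample(groups: GroupAssignment, table: IntensityTable) -> DetectedPerSampleResult:
    """Detected proteins per sample, with per-group totals and averages."""
    rows = []
    group_totals, group_averages = {}, {}
    for group, samples in groups.groups.items():
        per_sample = [int(table.values[s].notna().sum()) for s in samples]
        for sample, count in zip(samples, per_sample):
            rows.append({"sample": sample, "group": group, "detected": count})
        group_totals[group] = int((table.detection_counts(samples) > 0).sum())
        group_averages[group] = float(np.mean(per_sample))
    return DetectedPerSampleResult(
        per_sample=pd.DataFrame(rows), group_totals=group_totals, group_averages=group_averages
    )


# ---------------------------------------------------------------------------
# Venn diagrams


@dataclass
class VennResult:
    """Exclusive regions of up to six protein sets.

    ``regions`` maps a frozenset of set names to the proteins found in
    exactly those sets; regions are disjoint and their union equals the
    union of the input sets.
    """

    set_names: list[str]
    sets: dict[str, set[str]]
    regions: dict[frozenset, set[str]]
    style: str  # "classic" (<= 3 sets) or "bar" (<= 6 sets)

    def region_sizes(self) -> dict[frozenset, int]:
        return {k: len(v) for k, v in self.regions.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for members, proteins in sorted(
            self.regions.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
        ):
            rows.append(
                {
                    "region": "&".join(sorted(members)),
                    "n_sets": len(members),
                    "size": len(proteins),
                    "proteins": ";".join(sorted(proteins)),
                }
            )
        return pd.DataFrame(rows)


def _venn_regions(sets: dict[str, set[str]]) -> VennResult:
    names = list(sets)
    if len(names) > MAX_VENN_SETS:
        raise ProteoflowError(
            f"Venn diagrams support at most {MAX_VENN_SETS} sets, got {len(names)}"
        )
    regions: dict[frozenset, set[str]] = {}
    for r in range(1, len(names) + 1):
        for members in combinations(names, r):
            inside = set.intersection(*(sets[m] for m in members))
            outside = set.union(set(), *(sets[m] for m in names if m not in members))
            # empty regions are kept so the combination matrix is complete
            regions[frozenset(members)] = inside - outside
    style = "classic" if len(names) <= CLASSIC_VENN_SETS else "bar"
    return VennResult(set_names=names, sets=sets, regions=regions, style=style)


def venn_within_group(samples: list[str], table: IntensityTable) -> VennResult:
    """Venn regions of the per-sample detected-protein sets of one group."""
    sets = {
        s: set(table.values.index[table.values[s].notna()]) for s in samples
    }
    return _venn_regions(sets)


def venn_between_groups(
    groups: GroupAssignment, table: IntensityTable, policy: ThresholdPolicy
) -> VennResult:
    """Venn regions of per-group above-threshold protein sets.

    A protein belongs to a group's set iff its detection count meets the
    sigmoidal threshold for that group's size.
    """
    sets = {}
    for group, samples in groups.groups.items():
        counts = table.detection_counts(samples)
        needed = policy.required_count(len(samples))
        sets[group] = set(counts.index[counts >= needed])
    return _venn_regions(sets)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # samples × {PC1, PC2}, plus group column
    explained_variance_ratio: np.ndarray
    n_proteins: int

    def to_frame(self) -> pd.DataFrame:
        frame = self.coordinates.reset_index()
        for i, ratio in enumerate(self.explained_variance_ratio, start=1):
            frame[f"explained_variance_PC{i}"] = ratio
        frame["n_complete_proteins"] = self.n_proteins
        return frame


def pca_overview(
    groups: GroupAssignment, table: IntensityTable, n_components: int = 2
) -> PCAResult:
    """PCA of the samples on proteins detected in *all* samples.

    Proteins with any missing value are excluded (complete-case rule), so
    the projection uses exactly the proteins quantified everywhere.
    """
    samples = groups.samples
    if len(samples) < 2:
        raise InsufficientDataError("PCA needs at least 2 samples")
    sub = table.values[samples]
    complete = sub.dropna(axis=0)
    if len(complete) < 2:
        raise InsufficientDataError(
            f"PCA needs >= 2 proteins detected in all samples, got {len(complete)}"
        )
    n_components = min(n_components, len(samples) - 1, len(complete))
    model = PCA(n_components=n_components)
    coords = model.fit_transform(complete.T.to_numpy())
    frame = pd.DataFrame(
        coords, index=samples, columns=[f"PC{i+1}" for i in range(n_components)]
    )
    sample_to_group = {s: g for g, ss in groups.groups.items() for s in ss}
    frame["group"] = [sample_to_group[s] for s in samples]
    frame.index.name = "sample"
    return PCAResult(
        coordinates=frame,
        explained_variance_ratio=model.explained_variance_ratio_,
        n_proteins=len(complete),
    )


# ---------------------------------------------------------------------------
# intensity histogram


@dataclass
class IntensityHistogramResult:
    bin_edges: np.ndarray
    counts: pd.DataFrame  # bins × samples
    group_mean_intensity: float

    def to_frame(self) -> pd.DataFrame:
        frame = self.counts.copy()
        frame.insert(0, "bin_left", self.bin_edges[:-1])
        frame.insert(1, "bin_right", self.bin_edges[1:])
        frame["group_mean_intensity"] = self.group_mean_intensity
        return frame


def intensity_histogram(
    samples: list[str], table: IntensityTable, bins: int = 25
) -> IntensityHistogramResult:
    """Binned log2 intensities per sample of one group, on shared edges."""
    sub = table.values[list(samples)]
    flat = sub.to_numpy().ravel()
    flat = flat[np.isfinite(flat)]
    if flat.size == 0:
        raise InsufficientDataError("no observed intensities in the group")
    edges = np.histogram_bin_edges(flat, bins=bins)
    counts = {
        s: np.histogram(sub[s].dropna().to_numpy(), bins=edges)[0] for s in samples
    }
    return IntensityHistogramResult(
        bin_edges=edges,
        counts=pd.DataFrame(counts),
        group_mean_intensity=float(flat.mean()),
    )


# ---------------------------------------------------------------------------
# relative standard deviation


@dataclass
class RelativeSDResult:
    frame_: pd.DataFrame  # protein, mean_log2, rsd_percent
    counts_below: dict[int, int]  # {10: ..., 20: ..., 30: ...}

    def to_frame(self) -> pd.DataFrame:
        frame = self.frame_.copy()
        for cutoff, count in self.counts_below.items():
            frame[f"n_below_{cutoff}pct"] = count
        return frame


def relative_sd(
    samples: list[str],
    table: IntensityTable,
    policy: ThresholdPolicy,
    cutoffs: tuple[int, ...] = (10, 20, 30),
) -> RelativeSDResult:
    """Relative SD (%) versus mean intensity for above-threshold proteins.

    The coefficient of variation is computed on linear-scale intensities
    (2^log2), since a percent SD of log values is not scale-meaningful;
    the mean shown alongside stays on the log2 scale.
    """
    sub = table.values[list(samples)]
    counts = sub.notna().sum(axis=1)
    needed = policy.required_count(len(samples))
    keep = counts[(counts >= needed) & (counts >= 2)].index
    linear = np.power(2.0, sub.loc[keep])
    mean_lin = linear.mean(axis=1, skipna=True)
    sd_lin = linear.std(axis=1, ddof=1, skipna=True)
    rsd = sd_lin / mean_lin * 100.0
    frame = pd.DataFrame(
        {
            "mean_log2_intensity": sub.loc[keep].mean(axis=1, skipna=True),
            "rsd_percent": rsd,
        }
    )
    frame.index.name = "protein"
    counts_below = {c: int((rsd < c).sum()) for c in cutoffs}
    return RelativeSDResult(frame_=frame.reset_index(), counts_below=counts_below)


# ---------------------------------------------------------------------------
# scatter replicates / experiment comparison


@dataclass
class PairScatter:
    name_x: str
    name_y: str
    pairs: pd.DataFrame  # protein, x, y (pairwise complete)
    r_squared: float
    unique_x: list[str]  # observed in x only
    unique_y: list[str]


@dataclass
class ScatterResult:
    pairs: list[PairScatter]
    correlation: pd.DataFrame  # r² matrix

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.pairs:
            frame = p.pairs.copy()
            frame.insert(0, "x_name", p.name_x)
            frame.insert(1, "y_name", p.name_y)
            frame["r_squared"] = p.r_squared
            frame["unique_in_x"] = ";".join(p.unique_x)
            frame["unique_in_y"] = ";".join(p.unique_y)
            rows.append(frame)
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


def _pairwise_scatter(columns: pd.DataFrame) -> ScatterResult:
    names = list(columns.columns)
    corr = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    pairs = []
    for x, y in combinations(names, 2):
        both = columns[[x, y]].dropna()
        try:
            r2 = si.pearson_r2(both[x], both[y])
        except InsufficientDataError:
            r2 = float("nan")
        corr.loc[x, y] = corr.loc[y, x] = r2
        ux = columns.index[columns[x].notna() & columns[y].isna()]
        uy = columns.index[columns[y].notna() & columns[x].isna()]
        frame = both.rename(columns={x: "x", y: "y"}).reset_index()
        pairs.append(
            PairScatter(
                name_x=x,
                name_y=y,
                pairs=frame,
                r_squared=r2,
                unique_x=list(ux),
                unique_y=list(uy),
            )
        )
    return ScatterResult(pairs=pairs, correlation=corr)


def scatter_replicates(samples: list[str], table: IntensityTable) -> ScatterResult:
    """Sample-vs-sample intensities within a group, with r² and per-sample
    unique proteins."""
    return _pairwise_scatter(table.values[list(samples)])


def experiment_comparison(
    groups: GroupAssignment, table: IntensityTable, policy: ThresholdPolicy
) -> ScatterResult:
    """Group-vs-group mean intensities for mutually comparable proteins.

    Group means are taken over non-missing values; a protein contributes
    to a pair's scatter only when above threshold in both groups, to a
    unique list when above threshold in one group and entirely undetected
    in the other (the four-scenario categorization).
    """
    names = list(groups.groups)
    means = {}
    counts = {}
    for group, samples in groups.groups.items():
        sub = table.values[samples]
        means[group] = sub.mean(axis=1, skipna=True)
        counts[group] = sub.notna().sum(axis=1)
    mean_frame = pd.DataFrame(means)
    corr = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    pairs = []
    for ga, gb in combinations(names, 2):
        n_a, n_b = len(groups.groups[ga]), len(groups.groups[gb])
        labels = [
            categorize(int(counts[ga][p]), n_a, int(counts[gb][p]), n_b, policy)
            for p in mean_frame.index
        ]
        labels = pd.Series(labels, index=mean_frame.index)
        comp = mean_frame.index[labels == Category.COMPARABLE]
        both = mean_frame.loc[comp, [ga, gb]]
        try:
            r2 = si.pearson_r2(both[ga], both[gb])
        except InsufficientDataError:
            r2 = float("nan")
        corr.loc[ga, gb] = corr.loc[gb, ga] = r2
        pairs.append(
            PairScatter(
                name_x=ga,
                name_y=gb,
                pairs=both.rename(columns={ga: "x", gb: "y"}).reset_index(),
                r_squared=r2,
                unique_x=list(mean_frame.index[labels == Category.UNIQUE_IN_A]),
                unique_y=list(mean_frame.index[labels == Category.UNIQUE_IN_B]),
            )
        )
    return ScatterResult(pairs=pairs, correlation=corr)


# ---------------------------------------------------------------------------
# rank plot


@dataclass
class RankResult:
    frame_: pd.DataFrame  # protein, mean_log2, percentile, pathway
    pathway_stats: pd.DataFrame  # pathway, median_rank_percent, detected

    def to_frame(self) -> pd.DataFrame:
        return self.frame_.copy()


def rank_plot(
    samples: list[str],
    table: IntensityTable,
    pathways: dict[str, set[str]] | None = None,
) -> RankResult:
    """Rank proteins of one group by mean intensity.

    The highest-intensity protein gets percentile 0%, the lowest 100%
    (``100·i/(N−1)``; a single protein ranks 0%).  Pathway membership is
    matched case-insensitively on protein identifiers; each pathway
    reports the median rank of its detected members.
    """
    pathways = pathways or {}
    sub = table.values[list(samples)]
    means = sub.mean(axis=1, skipna=True).dropna().sort_values(ascending=False)
    n = len(means)
    if n == 0:
        raise InsufficientDataError("no detected proteins in the group")
    percentile = (
        np.zeros(1) if n == 1 else 100.0 * np.arange(n) / (n - 1)
    )
    lowered = {name: {g.lower() for g in members} for name, members in pathways.items()}

    def membership(protein: str) -> str:
        for name, members in lowered.items():
            if protein.lower() in members:
                return name
        return ""

    frame = pd.DataFrame(
        {
            "protein": means.index,
            "mean_log2_intensity": means.to_numpy(),
            "rank_percent": percentile,
        }
    )
    frame["pathway"] = [membership(p) for p in frame["protein"]]
    stats_rows = []
    for name in pathways:
        member_rows = frame[frame["pathway"] == name]
        stats_rows.append(
            {
                "pathway": name,
                "median_rank_percent": float(member_rows["rank_percent"].median())
                if len(member_rows)
                else float("nan"),
                "detected": int(len(member_rows)),
                "pathway_size": len(pathways[name]),
            }
        )
    return RankResult(frame_=frame, pathway_stats=pd.DataFrame(stats_rows))


# ---------------------------------------------------------------------------
# pathway analysis


@dataclass
class PathwayAnalysisResult:
    intensities: pd.DataFrame  # pathway, protein, group, sample, log2_intensity
    p_values: pd.DataFrame  # pathway, protein, group_a, group_b, p_value

    def to_frame(self) -> pd.DataFrame:
        frame = self.intensities.copy()
        if len(self.p_values):
            key = ["pathway", "protein"]
            merged = self.p_values.copy()
            merged["comparison"] = merged["group_a"] + " vs " + merged["group_b"]
            summary = merged.groupby(key).apply(
                lambda g: ";".join(
                    f"{c}:p={p:.3g}" for c, p in zip(g["comparison"], g["p_value"])
                ),
                include_groups=False,
            )
            frame = frame.merge(
                summary.rename("p_values").reset_index(), on=key, how="left"
            )
        return frame


def pathway_analysis(
    groups: GroupAssignment,
    table: IntensityTable,
    pathways: dict[str, set[str]],
    policy: ThresholdPolicy,
) -> PathwayAnalysisResult:
    """Per pathway protein: per-group intensity points and pairwise t-tests.

    A pairwise p-value is computed (pooled-variance two-sample t-test)
    only where the protein is above the detection threshold in both
    groups of the pair.
    """
    lowered_index = {p.lower(): p for p in table.values.index}
    points, pvals = [], []
    for pathway, members in pathways.items():
        proteins = sorted(
            {lowered_index[m.lower()] for m in members if m.lower() in lowered_index}
        )
        for protein in proteins:
            for group, samples in groups.groups.items():
                for sample in samples:
                    value = table.values.at[protein, sample]
                    points.append(
                        {
                            "pathway": pathway,
                            "protein": protein,
                            "group": group,
                            "sample": sample,
                            "log2_intensity": value,
                        }
                    )
            for ga, gb in combinations(groups.groups, 2):
                sa = table.values.loc[protein, groups.groups[ga]]
                sb = table.values.loc[protein, groups.groups[gb]]
                if not (
                    policy.above_threshold(int(sa.notna().sum()), len(sa))
                    and policy.above_threshold(int(sb.notna().sum()), len(sb))
                ):
                    continue
                try:
                    _, p, _ = si.independent_t_test(sa, sb)
                except InsufficientDataError:
                    continue
                pvals.append(
                    {
                        "pathway": pathway,
                        "protein": protein,
                        "group_a": ga,
                        "group_b": gb,
                        "p_value": p,
                    }
                )
    return PathwayAnalysisResult(
        intensities=pd.DataFrame(points),
        p_values=pd.DataFrame(pvals, columns=["pathway", "protein", "group_a", "group_b", "p_value"]),
    )


# ---------------------------------------------------------------------------
# GO analysis


@dataclass
class GOAnalysisResult:
    frame_: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.frame_.copy()


def go_analysis(
    groups: GroupAssignment,
    table: IntensityTable,
    go_terms: dict[str, set[str]],
) -> GOAnalysisResult:
    """Per GO term and group: detected in-term count and Fisher p-value.

    The background is the measured proteome (all proteins in the filtered
    table); "detected" means detected in at least one sample of the
    group.  The one-tailed Fisher test asks whether detected proteins are
    enriched for the term.
    """
    background = set(table.values.index)
    lowered_index = {p.lower(): p for p in background}
    rows = []
    for term, members in go_terms.items():
        in_term = {lowered_index[m.lower()] for m in members if m.lower() in lowered_index}
        for group, samples in groups.groups.items():
            counts = table.detection_counts(samples)
            detected = set(counts.index[counts > 0])
            a = len(in_term & detected)
            b = len(in_term - detected)
            c = len(detected - in_term)
            d = len(background) - a - b - c
            p = si.fisher_one_tailed(si.EnrichmentTable(a, b, c, d))
            rows.append(
                {
                    "go_term": term,
                    "group": group,
                    "detected_in_term": a,
                    "measured_in_term": len(in_term),
                    "term_size": len(members),
                    "detected_total": len(detected),
                    "background": len(background),
                    "p_value": p,
                }
            )
    return GOAnalysisResult(frame_=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# volcano


@dataclass
class VolcanoResult:
    """Differential comparison of two groups.

    ``stats`` holds one row per comparable protein (log2 fold change,
    moderated-t p-value, BH-adjusted p-value); proteins unique to one
    group are listed apart with their within-group mean intensities.
    """

    group_a: str
    group_b: str
    stats: pd.DataFrame
    unique_a: pd.DataFrame  # protein, mean_log2_intensity
    unique_b: pd.DataFrame
    excluded: list[str]
    annotations: list[str]
    prior_df: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        stats = self.stats.copy()
        stats.insert(0, "category", Category.COMPARABLE.value)
        ua = self.unique_a.copy()
        ua.insert(0, "category", Category.UNIQUE_IN_A.value)
        ub = self.unique_b.copy()
        ub.insert(0, "category", Category.UNIQUE_IN_B.value)
        ex = pd.DataFrame({"protein": self.excluded})
        ex.insert(0, "category", Category.NOT_CONSIDERED.value)
        out = pd.concat([stats, ua, ub, ex], ignore_index=True)
        out["comparison"] = f"{self.group_a} vs {self.group_b}"
        out["annotated"] = out["protein"].isin(self.annotations)
        return out


def volcano(
    group_a: str,
    samples_a: list[str],
    group_b: str,
    samples_b: list[str],
    table: IntensityTable,
    policy: ThresholdPolicy,
    pathways: dict[str, set[str]] | None = None,
    annotate_top: int = 10,
) -> VolcanoResult:
    """Moderated-t differential analysis of two groups with unique lists.

    Proteins are first categorized by the detection threshold; comparable
    proteins enter an intensity-trended moderated t-test with BH
    adjustment, unique proteins are reported with their group means, and
    the rest are excluded.  Annotations are the members of the given
    pathways, or the ``annotate_top`` proteins with smallest adjusted p.
    """
    sub_a = table.values[list(samples_a)]
    sub_b = table.values[list(samples_b)]
    det_a = sub_a.notna().sum(axis=1)
    det_b = sub_b.notna().sum(axis=1)
    n_a, n_b = len(samples_a), len(samples_b)
    labels = pd.Series(
        [
            categorize(int(det_a[p]), n_a, int(det_b[p]), n_b, policy)
            for p in table.values.index
        ],
        index=table.values.index,
    )
    comparable = labels.index[labels == Category.COMPARABLE]
    testable = [p for p in comparable if det_a[p] >= 2 and det_b[p] >= 2]

    if testable:
        fit = si.moderated_t_fit(sub_a.loc[testable], sub_b.loc[testable], trend=True)
        adj = si.benjamini_hochberg(fit.p_value)
        stats = pd.DataFrame(
            {
                "protein": testable,
                "log2_fc": fit.log2_fc,
                "mean_A": fit.mean_a,
                "mean_B": fit.mean_b,
                "t": fit.t,
                "p_value": fit.p_value,
                "adjusted_p_value": adj,
                "neg_log10_p": -np.log10(fit.p_value),
                "neg_log10_adjusted_p": -np.log10(adj),
            }
        )
        prior_df = fit.prior_df
    else:
        stats = pd.DataFrame(
            columns=[
                "protein",
                "log2_fc",
                "mean_A",
                "mean_B",
                "t",
                "p_value",
                "adjusted_p_value",
                "neg_log10_p",
                "neg_log10_adjusted_p",
            ]
        )
        prior_df = float("nan")
    untestable = [p for p in comparable if p not in set(testable)]

    def unique_frame(proteins: pd.Index, sub: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein": list(proteins),
                "mean_log2_intensity": sub.loc[proteins].mean(axis=1, skipna=True).to_numpy(),
            }
        )

    unique_a = unique_frame(labels.index[labels == Category.UNIQUE_IN_A], sub_a)
    unique_b = unique_frame(labels.index[labels == Category.UNIQUE_IN_B], sub_b)
    excluded = list(labels.index[labels == Category.NOT_CONSIDERED]) + untestable

    if pathways:
        lowered = {g.lower() for members in pathways.values() for g in members}
        annotations = [p for p in stats["protein"] if p.lower() in lowered]
    else:
        annotations = list(
            stats.sort_values("adjusted_p_value")["protein"].head(annotate_top)
        )
    return VolcanoResult(
        group_a=group_a,
        group_b=group_b,
        stats=stats,
        unique_a=unique_a,
        unique_b=unique_b,
        excluded=excluded,
        annotations=annotations,
        prior_df=prior_df,
    )
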