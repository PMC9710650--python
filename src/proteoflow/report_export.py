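"""Pipeline orchestration: run analyses, export PDFs + CSVs, log settings.

Every enabled analysis writes exactly one PDF (possibly multi-page) and
one CSV carrying the plotted numbers.  The complete run configuration —
including the package version and defaults the user never touched — is
saved alongside as YAML, so a run can be reproduced bit-for-bit from the
input file, the config and the seed.  Analyses are isolated: a failure in
one is logged and the run continues with the rest.
"""

from __future__ import annotations

import copy
import hashlib
import warnings
from dataclasses import dataclass
from datetime import datetime, timezone
from itertools import combinations
from pathlib import Path

import matplotlib.pyplot as plt
import pandas as pd
import yaml
from matplotlib.backends.backend_pdf import PdfPages

from . import __version__, exploratory as ex, plots
from .design_tree import GroupAssignment, build_design, groups_at_level
from .errors import ConfigError, ProteoflowError
from .io_maxquant import IntensityTable, load_intensity_table
from .normalization import METHODS, NormalizationSpec, apply_normalization
from .thresholding import ThresholdPolicy

#: Analyses runnable without pathway / GO term lists.
CORE_ANALYSES = (
    "detection_counts",
    "detected_per_sample",
    "venn_within_group",
    "venn_between_groups",
    "pca_overview",
    "intensity_histogram",
    "relative_sd",
    "scatter_replicates",
    "experiment_comparison",
    "rank",
    "volcano",
)
LIST_ANALYSES = ("pathway_analysis", "go_analysis")
ALL_ANALYSES = CORE_ANALYSES + LIST_ANALYSES


def default_config() -> dict:
    return {
        "input": {"path": None, "flavor": "raw"},
        "design": {"separator": "_", "level": 0},
        "threshold": {"n_full": 3, "n_half": 12, "steepness": 1.0},
        "normalization": {"method": "median_norm", "seed": 0},
        "lists": {"pathways_dir": None, "go_dir": None},
        "analyses": None,  # None = all feasible
        "output_dir": "proteoflow_out",
        "seed": 0,
        "version": __version__,
    }


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            warnings.warn(f"unknown config key {where!r} ignored", stacklevel=2)
            continue
        if isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = _merge(base[key], value, where)
        else:
            out[key] = value
    return out


def make_config(overrides: dict | None = None) -> dict:
    """Full config from defaults plus overrides; unknown keys warn."""
    cfg = _merge(default_config(), overrides or {})
    if cfg["normalization"]["method"] not in METHODS:
        raise ConfigError(
            f"unknown normalization method {cfg['normalization']['method']!r}; "
            f"expected one of {METHODS}"
        )
    return cfg


def save_config(config: dict, path: str | Path) -> None:
    config = dict(config, version=__version__)
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def load_config(path: str | Path) -> dict:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.pop("version", None)
    return make_config(raw)


def read_term_lists(directory: str | Path | None) -> dict[str, set[str]]:
    """Read plain-text protein lists (one gene symbol per line) from a
    directory; the file stem names the term."""
    if directory is None:
        return {}
    out = {}
    for file in sorted(Path(directory).glob("*.txt")):
        symbols = {line.strip() for line in file.read_text().splitlines() if line.strip()}
        out[file.stem] = symbols
    return out


@dataclass
class PipelineContext:
    table: IntensityTable
    groups: GroupAssignment
    policy: ThresholdPolicy
    pathways: dict[str, set[str]]
    go_terms: dict[str, set[str]]
    config: dict


def _build_context(config: dict) -> PipelineContext:
    inp = config["input"]
    if not inp.get("path"):
        raise ConfigError("input.path is required")
    table = load_intensity_table(inp["path"], inp.get("flavor", "raw"))
    spec = NormalizationSpec(
        method=config["normalization"]["method"],
        rng_seed=int(config["normalization"].get("seed", config.get("seed", 0))),
    )
    table = apply_normalization(table, spec)
    design = build_design(table.sample_names, config["design"]["separator"])
    groups = groups_at_level(design, int(config["design"]["level"]))
    policy = ThresholdPolicy(
        n_full=int(config["threshold"]["n_full"]),
        n_half=int(config["threshold"]["n_half"]),
        steepness=float(config["threshold"]["steepness"]),
    )
    return PipelineContext(
        table=table,
        groups=groups,
        policy=policy,
        pathways=read_term_lists(config["lists"]["pathways_dir"]),
        go_terms=read_term_lists(config["lists"]["go_dir"]),
        config=config,
    )


# --- analysis handlers: name -> (frame, figures) ---------------------------


def _run_detection_counts(ctx):
    res = ex.detection_counts(ctx.groups, ctx.table)
    return res.to_frame(), plots.fig_detection_counts(res)


def _run_detected_per_sample(ctx):
    res = ex.detected_per_sample(ctx.groups, ctx.table)
    return res.to_frame(), plots.fig_detected_per_sample(res)


def _run_venn_within(ctx):
    frames, figs = [], []
    for group, samples in ctx.groups.groups.items():
        if not 1 <= len(samples) <= ex.MAX_VENN_SETS:
            continue
        res = ex.venn_within_group(samples, ctx.table)
        frame = res.to_frame()
        frame.insert(0, "group", group)
        frames.append(frame)
        figs.extend(plots.fig_venn(res, f"Detected proteins — {group}"))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(), figs


def _run_venn_between(ctx):
    res = ex.venn_between_groups(ctx.groups, ctx.table, ctx.policy)
    return res.to_frame(), plots.fig_venn(res, "Above-threshold proteins per group")


def _run_pca(ctx):
    res = ex.pca_overview(ctx.groups, ctx.table)
    return res.to_frame(), plots.fig_pca(res)


def _run_intensity_histogram(ctx):
    frames, figs = [], []
    for group, samples in ctx.groups.groups.items():
        res = ex.intensity_histogram(samples, ctx.table)
        frame = res.to_frame()
        frame.insert(0, "group", group)
        frames.append(frame)
        figs.extend(plots.fig_intensity_histogram(res, group))
    return pd.concat(frames, ignore_index=True), figs


def _run_relative_sd(ctx):
    frames, figs = [], []
    for group, samples in ctx.groups.groups.items():
        res = ex.relative_sd(samples, ctx.table, ctx.policy)
        frame = res.to_frame()
        frame.insert(0, "group", group)
        frames.append(frame)
        figs.extend(plots.fig_relative_sd(res, group))
    return pd.concat(frames, ignore_index=True), figs


def _run_scatter_replicates(ctx):
    frames, figs = [], []
    for group, samples in ctx.groups.groups.items():
        if len(samples) < 2:
            continue
        res = ex.scatter_replicates(samples, ctx.table)
        frame = res.to_frame()
        if len(frame):
            frame.insert(0, "group", group)
            frames.append(frame)
        figs.extend(plots.fig_scatter(res, f"Replicates — {group}"))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(), figs


def _run_experiment_comparison(ctx):
    res = ex.experiment_comparison(ctx.groups, ctx.table, ctx.policy)
    return res.to_frame(), plots.fig_scatter(res, "Groups")


def _run_rank(ctx):
    frames, figs = [], []
    for group, samples in ctx.groups.groups.items():
        res = ex.rank_plot(samples, ctx.table, ctx.pathways)
        frame = res.to_frame()
        frame.insert(0, "group", group)
        frames.append(frame)
        figs.extend(plots.fig_rank(res, group))
    return pd.concat(frames, ignore_index=True), figs


def _run_pathway(ctx):
    if not ctx.pathways:
        raise ConfigError("pathway_analysis requires lists.pathways_dir")
    res = ex.pathway_analysis(ctx.groups, ctx.table, ctx.pathways, ctx.policy)
    return res.to_frame(), plots.fig_pathway(res)


def _run_go(ctx):
    if not ctx.go_terms:
        raise ConfigError("go_analysis requires lists.go_dir")
    res = ex.go_analysis(ctx.groups, ctx.table, ctx.go_terms)
    return res.to_frame(), plots.fig_go(res)


def _run_volcano(ctx):
    frames, figs = [], []
    names = list(ctx.groups.groups)
    for ga, gb in combinations(names, 2):
        res = ex.volcano(
            ga, ctx.groups.groups[ga], gb, ctx.groups.groups[gb],
            ctx.table, ctx.policy, pathways=ctx.pathways or None,
        )
        frames.append(res.to_frame())
        figs.extend(plots.fig_volcano(res))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(), figs


HANDLERS = {
    "detection_counts": _run_detection_counts,
    "detected_per_sample": _run_detected_per_sample,
    "venn_within_group": _run_venn_within,
    "venn_between_groups": _run_venn_between,
    "pca_overview": _run_pca,
    "intensity_histogram": _run_intensity_histogram,
    "relative_sd": _run_relative_sd,
    "scatter_replicates": _run_scatter_replicates,
    "experiment_comparison": _run_experiment_comparison,
    "rank": _run_rank,
    "pathway_analysis": _run_pathway,
    "go_analysis": _run_go,
    "volcano": _run_volcano,
}


def _write_outputs(name: str, frame: pd.DataFrame, figures, outdir: Path) -> None:
    frame.to_csv(outdir / f"{name}.csv", index=False)
    with PdfPages(outdir / f"{name}.pdf") as pdf:
        if not figures:
            fig, ax = plt.subplots()
            ax.axis("off")
            ax.annotate(f"{name}: nothing to plot", (0.5, 0.5), ha="center")
            figures = [fig]
        for fig in figures:
            pdf.savefig(fig)
            plt.close(fig)


def run_pipeline(config: dict) -> Path:
    """Execute the configured analyses; return the output directory.

    Writes, per analysis, ``<name>.pdf`` and ``<name>.csv``; plus
    ``config.yml`` (the complete settings actually used) and ``run.log``.
    """
    config = make_config(config)
    ctx = _build_context(config)
    outdir = Path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)

    requested = config["analyses"]
    if requested is None:
        requested = list(CORE_ANALYSES)
        if ctx.pathways:
            requested.append("pathway_analysis")
        if ctx.go_terms:
            requested.append("go_analysis")
    unknown = [a for a in requested if a not in HANDLERS]
    if unknown:
        raise ConfigError(f"unknown analyses: {unknown}; known: {sorted(HANDLERS)}")

    log_lines = [
        f"{datetime.now(timezone.utc).isoformat()} proteoflow {__version__}",
        f"input: {config['input']['path']} "
        f"(sha256 {_checksum(config['input']['path'])})",
        f"flavor: {config['input']['flavor']}  "
        f"normalization: {config['normalization']['method']}  "
        f"level: {config['design']['level']}",
        f"table: {ctx.table.shape[0]} proteins x {ctx.table.shape[1]} samples",
    ]
    for name in requested:
        try:
            frame, figures = HANDLERS[name](ctx)
            _write_outputs(name, frame, figures, outdir)
            log_lines.append(
                f"{datetime.now(timezone.utc).isoformat()} {name}: ok "
                f"({len(frame)} rows)"
            )
        except ProteoflowError as exc:
            log_lines.append(
                f"{datetime.now(timezone.utc).isoformat()} {name}: FAILED — {exc}"
            )
    save_config(config, outdir / "config.yml")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return outdir


def qc_report(config: dict) -> Path:
    """Bundle the QC analyses into one multi-page PDF.

    Pages: detected proteins per sample, detection counts, intensity
    histograms, replicate scatters, relative SD, PCA — technical and
    biological parameters at a glance.  The underlying numbers equal the
    standalone analyses' CSVs.
    """
    config = make_config(config)
    ctx = _build_context(config)
    if ctx.table.shape[0] == 0:
        raise ProteoflowError("empty intensity table; cannot build a QC report")
    outdir = Path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "qc_report.pdf"
    sections = (
        "detected_per_sample",
        "detection_counts",
        "intensity_histogram",
        "scatter_replicates",
        "relative_sd",
        "pca_overview",
    )
    with PdfPages(path) as pdf:
        for name in sections:
            _, figures = HANDLERS[name](ctx)
            for fig in figures:
                pdf.savefig(fig)
                plt.close(fig)
    save_config(config, outdir / "config.yml")
    return path


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
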