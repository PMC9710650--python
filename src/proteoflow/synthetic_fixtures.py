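"""Generator for MaxQuant-dialect protein-group tables with known truth.

Emulates the statistical structure of a label-free DDA benchmark
experiment: log-normally distributed protein abundances, per-sample
systematic shifts (pipetting/loading differences), replicate noise,
intensity-dependent dropout (low-abundance proteins are censored more
often — the missing-not-at-random regime the detection threshold exists
for), planted differential effects in one group, and a fraction of rows
flagged as contaminants / decoys / site-only identifications.

The generated file carries all three intensity flavors (raw, LFQ, iBAQ)
and parses through :mod:`proteoflow.io_maxquant` without warnings.  The
returned :class:`GroundTruth` records the exact log2 matrices, missing
mask, flagged rows and planted-effect proteins, so every downstream
module can be tested against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic benchmark-style dataset.

    The default design is 2 cell lines × 3 treatments × 2 replicates
    (12 samples) with log2 abundances around 25 ± 2 (typical orbitrap
    protein intensities span roughly 2^20–2^30), replicate noise of
    0.3 log2 units, per-sample shifts of SD 0.5 log2 units, logistic
    intensity-dependent dropout, and 10% of proteins shifted by 1 log2
    unit in one group.
    """

    n_proteins: int = 1000
    lines: tuple[str, ...] = ("A", "B")
    treatments: tuple[str, ...] = ("ctrl", "t1", "t2")
    replicates: int = 2
    base_mean: float = 25.0  # log2 units
    base_sd: float = 2.0
    noise_sd: float = 0.3  # replicate noise, log2 units
    sample_shift_sd: float = 0.5  # systematic per-sample shift, log2 units
    dropout: bool = True
    dropout_midpoint: float = 21.0  # log2 intensity of 50% dropout
    dropout_steepness: float = 1.0  # per log2 unit
    effect_fraction: float = 0.1
    effect_size: float = 1.0  # log2 units added in the affected group
    effect_group: str = "B"  # sample-name prefix receiving the effect
    contaminant_fraction: float = 0.05
    reverse_fraction: float = 0.02
    site_fraction: float = 0.02
    seed: int = 0

    @property
    def sample_names(self) -> list[str]:
        names = []
        for line in self.lines:
            if self.treatments:
                for treat in self.treatments:
                    for r in range(self.replicates):
                        names.append(f"{line}_{treat}_r{r + 1}")
            else:
                for r in range(self.replicates):
                    names.append(f"{line}_r{r + 1}")
        return names


@dataclass
class GroundTruth:
    """Exact planted values of a generated fixture."""

    log2: dict[str, pd.DataFrame]  # flavor -> proteins × samples (NaN = missing)
    missing_mask: pd.DataFrame
    flags: pd.DataFrame  # boolean, one column per flag
    planted_proteins: list[str]
    sample_shifts: pd.Series
    spec: FixtureSpec

    @property
    def unflagged(self) -> pd.Index:
        return self.flags.index[~self.flags.any(axis=1)]


FLAG_NAMES = ("Only identified by site", "Reverse", "Potential contaminant")


def generate(spec: FixtureSpec, path: str | Path | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a protein-group table; optionally write it to ``path``.

    Returns the written frame and the ground truth.  Identical spec (same
    seed) gives byte-identical files.
    """
    if spec.n_proteins < 1:
        raise ConfigError("need at least one protein")
    samples = spec.sample_names
    if not samples:
        raise ConfigError("design yields zero samples")
    rng = np.random.default_rng(spec.seed)

    proteins = [f"GENE{i:05d}" for i in range(spec.n_proteins)]
    base = rng.normal(spec.base_mean, spec.base_sd, size=spec.n_proteins)
    shifts = pd.Series(
        rng.normal(0.0, spec.sample_shift_sd, size=len(samples)), index=samples
    )

    n_effect = int(round(spec.effect_fraction * spec.n_proteins))
    planted = sorted(rng.choice(spec.n_proteins, size=n_effect, replace=False).tolist())
    effect = np.zeros((spec.n_proteins, len(samples)))
    affected_cols = [
        j for j, s in enumerate(samples)
        if s == spec.effect_group or s.startswith(spec.effect_group + "_")
    ]
    for i in planted:
        effect[i, affected_cols] = spec.effect_size

    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_proteins, len(samples)))
    biological = base[:, None] + effect + noise  # cross-sample-comparable signal
    raw_log2 = biological + shifts.to_numpy()[None, :]

    # intensity-dependent (left-censoring) dropout, decided on raw intensity
    if spec.dropout:
        p_miss = 1.0 / (
            1.0 + np.exp(spec.dropout_steepness * (raw_log2 - spec.dropout_midpoint))
        )
        missing = rng.random(raw_log2.shape) < p_miss
    else:
        missing = np.zeros(raw_log2.shape, dtype=bool)

    n_peptides = rng.integers(3, 60, size=spec.n_proteins)
    flavors = {
        "raw": raw_log2,
        "lfq": biological,
        "ibaq": raw_log2 - np.log2(n_peptides)[:, None],
    }
    log2_truth = {
        flavor: pd.DataFrame(
            np.where(missing, np.nan, mat), index=proteins, columns=samples
        )
        for flavor, mat in flavors.items()
    }

    # disjoint flagged-row sets
    n_flagged = {
        "Potential contaminant": int(round(spec.contaminant_fraction * spec.n_proteins)),
        "Reverse": int(round(spec.reverse_fraction * spec.n_proteins)),
        "Only identified by site": int(round(spec.site_fraction * spec.n_proteins)),
    }
    pool = rng.permutation(spec.n_proteins)
    flags = pd.DataFrame(False, index=proteins, columns=list(FLAG_NAMES))
    cursor = 0
    for flag in FLAG_NAMES:
        take = pool[cursor : cursor + n_flagged[flag]]
        flags.iloc[take, flags.columns.get_loc(flag)] = True
        cursor += n_flagged[flag]

    frame = pd.DataFrame(
        {
            "Protein IDs": [f"P{i:05d}" for i in range(spec.n_proteins)],
            "Majority protein IDs": [f"P{i:05d}" for i in range(spec.n_proteins)],
            "Gene names": proteins,
        }
    )
    for flag in FLAG_NAMES:
        frame[flag] = np.where(flags[flag].to_numpy(), "+", "")
    prefix = {"raw": "Intensity ", "lfq": "LFQ intensity ", "ibaq": "iBAQ "}
    for flavor, mat in flavors.items():
        linear = np.where(missing, 0.0, np.power(2.0, mat))
        for j, sample in enumerate(samples):
            frame[prefix[flavor] + sample] = linear[:, j]

    truth = GroundTruth(
        log2=log2_truth,
        missing_mask=pd.DataFrame(missing, index=proteins, columns=samples),
        flags=flags,
        planted_proteins=[proteins[i] for i in planted],
        sample_shifts=shifts,
        spec=spec,
    )
    if path is not None:
        write_fixture(frame, truth, Path(path))
    return frame, truth


def write_fixture(frame: pd.DataFrame, truth: GroundTruth, path: Path) -> None:
    """Write the table (tab-separated) and its ground truth alongside."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
    truth_dir = path.with_suffix("")
    truth.log2["raw"].to_csv(str(truth_dir) + ".truth_log2_raw.csv")
    truth.missing_mask.to_csv(str(truth_dir) + ".truth_missing.csv")
    pd.Series(truth.planted_proteins, name="protein").to_csv(
        str(truth_dir) + ".truth_planted.csv", index=False
    )
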