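"""Import of MaxQuant ``proteinGroups.txt``-style tables.

The protein-group table is the per-protein summary that MaxQuant writes after
feature detection and quantification: one row per protein group, per-sample
intensity columns in up to three flavors (raw ``Intensity <sample>``,
cross-sample-normalized ``LFQ intensity <sample>`` and abundance-scaled
``iBAQ <sample>``) and quality-flag columns marking decoy hits,
site-only identifications and potential contaminants.

This module reads such tables, removes flagged rows, and converts the
result into an :class:`IntensityTable` — a proteins × samples matrix of
log2 intensities in which a raw intensity of 0 ("not detected") becomes a
missing value.  All downstream statistics operate on this container.

Other input formats can be supported by implementing :class:`BaseReader`.
"""

from __future__ import annotations

import warnings
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError

#: Column prefix per intensity flavor.  The prefix is stripped to obtain the
#: sample name, e.g. "LFQ intensity A_t1_r1" -> "A_t1_r1".
FLAVOR_PREFIXES: dict[str, str] = {
    "raw": "Intensity ",
    "lfq": "LFQ intensity ",
    "ibaq": "iBAQ ",
}

#: MaxQuant quality-flag columns; a "+" marks a row for removal.
FLAG_COLUMNS: tuple[str, ...] = (
    "Only identified by site",
    "Reverse",
    "Potential contaminant",
)

GENE_NAME_COLUMN = "Gene names"
FALLBACK_ID_COLUMNS = ("Majority protein IDs", "Protein IDs")


@dataclass
class RawTable:
    """A validated protein-group table with one intensity flavor resolved.

    ``frame`` holds all original columns; ``intensity_columns`` are the
    columns of the requested flavor, in file order, and ``sample_names`` the
    corresponding names with the flavor prefix stripped.
    """

    frame: pd.DataFrame
    flavor: str
    intensity_columns: list[str]
    sample_names: list[str]
    source_path: Path | None = None

    def __len__(self) -> int:  # number of protein-group rows
        return len(self.frame)


@dataclass
class IntensityTable:
    """Proteins × samples matrix of log2 intensities with missing values.

    ``values`` uses NaN for missing entries (raw intensity 0, i.e. the
    protein was not detected in that sample); every non-missing entry is a
    finite log2 intensity.  The index holds unique protein identifiers
    (gene symbols after aggregation), the columns hold sample names.
    """

    values: pd.DataFrame
    flavor: str = "raw"

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def detection_counts(self, samples: list[str] | None = None) -> pd.Series:
        """Number of samples each protein is detected in (restricted to
        ``samples`` if given)."""
        sub = self.values if samples is None else self.values[list(samples)]
        return sub.notna().sum(axis=1)

    def copy(self) -> "IntensityTable":
        return IntensityTable(self.values.copy(), self.flavor)


class BaseReader(ABC):
    """Interface a data source must provide to feed the pipeline.

    Implementing these three operations for a new search-engine output is
    all that is required to plug another format into the pipeline; the rest
    of the package only ever sees :class:`RawTable` / :class:`IntensityTable`.
    """

    @abstractmethod
    def list_samples(self, flavor: str) -> list[str]:
        """Sample names available for the given intensity flavor."""

    @abstractmethod
    def fetch_matrix(self, flavor: str) -> pd.DataFrame:
        """Raw (linear-scale) intensities, proteins × samples; 0 = not
        detected."""

    @abstractmethod
    def fetch_flags(self) -> pd.DataFrame:
        """Boolean frame, one column per quality flag; True = row flagged."""


class MaxQuantReader(BaseReader):
    """Reader over an in-memory MaxQuant protein-group frame."""

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame

    def list_samples(self, flavor: str) -> list[str]:
        prefix = _flavor_prefix(flavor)
        return [c[len(prefix):] for c in self.frame.columns if c.startswith(prefix)]

    def fetch_matrix(self, flavor: str) -> pd.DataFrame:
        prefix = _flavor_prefix(flavor)
        cols = [c for c in self.frame.columns if c.startswith(prefix)]
        mat = self.frame[cols].copy()
        mat.columns = [c[len(prefix):] for c in cols]
        return mat

    def fetch_flags(self) -> pd.DataFrame:
        out = {}
        for col in FLAG_COLUMNS:
            if col in self.frame.columns:
                out[col] = self.frame[col].fillna("").astype(str).str.strip() == "+"
            else:
                out[col] = pd.Series(False, index=self.frame.index)
        return pd.DataFrame(out)


def _flavor_prefix(flavor: str) -> str:
    try:
        return FLAVOR_PREFIXES[flavor]
    except KeyError:
        raise FormatError(
            f"unknown intensity flavor {flavor!r}; expected one of "
            f"{sorted(FLAVOR_PREFIXES)}"
        ) from None


def read_protein_groups(path: str | Path, flavor: str = "raw") -> RawTable:
    """Read a tab-separated protein-group table and resolve one flavor.

    Parameters
    ----------
    path:
        Tab-separated file with a header row (MaxQuant ``proteinGroups.txt``
        dialect).
    flavor:
        Which intensity columns to use: ``raw``, ``lfq`` or ``ibaq``.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    FormatError
        If no column carries the flavor's prefix.
    ParseError
        If an intensity cell is non-numeric, negative or non-finite; the
        message names the offending row and column.
    """
    path = Path(path)
    prefix = _flavor_prefix(flavor)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    intensity_columns = [c for c in frame.columns if c.startswith(prefix)]
    if not intensity_columns:
        raise FormatError(
            f"no intensity column with prefix {prefix!r} found in {path}; "
            f"cannot use flavor {flavor!r}"
        )
    for col in intensity_columns:
        parsed = pd.to_numeric(frame[col].replace("", np.nan), errors="coerce")
        bad = parsed.isna() | ~np.isfinite(parsed) | (parsed < 0)
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(
                f"cannot parse intensity cell at row {row}, column {col!r}: "
                f"{frame.at[row, col]!r} (expected a non-negative finite number)"
            )
        frame[col] = parsed.astype(float)
    sample_names = [c[len(prefix):] for c in intensity_columns]
    return RawTable(
        frame=frame,
        flavor=flavor,
        intensity_columns=intensity_columns,
        sample_names=sample_names,
        source_path=path,
    )


def filter_protein_groups(table: RawTable) -> RawTable:
    """Drop rows flagged "+" in any MaxQuant quality-flag column.

    Removes decoy hits ("Reverse"), site-only identifications and potential
    contaminants.  Flag columns that are absent are treated as all-unflagged
    with a warning, so minimal tables remain readable.  Row order is
    preserved; filtering is idempotent.
    """
    keep = pd.Series(True, index=table.frame.index)
    for col in FLAG_COLUMNS:
        if col not in table.frame.columns:
            warnings.warn(
                f"flag column {col!r} absent; treating all rows as unflagged",
                stacklevel=2,
            )
            continue
        flagged = table.frame[col].fillna("").astype(str).str.strip() == "+"
        keep &= ~flagged
    return RawTable(
        frame=table.frame[keep].reset_index(drop=True),
        flavor=table.flavor,
        intensity_columns=list(table.intensity_columns),
        sample_names=list(table.sample_names),
        source_path=table.source_path,
    )


def _protein_identifier(row: pd.Series) -> str:
    gene = str(row.get(GENE_NAME_COLUMN, "") or "").strip()
    if gene:
        return gene.split(";")[0].strip()
    for col in FALLBACK_ID_COLUMNS:
        val = str(row.get(col, "") or "").strip()
        if val:
            return val.split(";")[0].strip()
    return f"row{row.name}"


def to_intensity_table(table: RawTable) -> IntensityTable:
    """Convert a (filtered) :class:`RawTable` into log2 intensities.

    Raw intensities of 0 become missing values; positive intensities become
    log2(intensity).  Rows sharing a protein identifier (first gene symbol;
    majority-protein ID where the gene name is empty) are aggregated by
    summing their raw intensities before the log transform, so identifiers
    are unique afterwards.
    """
    if not table.sample_names:
        raise FormatError("table has no samples for the requested flavor")
    raw = table.frame[table.intensity_columns].astype(float)
    raw.columns = table.sample_names
    ids = table.frame.apply(_protein_identifier, axis=1)
    # keep first-appearance order of identifiers through the groupby
    order = ids.drop_duplicates().tolist()
    summed = raw.groupby(ids, sort=False).sum().reindex(order)
    values = summed.where(summed > 0, np.nan)
    values = np.log2(values)
    values.index.name = "protein"
    return IntensityTable(values=values, flavor=table.flavor)


def load_intensity_table(path: str | Path, flavor: str = "raw") -> IntensityTable:
    """Read, filter and log2-transform in one step."""
    return to_intensity_table(filter_protein_groups(read_protein_groups(path, flavor)))
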