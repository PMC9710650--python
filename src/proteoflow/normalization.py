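"""Normalization strategies for log2 intensity matrices.

Five strategies (plus "none") correct systematic between-sample intensity
shifts while leaving missing values untouched:

* ``median_norm`` — shift each sample so all sample medians coincide at
  the grand mean of the medians.
* ``quantile_norm_missing_handled`` — classic quantile normalization
  (every sample receives the cross-sample mean distribution); missing
  cells are temporarily filled by resampling from the sample's own
  observed intensities, then restored to missing afterwards.
* ``trqn`` / ``trqn_missing_handled`` — tail-robust quantile
  normalization: each sample is mean-centered first, quantile
  normalization is applied to the centered values, and the sample mean is
  added back.  Centering protects the distribution tails from being
  flattened onto a common reference.
* ``trmn`` — the same offset construction around median normalization.

All operations act on the log2 scale (shifts are subtractions) and
preserve the missing-value mask bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, NormalizationError
from .io_maxquant import IntensityTable

#: Accepted method names for :func:`apply_normalization`.
METHODS = (
    "none",
    "median_norm",
    "quantile_norm_missing_handled",
    "trqn",
    "trqn_missing_handled",
    "trmn",
)


@dataclass(frozen=True)
class NormalizationSpec:
    method: str = "none"
    rng_seed: int = 0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ConfigError(
                f"unknown normalization method {self.method!r}; "
                f"expected one of {METHODS}"
            )


def _check_columns_observed(values: pd.DataFrame) -> None:
    empty = [c for c in values.columns if values[c].notna().sum() == 0]
    if empty:
        raise NormalizationError(
            f"sample(s) with no observed values cannot be normalized: {empty}"
        )


def median_norm(table: IntensityTable) -> IntensityTable:
    """Equalize sample medians at the grand mean of the sample medians.

    For sample j with median m_j and mean-of-medians m̄, every observed
    intensity x becomes x − (m_j − m̄).
    """
    values = table.values
    _check_columns_observed(values)
    medians = values.median(axis=0, skipna=True)
    correction = medians - medians.mean()
    return IntensityTable(values.sub(correction, axis=1), table.flavor)


def _assign_quantile_means(column: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Replace each value by the reference value of its rank; ties receive
    the mean of the reference values over the tied rank span."""
    order = np.argsort(column, kind="mergesort")
    sorted_vals = column[order]
    out = np.empty_like(column)
    n = len(column)
    i = 0
    while i < n:
        j = i + 1
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        out[order[i:j]] = reference[i:j].mean()
        i = j
    return out


def quantile_norm(
    table: IntensityTable, handle_missing: bool = False, seed: int | None = None
) -> IntensityTable:
    """Quantile normalization with optional missing-value handling.

    Without missing handling the matrix must be complete (an incomplete
    matrix raises :class:`NormalizationError` rather than silently
    dropping rows).  With it, each sample's missing cells are filled by
    sampling with replacement from that sample's observed intensities
    (seeded), the complete matrix is normalized, and the filled cells are
    set back to missing — so the output mask equals the input mask.
    """
    values = table.values
    _check_columns_observed(values)
    mask = values.isna().to_numpy()
    if mask.any() and not handle_missing:
        raise NormalizationError(
            "matrix contains missing values; quantile normalization without "
            "missing-value handling requires complete data"
        )
    filled = values.to_numpy(dtype=float, copy=True)
    if handle_missing and mask.any():
        rng = np.random.default_rng(seed)
        for j in range(filled.shape[1]):
            miss = mask[:, j]
            if miss.any():
                observed = filled[~miss, j]
                filled[miss, j] = rng.choice(observed, size=int(miss.sum()), replace=True)
    reference = np.sort(filled, axis=0).mean(axis=1)
    out = np.column_stack(
        [_assign_quantile_means(filled[:, j], reference) for j in range(filled.shape[1])]
    )
    out[mask] = np.nan
    return IntensityTable(
        pd.DataFrame(out, index=values.index, columns=values.columns), table.flavor
    )


def trqn(
    table: IntensityTable, handle_missing: bool = False, seed: int | None = None
) -> IntensityTable:
    """Tail-robust quantile normalization: mean-center each sample,
    quantile-normalize, add the sample means back."""
    values = table.values
    _check_columns_observed(values)
    offsets = values.mean(axis=0, skipna=True)
    centered = IntensityTable(values.sub(offsets, axis=1), table.flavor)
    normalized = quantile_norm(centered, handle_missing=handle_missing, seed=seed)
    return IntensityTable(normalized.values.add(offsets, axis=1), table.flavor)


def trmn(table: IntensityTable) -> IntensityTable:
    """Tail-robust median normalization: mean-center each sample,
    median-normalize, add the sample means back."""
    values = table.values
    _check_columns_observed(values)
    offsets = values.mean(axis=0, skipna=True)
    centered = IntensityTable(values.sub(offsets, axis=1), table.flavor)
    normalized = median_norm(centered)
    return IntensityTable(normalized.values.add(offsets, axis=1), table.flavor)


def apply_normalization(table: IntensityTable, spec: NormalizationSpec) -> IntensityTable:
    """Dispatch on ``spec.method``; ``none`` returns the input unchanged."""
    if spec.method == "none":
        return table.copy()
    if spec.method == "median_norm":
        return median_norm(table)
    if spec.method == "quantile_norm_missing_handled":
        return quantile_norm(table, handle_missing=True, seed=spec.rng_seed)
    if spec.method == "trqn":
        return trqn(table, handle_missing=False)
    if spec.method == "trqn_missing_handled":
        return trqn(table, handle_missing=True, seed=spec.rng_seed)
    if spec.method == "trmn":
        return trmn(table)
    raise ConfigError(f"unknown normalization method {spec.method!r}")
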