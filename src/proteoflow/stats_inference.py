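"""Statistical kernels: t-tests, empirical-Bayes moderation, FDR, Fisher.

The differential-analysis statistic is a moderated two-sample t-test:
per-protein residual variances s_g² (d_g degrees of freedom) are shrunk
toward a prior s0² with d0 prior degrees of freedom,

    s̃_g² = (d0·s0² + d_g·s_g²) / (d0 + d_g),

and the t-statistic uses s̃_g² with d0 + d_g degrees of freedom.  (d0, s0²)
are estimated by the method of moments on log s_g², treating log s_g² as a
scaled log-F deviate.  With ``trend=True`` the constant prior is replaced
by a smooth function of average log2 intensity (a lowess fit), which
corrects for the intensity–variance relationship typical of MS data.

Enrichment of protein sets uses the one-tailed Fisher exact test
(hypergeometric upper tail); multiple testing is controlled with the
Benjamini–Hochberg step-up procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, ProteoflowError

_TINY_P = float(np.nextafter(0.0, 1.0))


def independent_t_test(a, b) -> tuple[float, float, int]:
    """Two-sided two-sample t-test with pooled variance.

    Missing values are dropped; each group needs at least two observations,
    otherwise :class:`InsufficientDataError` is raised so the caller can
    skip the protein.  Returns ``(t, p, df)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError(
            f"need >= 2 observations per group, got {len(a)} and {len(b)}"
        )
    df = len(a) + len(b) - 2
    pooled = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0, 1.0, df
        return math.copysign(math.inf, diff), _TINY_P, df
    t = diff / math.sqrt(pooled * (1.0 / len(a) + 1.0 / len(b)))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(max(p, _TINY_P), 1.0)), df


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (same order as input)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class EnrichmentTable:
    """2×2 protein counts for a one-tailed enrichment test.

    Rows: protein in the term / not in the term; columns: detected / not
    detected.  All counts refer to the measured background.
    """

    in_term_detected: int
    in_term_missed: int
    background_detected: int
    background_missed: int

    def __post_init__(self):
        counts = (
            self.in_term_detected,
            self.in_term_missed,
            self.background_detected,
            self.background_missed,
        )
        if any(c < 0 for c in counts):
            raise ValueError(f"counts must be non-negative, got {counts}")


def fisher_one_tailed(table: EnrichmentTable) -> float:
    """Upper-tail (enrichment) Fisher exact p-value.

    The probability, under the hypergeometric null, of seeing at least the
    observed number of detected in-term proteins.
    """
    a = table.in_term_detected
    total = (
        a + table.in_term_missed + table.background_detected + table.background_missed
    )
    in_term = a + table.in_term_missed
    detected = a + table.background_detected
    if total == 0:
        return 1.0
    return float(min(stats.hypergeom.sf(a - 1, total, in_term, detected), 1.0))


def pearson_r2(x, y) -> float:
    """Squared Pearson correlation on pairwise-complete observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 2:
        raise InsufficientDataError("need >= 2 pairwise-complete observations")
    if x.std() == 0.0 or y.std() == 0.0:
        raise InsufficientDataError("correlation undefined: zero variance")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _trigamma_inverse(x: float) -> float:
    # Newton iteration for y with trigamma(y) = x.
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(60):
        tri = float(special.polygamma(1, y))
        step = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += step
        if -step / y < 1e-10:
            break
    return y


@dataclass
class ModeratedFit:
    """Result of the empirical-Bayes moderated t-test for one comparison.

    All per-protein quantities are aligned with ``index``; ``prior_df`` is
    the shared d0 (may be ``inf``) and ``prior_var`` the per-protein prior
    variance s0² (constant unless a trend was fit).
    """

    index: pd.Index
    mean_a: np.ndarray
    mean_b: np.ndarray
    log2_fc: np.ndarray
    average_intensity: np.ndarray
    residual_var: np.ndarray
    residual_df: np.ndarray
    prior_df: float
    prior_var: np.ndarray
    posterior_var: np.ndarray
    t: np.ndarray
    p_value: np.ndarray
    total_df: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_A": self.mean_a,
                "mean_B": self.mean_b,
                "log2_fc": self.log2_fc,
                "average_intensity": self.average_intensity,
                "residual_var": self.residual_var,
                "residual_df": self.residual_df,
                "prior_var": self.prior_var,
                "posterior_var": self.posterior_var,
                "t": self.t,
                "p_value": self.p_value,
                "total_df": self.total_df,
            },
            index=self.index,
        )


def moderated_t_fit(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    trend: bool = True,
    prior_df: float | None = None,
) -> ModeratedFit:
    """Fit the moderated two-sample t-test across proteins.

    ``group_a`` and ``group_b`` are proteins × samples slices of log2
    intensities (NaN = missing) with identical indexes; every protein must
    retain >= 2 observations per group.  The fold change is mean(A) −
    mean(B).  ``prior_df`` overrides the estimated d0 (0 recovers the
    ordinary t-test; ``inf`` uses the prior variance alone).
    """
    if not group_a.index.equals(group_b.index):
        raise ValueError("group slices must share the same protein index")
    a = group_a.to_numpy(dtype=float)
    b = group_b.to_numpy(dtype=float)
    n_a = np.isfinite(a).sum(axis=1)
    n_b = np.isfinite(b).sum(axis=1)
    if np.any(n_a < 2) or np.any(n_b < 2):
        bad = group_a.index[(n_a < 2) | (n_b < 2)]
        raise InsufficientDataError(
            f"{len(bad)} protein(s) with < 2 observations in a group; "
            f"filter before fitting (e.g. {list(bad[:5])})"
        )
    mean_a = np.nanmean(a, axis=1)
    mean_b = np.nanmean(b, axis=1)
    log2_fc = mean_a - mean_b
    abar = np.nanmean(np.concatenate([a, b], axis=1), axis=1)
    ss = np.nansum((a - mean_a[:, None]) ** 2, axis=1) + np.nansum(
        (b - mean_b[:, None]) ** 2, axis=1
    )
    d_g = (n_a + n_b - 2).astype(float)
    if np.all(d_g <= 0):
        raise ProteoflowError("no protein has positive residual degrees of freedom")
    s2 = ss / d_g

    d0, s0 = _estimate_prior(s2, d_g, abar, trend)
    if prior_df is not None:
        d0 = float(prior_df)

    if math.isinf(d0):
        post = s0.copy()
        total_df = np.full_like(d_g, np.inf)
    elif d0 == 0.0:
        post = s2.copy()
        total_df = d_g.copy()
    else:
        post = (d0 * s0 + d_g * s2) / (d0 + d_g)
        total_df = d0 + d_g
    se = np.sqrt(post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2_fc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), total_df)
    p = np.clip(p, _TINY_P, 1.0)
    return ModeratedFit(
        index=group_a.index,
        mean_a=mean_a,
        mean_b=mean_b,
        log2_fc=log2_fc,
        average_intensity=abar,
        residual_var=s2,
        residual_df=d_g,
        prior_df=d0,
        prior_var=s0,
        posterior_var=post,
        t=t,
        p_value=p,
        total_df=total_df,
    )


def _estimate_prior(
    s2: np.ndarray, d_g: np.ndarray, abar: np.ndarray, trend: bool
) -> tuple[float, np.ndarray]:
    """Method-of-moments fit of (d0, s0²) on log residual variances.

    log s_g² is (up to known digamma/trigamma offsets) a location-shifted
    log-F variate; matching its mean and excess variance yields d0 and the
    prior.  With ``trend`` the location is a lowess fit on average
    intensity instead of a constant.
    """
    ok = np.isfinite(s2) & (s2 > 0) & (d_g > 0)
    if ok.sum() < 2:
        # too few informative proteins for a prior: no moderation
        return 0.0, np.where(ok, s2, np.nan)
    z = np.log(s2[ok])
    e = z - special.digamma(d_g[ok] / 2.0) + np.log(d_g[ok] / 2.0)
    if trend and ok.sum() >= 10 and np.unique(abar[ok]).size >= 5:
        fitted = lowess(e, abar[ok], frac=0.3, it=3, return_sorted=False)
        # extend to all proteins by interpolation over average intensity
        order = np.argsort(abar[ok], kind="mergesort")
        e0_all = np.interp(abar, abar[ok][order], fitted[order])
        e0 = fitted
    else:
        e0 = np.full(ok.sum(), e.mean())
        e0_all = np.full_like(abar, e.mean())
    resid = e - e0
    evar = resid.var(ddof=1) - float(np.mean(special.polygamma(1, d_g[ok] / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_all = np.exp(e0_all + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_all = np.exp(e0_all)
    return float(d0), s0_all
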