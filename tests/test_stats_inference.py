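import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from proteoflow import stats_inference as si
from proteoflow.errors import InsufficientDataError


def hand_pooled_t(a, b):
    """Closed-form pooled-variance two-sample t, evaluated independently."""
    na, nb = len(a), len(b)
    sp2 = (sum((x - np.mean(a)) ** 2 for x in a) + sum((x - np.mean(b)) ** 2 for x in b)) / (
        na + nb - 2
    )
    return (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))


def brute_force_fisher_upper(a, b, c, d):
    """Exact hypergeometric upper tail by enumerating the support with
    integer binomial coefficients."""
    total, in_term, detected = a + b + c + d, a + b, a + c
    denom = math.comb(total, detected)
    if denom == 0:
        return 1.0
    num = sum(
        math.comb(in_term, k) * math.comb(total - in_term, detected - k)
        for k in range(a, min(in_term, detected) + 1)
    )
    return num / denom


class TestIndependentT:
    def test_identical_groups_give_t0_p1(self):
        t, p, df = si.independent_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0 and df == 4

    def test_matches_hand_computed_pooled_formula(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        t, p, df = si.independent_t_test(a, b)
        assert t == pytest.approx(hand_pooled_t(a, b), abs=1e-12)
        from scipy import stats
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 4), abs=1e-12)

    def test_single_observation_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            si.independent_t_test([1.0], [1.0, 2.0])

    def test_missing_values_are_dropped_first(self):
        t1 = si.independent_t_test([1, 2, np.nan], [4, 5, 6])
        t2 = si.independent_t_test([1, 2], [4, 5, 6])
        assert t1 == t2


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            si.benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_and_constant_vectors_unchanged(self):
        assert si.benjamini_hochberg([0.2]).tolist() == [0.2]
        np.testing.assert_allclose(si.benjamini_hochberg([0.1] * 4), [0.1] * 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            si.benjamini_hochberg([0.5, 1.5])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_at_most_one(self, p):
        adj = si.benjamini_hochberg(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)
        # step-up envelope: sorting by p sorts adjusted monotonically
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestFisher:
    def test_two_of_four_worked_example(self):
        # drawing 2 of 4 with 2 successes: P(both in term) = 1/6
        p = si.fisher_one_tailed(si.EnrichmentTable(2, 0, 0, 2))
        assert p == pytest.approx(1 / 6, abs=1e-12)

    def test_zero_detected_in_term_gives_p1(self):
        p = si.fisher_one_tailed(si.EnrichmentTable(0, 3, 5, 2))
        assert p == pytest.approx(1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            si.EnrichmentTable(-1, 0, 0, 0)

    def test_matches_enumeration_on_sampled_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 8, size=4)
            p = si.fisher_one_tailed(si.EnrichmentTable(int(a), int(b), int(c), int(d)))
            assert p == pytest.approx(brute_force_fisher_upper(a, b, c, d), abs=1e-12)


class TestPearson:
    def test_perfect_lines_give_one(self):
        x = np.arange(5.0)
        assert si.pearson_r2(x, x) == pytest.approx(1.0)
        assert si.pearson_r2(x, -x) == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=30), rng.normal(size=30)
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        expected = sxy**2 / (((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert si.pearson_r2(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_is_undefined(self):
        with pytest.raises(InsufficientDataError):
            si.pearson_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def simulate_groups(n_proteins, n_a, n_b, sigma=0.3, seed=0, shift=None):
    rng = np.random.default_rng(seed)
    base = rng.normal(25, 2, size=n_proteins)
    a = base[:, None] + rng.normal(0, sigma, size=(n_proteins, n_a))
    b = base[:, None] + rng.normal(0, sigma, size=(n_proteins, n_b))
    if shift is not None:
        a[shift] += 1.0
    idx = pd.Index([f"p{i}" for i in range(n_proteins)])
    return (
        pd.DataFrame(a, index=idx),
        pd.DataFrame(b, index=idx),
    )


class TestModeratedT:
    def test_zero_prior_df_recovers_ordinary_t(self):
        a, b = simulate_groups(100, 4, 4, seed=3)
        fit = si.moderated_t_fit(a, b, trend=True, prior_df=0.0)
        for i in range(100):
            t_ref, _, _ = si.independent_t_test(a.iloc[i], b.iloc[i])
            assert fit.t[i] == pytest.approx(t_ref, abs=1e-9)

    def test_infinite_prior_df_uses_prior_variance_only(self):
        a, b = simulate_groups(100, 4, 4, seed=4)
        fit = si.moderated_t_fit(a, b, trend=False, prior_df=math.inf)
        np.testing.assert_allclose(fit.posterior_var, fit.prior_var, rtol=1e-12)

    def test_posterior_variance_between_prior_and_residual(self):
        a, b = simulate_groups(200, 4, 4, seed=5)
        fit = si.moderated_t_fit(a, b, trend=False)
        lo = np.minimum(fit.prior_var, fit.residual_var)
        hi = np.maximum(fit.prior_var, fit.residual_var)
        assert np.all(fit.posterior_var >= lo - 1e-12)
        assert np.all(fit.posterior_var <= hi + 1e-12)
        assert np.all((fit.p_value > 0) & (fit.p_value <= 1))

    def test_type_i_error_near_nominal_on_null_data(self):
        a, b = simulate_groups(500, 4, 4, seed=6)
        fit = si.moderated_t_fit(a, b, trend=True)
        rate = float(np.mean(fit.p_value < 0.05))
        half_width = 2.576 * math.sqrt(0.05 * 0.95 / 500)
        assert abs(rate - 0.05) < half_width

    def test_insufficient_observations_rejected(self):
        a, b = simulate_groups(10, 4, 4, seed=7)
        a.iloc[0, 1:] = np.nan
        with pytest.raises(InsufficientDataError):
            si.moderated_t_fit(a, b)

    def test_planted_effects_rank_top(self):
        shift = np.arange(0, 50)  # 50 of 500 proteins shifted by 1 log2 unit
        a, b = simulate_groups(500, 4, 4, seed=8, shift=shift)
        fit = si.moderated_t_fit(a, b, trend=True)
        adj = si.benjamini_hochberg(fit.p_value)
        labels = np.zeros(500, dtype=bool)
        labels[shift] = True
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(labels, -adj) > 0.95
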