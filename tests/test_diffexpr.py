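import numpy as np
import pandas as pd
import pytest
from scipy import stats

from awasig import (
    CohortSpec,
    ExpressionMatrix,
    estimate_de_fraction,
    generate_null_cohort,
    pvalue_histogram,
    sam_permutation,
    storey_qvalue,
    t_from_summary,
    welch_t,
)
from awasig.diffexpr import Pi0Estimate, _d_statistic, two_group_t


def _em(arr):
    arr = np.asarray(arr, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(arr, index=[f"p{i:03d}" for i in range(arr.shape[0])],
                     columns=[f"s{i}" for i in range(arr.shape[1])])
    )


class TestWelchT:
    def test_matches_scipy_oracle(self):
        g1, g0 = [2.0, 2.2, 1.8], [1.0, 1.2, 0.8]
        res = welch_t(_em([g1 + g0]), [1, 1, 1, 0, 0, 0])
        t_ref, p_ref = stats.ttest_ind(g1, g0, equal_var=False)
        assert res.table["t"].iloc[0] == pytest.approx(t_ref)
        assert res.table["p"].iloc[0] == pytest.approx(p_ref)
        assert res.table["log2_fc"].iloc[0] == pytest.approx(1.0)

    def test_pooled_matches_scipy_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(5, 9))
        labels = np.array([1] * 4 + [0] * 5)
        res = welch_t(_em(x), labels, equal_var=True)
        t_ref, p_ref = stats.ttest_ind(x[:, :4], x[:, 4:], axis=1, equal_var=True)
        np.testing.assert_allclose(res.table["t"], t_ref)
        np.testing.assert_allclose(res.table["p"], p_ref)

    def test_identical_groups_give_t0_p1_fc0(self):
        res = welch_t(_em([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]]), [1, 1, 1, 0, 0, 0])
        assert res.table["t"].iloc[0] == pytest.approx(0.0)
        assert res.table["p"].iloc[0] == pytest.approx(1.0)
        assert res.table["log2_fc"].iloc[0] == pytest.approx(0.0)

    def test_zero_variance_probe_flagged_not_nan(self):
        res = welch_t(_em([[1.0, 1.0, 2.0, 2.0]]), [1, 1, 0, 0])
        assert bool(res.table["zero_variance"].iloc[0])
        assert np.isfinite(res.table["p"].iloc[0])

    def test_constant_shift_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4, 10))
        labels = np.array([1] * 5 + [0] * 5)
        a = welch_t(_em(x), labels).table
        b = welch_t(_em(x + 7.5), labels).table
        np.testing.assert_allclose(a["t"], b["t"], atol=1e-8)
        np.testing.assert_allclose(a["log2_fc"], b["log2_fc"], atol=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            welch_t(_em([[1.0, 2.0, 3.0]]), [1, 0, 0])


class TestTFromSummary:
    def test_framingham_row_highly_significant(self):
        _, p = t_from_summary(5.8, 4.5, 48, 2.6, 2.9, 71)
        assert p < 0.001

    def test_bmi_row_matches_printed_value(self):
        _, p = t_from_summary(28.2, 6.0, 48, 27.2, 5.8, 71)
        assert p == pytest.approx(0.38, abs=0.02)

    def test_equal_means(self):
        t, p = t_from_summary(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert t == 0.0 and p == 1.0

    def test_degenerate_sds_rejected(self):
        with pytest.raises(ValueError):
            t_from_summary(1.0, 0.0, 5, 2.0, 0.0, 5)


def _bh_bruteforce(p):
    """Independent step-up Benjamini-Hochberg oracle (quadratic, tiny n)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            m * p[order[j - 1]] / j for j in range(rank_pos, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestStoreyQvalue:
    def test_equals_bh_when_pi0_forced_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(1, 21)
            p = np.round(rng.uniform(size=n), 3)
            q, _ = storey_qvalue(p, pi0=1.0)
            np.testing.assert_allclose(q, _bh_bruteforce(p), atol=1e-12)

    def test_hand_computed_bh_example(self):
        p = np.array([0.001, 0.01, 0.2, 0.5, 0.9])
        q, _ = storey_qvalue(p, pi0=1.0)
        np.testing.assert_allclose(q, [0.005, 0.025, 1 / 3, 0.625, 0.9])

    def test_pi0_near_one_on_uniform(self):
        rng = np.random.default_rng(1)
        _, est = storey_qvalue(rng.uniform(size=10_000))
        assert 0.95 <= est.pi0 <= 1.05 or est.pi0 == 1.0
        assert est.method == "spline"

    def test_all_ones(self):
        q, _ = storey_qvalue(np.ones(20))
        np.testing.assert_array_equal(q, 1.0)

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(4)
        p = np.concatenate([rng.uniform(0, 0.01, 50), rng.uniform(size=500)])
        q, _ = storey_qvalue(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= 0).all() and (q <= 1).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalue([0.5, 1.5])

    def test_short_vector_uses_fixed_lambda(self):
        _, est = storey_qvalue([0.2, 0.4, 0.6, 0.9])
        assert est.method == "fixed_lambda"

    def test_de_fraction(self):
        assert estimate_de_fraction(Pi0Estimate(0.8, np.array([0.5]),
                                                np.array([0.8]), "fixed")) == pytest.approx(0.20)
        assert estimate_de_fraction(Pi0Estimate(1.0, np.array([0.5]),
                                                np.array([1.0]), "fixed")) == 0.0


class TestSamPermutation:
    def test_d_reduces_to_pooled_t_when_s0_zero(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(50, 20))
        labels = np.array([1] * 10 + [0] * 10)
        d = _d_statistic(x, labels, 0.0)
        t, _, _, _ = two_group_t(x, labels, equal_var=True)
        np.testing.assert_allclose(d, t, atol=1e-10)

    def test_null_data_yields_high_fdr_at_5pct_calls(self):
        matrix, ann, _ = generate_null_cohort(
            CohortSpec(n_probes=500, n_cases=20, n_controls=30), seed=5
        )
        res = sam_permutation(matrix, ann["case_status"].to_numpy(),
                              n_permutations=150, seed=5)
        tab = res.table
        row = tab.iloc[(tab["called"] - 25).abs().argmin()]
        assert row["fdr"] >= 0.8

    def test_planted_signal_recovered_at_fdr_20pct(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, (1000, 100))
        x[:100, 50:] += 2.0  # 10% of probes shifted by 2 SD
        labels = np.array([0] * 50 + [1] * 50)
        res = sam_permutation(_em(x), labels, n_permutations=150, seed=2)
        called = res.significant_probes(0.2)
        called_idx = np.array([int(c[1:]) for c in called])
        assert (called_idx < 100).sum() >= 70
        assert (called_idx >= 100).sum() <= 0.3 * len(called)

    def test_called_counts_monotone_in_cutoff(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(200, 30))
        labels = np.array([1] * 15 + [0] * 15)
        res = sam_permutation(_em(x), labels, n_permutations=120, seed=1)
        assert (np.diff(res.table["called"]) <= 0).all()
        assert (res.table["fdr"] >= 0).all()

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError):
            sam_permutation(_em(np.zeros((10, 4))), [0, 0, 0, 0], 100, 0)


class TestPvalueHistogram:
    def test_counts_conserved_and_uniform_bound(self):
        rng = np.random.default_rng(8)
        m = 4000
        hist = pvalue_histogram(rng.uniform(size=m), n_bins=20)
        assert hist["count"].sum() == m
        bound = 3 * np.sqrt(m / 20)
        assert (np.abs(hist["count"] - m / 20) < bound).all()

    def test_point_mass_in_first_bin(self):
        hist = pvalue_histogram(np.full(100, 0.001), n_bins=20)
        assert hist["count"].iloc[0] == 100

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pvalue_histogram([])
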