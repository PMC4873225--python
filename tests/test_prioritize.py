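"""Unit and property tests for the prioritization cascade statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markerval.prioritize import (
    PrioritizationConfig,
    adjust_pvalues,
    anova_f,
    combined_rank,
    km_curves,
    km_stratify,
    literature_filter,
    log2_fold_change,
    logrank_test,
    run_prioritization,
    sam_d,
    select_top_k,
    tissue_filter,
    two_group_tests,
)


def exact_mw_pvalue(a, b):
    """Exhaustive-enumeration oracle for the two-sided Mann-Whitney p.

    Enumerates every assignment of the pooled ranks to group A, computes
    the U null distribution, and doubles the smaller tail (clipped to 1).
    """
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    order = np.argsort(pooled)
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    u_obs = np.sum(ranks[:na]) - na * (na + 1) / 2
    us = [
        sum(ranks[list(comb)]) - na * (na + 1) / 2
        for comb in itertools.combinations(range(n), na)
    ]
    us = np.array(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(lo, hi))


class TestFoldChange:
    def test_powers_of_two(self):
        # linear means 8 vs 2 -> log2 FC = 2
        mat = pd.DataFrame({"a1": [3.0], "a2": [3.0], "b1": [1.0], "b2": [1.0]}, index=["g"])
        fc = log2_fold_change(mat, ["a1", "a2"], ["b1", "b2"])
        assert fc["g"] == pytest.approx(2.0)

    def test_equal_means_zero(self):
        mat = pd.DataFrame({"a": [5.0], "b": [5.0]}, index=["g"])
        assert log2_fold_change(mat, ["a"], ["b"])["g"] == pytest.approx(0.0)

    def test_zero_mean_with_pseudocount(self):
        mat = pd.DataFrame({"a": [0.0], "b": [3.0]}, index=["g"])
        fc = log2_fold_change(mat, ["a"], ["b"], pseudocount=1.0, input_scale="linear")
        assert fc["g"] == pytest.approx(-2.0)  # log2(1/4)

    def test_empty_group_raises(self):
        mat = pd.DataFrame({"a": [1.0]}, index=["g"])
        with pytest.raises(ValueError):
            log2_fold_change(mat, [], ["a"])


class TestTwoGroupTests:
    def test_exact_u_example(self):
        res = two_group_tests(np.array([1.2, 2.3]), np.array([3.1, 4.5, 5.0]))
        assert res.u == 0.0
        assert res.u_p == pytest.approx(0.2)  # 2/10 arrangements as extreme

    def test_identical_samples_symmetric(self):
        a = np.array([1.2, 2.3, 4.4])
        res = two_group_tests(a, a.copy())
        assert res.u == pytest.approx(len(a) ** 2 / 2)
        assert res.u_p == pytest.approx(1.0)

    def test_large_shift_all_significant(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, 20)
        b = rng.normal(10.0, 1.0, 20)  # 10 SD apart
        res = two_group_tests(b, a)
        assert res.t_p < 1e-6 and res.z_p < 1e-6 and res.u_p < 1e-6

    def test_degenerate_zero_variance(self):
        res = two_group_tests(np.array([2.0, 2.0]), np.array([2.0, 2.0]))
        assert res.degenerate and res.t_p == 1.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        na=st.integers(2, 6),
        nb=st.integers(2, 6),
        seed=st.integers(0, 10_000),
    )
    def test_exact_p_matches_enumeration(self, na, nb, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=na)
        b = rng.normal(size=nb)
        res = two_group_tests(a, b)
        assert res.u_p == pytest.approx(exact_mw_pvalue(a, b), abs=1e-12)


class TestAnova:
    def test_flat_groups(self, ):
        mat = pd.DataFrame([[1.0] * 6], index=["g"], columns=list("abcdef"))
        groups = pd.Series(list("NNTTMM"), index=list("abcdef"))
        res = anova_f(mat, groups)
        assert res.loc["g", "F"] == 0.0 and res.loc["g", "p"] == 1.0

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        vals = np.array([1, 1, 2, 2, 3, 3], dtype=float) + rng.normal(0, 1e-6, 6)
        mat = pd.DataFrame([vals], index=["g"], columns=list("abcdef"))
        groups = pd.Series(list("NNTTMM"), index=list("abcdef"))
        assert anova_f(mat, groups).loc["g", "p"] < 0.01

    def test_hand_computed_f(self):
        # groups [1,2], [1,2], [4,5]: SSB=12 (df 2), SSW=1.5 (df 3) -> F=12
        mat = pd.DataFrame([[1, 2, 1, 2, 4, 5]], index=["g"], columns=list("abcdef"), dtype=float)
        groups = pd.Series(list("NNTTMM"), index=list("abcdef"))
        assert anova_f(mat, groups).loc["g", "F"] == pytest.approx(12.0)

    def test_small_group_rejected(self):
        mat = pd.DataFrame([[1, 2, 3]], index=["g"], columns=list("abc"), dtype=float)
        groups = pd.Series(["N", "N", "T"], index=list("abc"))
        with pytest.raises(ValueError):
            anova_f(mat, groups)


class TestAdjustment:
    @pytest.mark.parametrize(
        "p,method,expected",
        [
            ([0.01] * 5, "bonferroni", [0.05] * 5),
            ([0.5] * 5, "bonferroni", [1.0] * 5),
            ([0.01, 0.02, 0.03, 0.04], "bh", [0.04] * 4),
        ],
    )
    def test_examples(self, p, method, expected):
        np.testing.assert_allclose(adjust_pvalues(p, method), expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_invariants(self, p):
        bonf = adjust_pvalues(p, "bonferroni")
        assert (bonf >= np.asarray(p) - 1e-15).all()
        q = adjust_pvalues(p, "bh")
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()  # monotone in sorted raw p

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([1.5], "bonferroni")


class TestSamD:
    def test_zero_pooled_ss(self):
        assert sam_d([1, 1], [3, 3], s0=1.0) == pytest.approx(-2.0)

    def test_identical_groups(self):
        assert sam_d([1.0, 2.0], [1.0, 2.0], s0=0.5) == 0.0

    def test_s0_shrinks_d_monotonically(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(1, 1, 5), rng.normal(0, 1, 5)
        ds = [abs(sam_d(a, b, s0)) for s0 in (0.0, 1.0, 10.0, 1000.0)]
        assert all(x > y for x, y in zip(ds, ds[1:]))
        assert ds[-1] < 1e-2


class TestRanking:
    def _de(self, n_sig, n_total=10):
        genes = [f"g{i:02d}" for i in range(n_total)]
        fc = np.linspace(3.0, 0.5, n_total)
        p = np.array([1e-6] * n_sig + [0.9] * (n_total - n_sig))
        return pd.DataFrame({"log2fc": fc, "p_bonf": p, "q_bh": p}, index=genes)

    def test_truncates_to_k(self):
        cfg = PrioritizationConfig(K=3)
        assert len(select_top_k(self._de(8), cfg)) == 3

    def test_short_list_not_padded(self):
        cfg = PrioritizationConfig(K=300)
        assert len(select_top_k(self._de(4), cfg)) == 4

    def test_fc_tie_breaks_lexicographically(self):
        de = pd.DataFrame(
            {"log2fc": [2.0, 2.0], "p_bonf": [1e-9, 1e-9], "q_bh": [1e-9, 1e-9]},
            index=["zz", "aa"],
        )
        assert select_top_k(de, PrioritizationConfig(K=2)) == ["aa", "zz"]

    def test_combined_rank_boost(self):
        tn = [f"g{i:02d}" for i in range(12)]
        ranked = combined_rank(tn, ["g09"], boost=5)
        assert ranked.at["g09", "score"] == 5  # rank 10 boosted to effective rank 5
        # ties with g04 (score 5); stable sort keeps the original-position gene first
        assert list(ranked.index).index("g09") == 5

    def test_no_overlap_identity(self):
        tn = ["a", "b", "c"]
        ranked = combined_rank(tn, ["x", "y"], boost=5)
        assert list(ranked.index) == tn

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            combined_rank(["a", "a"], [], boost=1)


class TestFilters:
    def test_tissue_specific_kept(self):
        scores = pd.DataFrame(
            {"prostate": [10.0], "lung": [1.0], "liver": [1.0]}, index=["g"]
        )
        assert tissue_filter(["g"], scores, 2.0).at["g", "passed"]

    def test_uniform_scores_removed_with_reason(self):
        scores = pd.DataFrame(
            {"prostate": [1.0], "lung": [1.0], "liver": [1.0]}, index=["g"]
        )
        out = tissue_filter(["g"], scores, 2.0)
        assert not out.at["g", "passed"] and out.at["g", "reason"] == "tissue"

    def test_boundary_ratio_inclusive(self):
        scores = pd.DataFrame(
            {"prostate": [6.0], "lung": [3.0], "liver": [3.0], "colon": [3.0]},
            index=["g"],
        )
        assert tissue_filter(["g"], scores, 2.0).at["g", "passed"]

    def test_missing_gene_is_per_gene_verdict(self):
        scores = pd.DataFrame({"prostate": [1.0], "lung": [1.0]}, index=["g"])
        out = tissue_filter(["g", "absent"], scores, 2.0)
        assert out.at["absent", "reason"] == "missing" and not out.at["absent", "passed"]

    def test_literature_boundary(self):
        counts = pd.Series({"g1": 0, "g2": 5, "g3": 6})
        out = literature_filter(["g1", "g2", "g3"], counts, citation_max=5)
        assert list(out[out["passed"]].index) == ["g1", "g2"]

    def test_literature_max_zero(self):
        counts = pd.Series({"g1": 0, "g2": 1})
        out = literature_filter(["g1", "g2"], counts, citation_max=0)
        assert list(out[out["passed"]].index) == ["g1"]

    def test_missing_count_treated_as_zero(self):
        out = literature_filter(["ghost"], pd.Series(dtype=int), citation_max=5)
        assert out.at["ghost", "passed"] and out.at["ghost", "count_missing"]

    def test_filters_idempotent(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(30)]
        scores = pd.DataFrame(
            rng.uniform(0.5, 5.0, size=(30, 4)),
            index=genes, columns=["prostate", "lung", "liver", "colon"],
        )
        counts = pd.Series(rng.integers(0, 12, 30), index=genes)
        kept = [g for g in genes if tissue_filter([g], scores, 2.0).at[g, "passed"]]
        kept = [g for g in kept if literature_filter([g], counts, 5).at[g, "passed"]]
        again_t = tissue_filter(kept, scores, 2.0)
        again_l = literature_filter(kept, counts, 5)
        assert again_t["passed"].all() and again_l["passed"].all()


class TestSurvival:
    def test_stratify_15_percent(self):
        values = pd.Series(np.arange(20, dtype=float))
        labels = km_stratify(values, 0.85)
        assert (labels == "high").sum() == 3
        assert set(labels[labels == "high"].index) == {17, 18, 19}

    def test_stratify_200(self):
        values = pd.Series(np.random.default_rng(0).normal(size=200))
        assert (km_stratify(values, 0.85) == "high").sum() == 30

    def test_all_equal_stable_order(self):
        values = pd.Series([1.0] * 10, index=[f"p{i}" for i in range(10)])
        labels = km_stratify(values, 0.85)
        assert list(labels[labels == "high"].index) == ["p0", "p1"]  # round(1.5)=2

    def test_km_no_events_flat(self):
        curve = km_curves([5, 6, 7], [False, False, False], ["g"] * 3)["g"]
        assert (curve["survival"] == 1.0).all()

    def test_km_product_limit_by_hand(self):
        curve = km_curves([1, 2], [True, True], ["g", "g"])["g"]
        s = dict(zip(curve["time"], curve["survival"]))
        assert s[1.0] == pytest.approx(0.5) and s[2.0] == pytest.approx(0.0)

    def test_km_censoring_does_not_drop_curve(self):
        cens = km_curves([1, 2, 5], [True, True, False], ["g"] * 3)["g"]
        s = dict(zip(cens["time"], cens["survival"]))
        assert s[5.0] == pytest.approx(s[2.0])  # censor after last event: no step

    def test_logrank_identical_groups(self):
        chi2, p = logrank_test([1, 2, 1, 2], [1, 1, 1, 1], ["A", "A", "B", "B"])
        # groups with identical event patterns: O=E at t=1; small residual at t=2
        assert p > 0.5

    def test_logrank_hand_computed(self):
        # A events at 1,2; B at 3,4: O_A=2, E_A=5/6, Var=17/36 -> chi2 = 2.882
        chi2, _ = logrank_test([1, 2, 3, 4], [1] * 4, ["A", "A", "B", "B"])
        assert chi2 == pytest.approx(2.8824, abs=1e-3)

    def test_logrank_label_permutation_invariant(self):
        t = [1, 3, 2, 8, 5, 4]
        e = [1, 1, 0, 1, 1, 1]
        g1 = ["A", "A", "A", "B", "B", "B"]
        g2 = ["B", "B", "B", "A", "A", "A"]
        assert logrank_test(t, e, g1)[0] == pytest.approx(logrank_test(t, e, g2)[0])


class TestCascade:
    def test_default_synthetic_recovers_planted(self, default_cohort):
        cohort, truth = default_cohort
        trace = run_prioritization(cohort, PrioritizationConfig())
        assert sorted(trace.final) == sorted(truth["planted"].index)

    def test_alpha_zero_empty(self, tiny_cohort):
        trace = run_prioritization(tiny_cohort, PrioritizationConfig(alpha=0.0))
        assert trace.final == []

    def test_missing_citations_names_stage(self, tiny_cohort):
        tiny_cohort.citations = None
        with pytest.raises(ValueError, match="literature"):
            run_prioritization(tiny_cohort, PrioritizationConfig())

    def test_every_removal_attributed_once(self, default_cohort):
        cohort, _ = default_cohort
        trace = run_prioritization(cohort, PrioritizationConfig())
        removed = trace.table[~trace.table["final"]]
        assert (removed["first_fail"] != "").all()
        assert (trace.table[trace.table["final"]]["first_fail"] == "").all()
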