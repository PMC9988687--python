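"""Leave-one-out cross-validation, ROC/AUC metrics and cohort summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gepbridge as gb
from conftest import paired_matrices


def brute_force_auc(scores, labels):
    """O(n²) pair-counting AUC oracle (ties count one half)."""
    scores, labels = np.asarray(scores), np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestLoocv:
    def test_noiseless_affine_out_of_fold_scores_match_original(
            self, noiseless_cohort, original_model):
        em, ct, _, _ = noiseless_cohort
        x_src, x_tgt = paired_matrices(em, ct, original_model)
        cv = gb.loocv(x_src, x_tgt, original_model)
        assert not cv.failed_folds
        np.testing.assert_allclose(cv.bridged_scores.to_numpy(),
                                   cv.original_scores.to_numpy(), atol=1e-8)

    def test_left_out_sample_cannot_leak(self):
        rng = np.random.default_rng(3)
        x_src = pd.DataFrame(rng.normal(10, 1, (12, 2)),
                             index=[f"s{i}" for i in range(12)],
                             columns=["A", "B"])
        x_tgt = x_src * 1.3 + rng.normal(0, 0.2, (12, 2))
        x_tgt.columns = ["a", "b"]
        model = gb.LinearClassifier(0.0, {"A": 1.0, "B": -1.0},
                                    "microarray-log2")
        cv = gb.loocv(x_src, x_tgt, model)
        # the fold that scores s0 must be blind to s0: perturbing only s0's
        # target values leaves that fold's inner coefficients unchanged
        # (s0's own score shifts purely through the scoring step)
        rest = x_src.index.drop("s0")
        x_tgt2 = x_tgt.copy()
        x_tgt2.loc["s0"] += 5.0
        inner1 = gb.fit_bridge(x_src.loc[rest], x_tgt.loc[rest],
                               min_residual_df=0)
        inner2 = gb.fit_bridge(x_src.loc[rest], x_tgt2.loc[rest],
                               min_residual_df=0)
        for j in ("A", "B"):
            pd.testing.assert_series_equal(inner1[j].coefficients,
                                           inner2[j].coefficients)
        # and loocv's out-of-fold score is exactly the inner-model score
        manual = gb.score(gb.reweight(model, inner1), x_tgt.loc[["s0"]])
        assert cv.bridged_scores["s0"] == pytest.approx(manual.iloc[0])
        cv2 = gb.loocv(x_src, x_tgt2, model)
        assert cv2.bridged_scores["s0"] != pytest.approx(
            cv.bridged_scores["s0"])

    def test_sample_count_bound(self):
        rng = np.random.default_rng(4)
        k = 2
        model = gb.LinearClassifier(0.0, {"A": 1.0}, "microarray-log2")

        def run(n):
            x_src = pd.DataFrame(rng.normal(0, 1, (n, 1)),
                                 index=[f"s{i}" for i in range(n)],
                                 columns=["A"])
            x_tgt = pd.DataFrame(rng.normal(0, 1, (n, k)),
                                 index=x_src.index, columns=["a", "b"])
            return gb.loocv(x_src, x_tgt, model)

        assert len(run(k + 2).bridged_scores) == k + 2  # runs at n = K+2
        with pytest.raises(ValueError, match="K \\+ 2"):
            run(k + 1)


class TestRocMetrics:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(10), np.ones(10)]
        labels = np.r_[np.zeros(10), np.ones(10)].astype(bool)
        r = gb.roc_metrics(scores, labels)
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_single_class_is_hard_error(self):
        with pytest.raises(ValueError, match="both classes"):
            gb.roc_metrics([1.0, 2.0], [True, True])

    def test_monotone_invariance(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(0, 1, 100)
        labels = rng.random(100) < 0.4
        r1 = gb.roc_metrics(scores, labels)
        r2 = gb.roc_metrics(3.0 * scores + 11.0, labels)
        assert r1.auc == pytest.approx(r2.auc)
        assert r1.sensitivity == r2.sensitivity
        assert r1.specificity == r2.specificity

    def test_null_auc_within_delong_99_ci(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(0, 1, 4000)
        labels = np.r_[np.ones(2000), np.zeros(2000)].astype(bool)
        r = gb.roc_metrics(scores, labels, ci_level=0.99)
        assert r.ci_low <= 0.5 <= r.ci_high

    def test_agrees_with_pair_counting_oracle(self):
        rng = np.random.default_rng(7)
        for n in (10, 57, 200):
            scores = np.round(rng.normal(0, 1, n), 1)  # provoke ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                labels[0] = not labels[0]
            r = gb.roc_metrics(scores, labels)
            assert r.auc == pytest.approx(brute_force_auc(scores, labels),
                                          abs=1e-12)

    def test_ci_contains_auc_and_stays_in_unit_interval(self):
        rng = np.random.default_rng(9)
        scores = np.r_[rng.normal(2, 1, 20), rng.normal(0, 1, 30)]
        labels = np.r_[np.ones(20), np.zeros(30)].astype(bool)
        for method in ("delong", "bootstrap"):
            r = gb.roc_metrics(scores, labels, ci_method=method, seed=0)
            assert 0.0 <= r.ci_low <= r.auc <= r.ci_high <= 1.0

    def test_youden_tie_breaks_toward_specificity(self):
        # (sens .5, spec 1) and (sens 1, spec .5) both reach J = 0.5;
        # the higher-specificity operating point must be chosen
        scores = np.array([3.0, 2.0, 1.0, 0.0])
        labels = np.array([True, False, True, False])
        r = gb.roc_metrics(scores, labels)
        assert (r.specificity, r.sensitivity) == (1.0, 0.5)


class TestSummaries:
    def test_single_sample_condition(self):
        s = pd.Series([5.0], index=["a"])
        out = gb.condition_summaries(s, pd.Series(["KD"], index=["a"]))
        assert out.loc["KD", "median"] == 5.0
        assert out.loc["KD", "q3"] - out.loc["KD", "q1"] == 0.0

    def test_linear_interpolation_quartiles(self):
        s = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        cond = pd.Series(["X"] * 5, index=s.index)
        out = gb.condition_summaries(s, cond)
        assert (out.loc["X", "q1"], out.loc["X", "median"],
                out.loc["X", "q3"]) == (2.0, 3.0, 4.0)

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        s = pd.Series(rng.normal(0, 1, 30),
                      index=[f"s{i}" for i in range(30)])
        cond = pd.Series(rng.choice(["KD", "DV", "DB"], 30), index=s.index)
        a = gb.condition_summaries(s, cond)
        perm = rng.permutation(s.index)
        b = gb.condition_summaries(s.loc[perm], cond.loc[perm])
        pd.testing.assert_frame_equal(a, b)


class TestRinBias:
    def test_identical_multisets_give_p_one(self):
        s = pd.Series([1.0, 2, 3, 1, 2, 3], index=list("abcdef"))
        rin = pd.Series([7, 7, 7, 9, 9, 9.0], index=s.index)
        assert gb.rin_bias_test(s, rin)["p_value"] == 1.0

    def test_exact_enumeration_p(self):
        # (1,2,3) vs (4,5,6): 2 of the 20 equally likely rank assignments
        # are at least as extreme per tail -> two-sided exact p = 0.1
        s = pd.Series([1.0, 2, 3, 4, 5, 6], index=list("abcdef"))
        rin = pd.Series([7, 7, 7, 9, 9, 9.0], index=s.index)
        out = gb.rin_bias_test(s, rin)
        assert out["method"] == "exact"
        assert out["p_value"] == pytest.approx(0.1)

    def test_unquantifiable_rin_joins_low_stratum(self):
        s = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        rin = pd.Series([np.nan, 7.0, 9.0, 9.0], index=s.index)
        out = gb.rin_bias_test(s, rin)
        assert out["n_low"] == 2 and out["n_high"] == 2

    def test_monotone_transform_invariance(self):
        s = pd.Series([1.0, 2, 3, 4, 5, 6], index=list("abcdef"))
        rin = pd.Series([7, 7, 7, 9, 9, 9.0], index=s.index)
        p1 = gb.rin_bias_test(s, rin)["p_value"]
        p2 = gb.rin_bias_test(np.exp(s), rin)["p_value"]
        assert p1 == p2

    def test_empty_stratum_is_hard_error(self):
        s = pd.Series([1.0, 2], index=list("ab"))
        rin = pd.Series([9.0, 9.0], index=s.index)
        with pytest.raises(ValueError, match="non-empty"):
            gb.rin_bias_test(s, rin)


class TestRinFilter:
    def test_strictly_greater_than_cutoff(self):
        rin = pd.Series([8.0, 8.1, np.nan, 9.0], index=list("abcd"))
        kept = gb.rin_filter(rin)
        assert list(kept) == ["b", "d"]  # 8.0 and unquantifiable excluded
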