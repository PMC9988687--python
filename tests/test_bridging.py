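"""Bridge regressions, coefficient substitution and representation algebra."""

import numpy as np
import pandas as pd
import pytest

import gepbridge as gb
from gepbridge.fixtures import GENE_TO_PROBE


def _frame(arr, prefix="F"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, index=[f"s{i}" for i in range(arr.shape[0])],
                        columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


@pytest.fixture
def random_source():
    rng = np.random.default_rng(0)
    return _frame(rng.normal(10, 2, (30, 4)))


class TestFitBridge:
    def test_self_regression_is_identity(self, random_source):
        x = random_source
        br = gb.fit_bridge(x, x)
        for j in x.columns:
            reg = br[j]
            assert reg.r_squared == pytest.approx(1.0)
            expected = pd.Series(0.0, index=x.columns)
            expected[j] = 1.0
            pd.testing.assert_series_equal(
                reg.coefficients, expected, atol=1e-8, check_names=False)
            assert reg.intercept == pytest.approx(0.0, abs=1e-7)

    def test_noiseless_affine_recovers_inverse_slopes(self, random_source):
        a = np.array([1.0, -2.0, 0.5, 3.0])
        b = np.array([0.5, 2.0, -1.5, 1.0])
        x_tgt = _frame(a + b * random_source.to_numpy(), prefix="T")
        br = gb.fit_bridge(random_source, x_tgt)
        for j, src in enumerate(random_source.columns):
            reg = br[src]
            assert reg.r_squared == pytest.approx(1.0)
            assert reg.coefficients[f"T{j}"] == pytest.approx(1 / b[j])
            off = [reg.coefficients[f"T{k}"] for k in range(4) if k != j]
            np.testing.assert_allclose(off, 0.0, atol=1e-8)

    def test_rank_deficiency_names_collinear_feature(self, random_source):
        x_tgt = random_source.copy()
        x_tgt["DUP"] = x_tgt["F0"] * 2.0
        with pytest.raises(ValueError, match="rank-deficient"):
            gb.fit_bridge(random_source, x_tgt)

    def test_too_few_samples_is_hard_error(self, random_source):
        with pytest.raises(ValueError, match="too few"):
            gb.fit_bridge(random_source.iloc[:5], random_source.iloc[:5])

    def test_missing_rows_dropped_with_warning(self, random_source):
        x_tgt = random_source.copy()
        x_tgt.iloc[0, 0] = np.nan
        with pytest.warns(UserWarning, match="missing"):
            br = gb.fit_bridge(random_source, x_tgt)
        assert br.n_samples == len(random_source) - 1
        assert br.dropped_samples == ["s0"]

    def test_coefficient_recovery_within_ci(self):
        # regression-direction truth: target features exact affine in the
        # latent, noise only on the source side -> OLS is unbiased and the
        # t-based 95% CI should cover the generative value ~95% of the time
        rng = np.random.default_rng(5)
        n, k, reps, hits, total = 60, 3, 40, 0, 0
        for _ in range(reps):
            latent = rng.normal(0, 1, (n, k))
            b = rng.uniform(0.5, 2.0, k)
            x_tgt = _frame(latent * b, prefix="T")
            x_src = _frame(latent + rng.normal(0, 0.4, (n, k)))
            br = gb.fit_bridge(x_src, x_tgt)
            from scipy.stats import t as tdist
            for j, src in enumerate(x_src.columns):
                reg = br[src]
                crit = tdist.ppf(0.975, reg.df_resid)
                truth = np.zeros(k)
                truth[j] = 1 / b[j]
                for m, name in enumerate(x_tgt.columns):
                    half = crit * reg.stderr[name]
                    hits += abs(reg.coefficients[name] - truth[m]) <= half
                    total += 1
        assert hits / total > 0.90

    def test_cv_r_squared_below_fit_r_squared_in_noise(self):
        rng = np.random.default_rng(6)
        x_tgt = _frame(rng.normal(0, 1, (40, 3)), prefix="T")
        y = x_tgt["T0"] * 1.5 + rng.normal(0, 1.0, 40)
        br = gb.fit_bridge(y.to_frame("Y"), x_tgt)
        assert br["Y"].r_squared_cv < br["Y"].r_squared


class TestReweight:
    def _identity_bridge(self, features):
        regs = {
            j: gb.BridgeRegression(
                source_feature=j, intercept=0.0,
                coefficients=pd.Series(
                    [1.0 if k == j else 0.0 for k in features],
                    index=features),
                stderr_intercept=0.0,
                stderr=pd.Series(0.0, index=features),
                r_squared=1.0, r_squared_cv=1.0, df_resid=10)
            for j in features
        }
        return gb.BridgeRegressionSet(regs, list(features), 12)

    def test_identity_regressions_return_original(self):
        original = gb.LinearClassifier(
            2.0, {"A": 1.5, "B": -0.5}, "microarray-log2")
        out = gb.reweight(original, self._identity_bridge(["A", "B"]))
        assert out.intercept == pytest.approx(2.0)
        assert out.weights == pytest.approx({"A": 1.5, "B": -0.5})
        assert out.representation == "raw-dct"

    def test_missing_regression_is_contract_error(self):
        original = gb.LinearClassifier(
            0.0, {"A": 1.0, "MISSING": 2.0}, "microarray-log2")
        with pytest.raises(ValueError, match="MISSING"):
            gb.reweight(original, self._identity_bridge(["A"]))

    def test_linear_in_original_weights(self, random_source):
        rng = np.random.default_rng(2)
        x_tgt = _frame(rng.normal(0, 1, (30, 4)), prefix="T")
        br = gb.fit_bridge(random_source, x_tgt)
        feats = list(random_source.columns)
        w1 = gb.LinearClassifier(1.0, dict(zip(feats, [1, 2, 3, 4.0])),
                                 "microarray-log2")
        w2 = gb.LinearClassifier(-2.0, dict(zip(feats, [0.5, -1, 0, 2.0])),
                                 "microarray-log2")
        wsum = gb.LinearClassifier(
            -1.0, {f: w1.weights[f] + w2.weights[f] for f in feats},
            "microarray-log2")
        b1, b2, bsum = (gb.reweight(m, br) for m in (w1, w2, wsum))
        assert bsum.intercept == pytest.approx(b1.intercept + b2.intercept)
        for k in bsum.weights:
            assert bsum.weights[k] == pytest.approx(
                b1.weights[k] + b2.weights[k])

    def test_noiseless_affine_substitution_oracle(self, noiseless_cohort,
                                                  original_model):
        # exact gene-wise affine platform map: bridged scores on delta-Ct
        # must equal original scores on the microarray, sample for sample
        from conftest import paired_matrices
        em, ct, _, _ = noiseless_cohort
        x_src, x_tgt = paired_matrices(em, ct, original_model)
        br = gb.fit_bridge(x_src, x_tgt)
        bridged = gb.reweight(original_model, br)
        np.testing.assert_allclose(
            gb.score(bridged, x_tgt).to_numpy(),
            gb.score(original_model, x_src).to_numpy(), atol=1e-9)


class TestRepresentations:
    def test_published_raw_weights(self, normalized_model, raw_model):
        raw = gb.to_raw(normalized_model)
        for g, w in raw_model.weights.items():
            assert round(raw.weights[g], 3) == pytest.approx(w)
        # the published raw intercept was computed from unrounded internal
        # values; from the printed 3-dp inputs it lands at 23.9708
        assert raw.intercept == pytest.approx(23.9708, abs=5e-4)

    def test_round_trip(self, normalized_model):
        back = gb.to_normalized(gb.to_raw(normalized_model),
                                normalized_model.norm_params)
        assert back.intercept == pytest.approx(normalized_model.intercept)
        for g, w in normalized_model.weights.items():
            assert back.weights[g] == pytest.approx(w)

    def test_published_raw_recovers_normalized_at_3dp(self, raw_model,
                                                      normalized_model):
        back = gb.to_normalized(raw_model, normalized_model.norm_params)
        for g, w in normalized_model.weights.items():
            assert round(back.weights[g], 3) == pytest.approx(w, abs=2e-3)

    def test_identity_norm_params(self):
        m = gb.LinearClassifier(1.0, {"G": 2.0}, "normalized-dct",
                                norm_params={"G": (0.0, 1.0)})
        raw = gb.to_raw(m)
        assert raw.intercept == 1.0 and raw.weights["G"] == 2.0

    def test_single_feature_hand_algebra(self):
        # w=2 on z=(x-3)/0.5, intercept 1  ->  raw: 4x + (1 - 12)
        m = gb.LinearClassifier(1.0, {"G": 2.0}, "normalized-dct",
                                norm_params={"G": (3.0, 0.5)})
        raw = gb.to_raw(m)
        assert raw.weights["G"] == pytest.approx(4.0)
        assert raw.intercept == pytest.approx(-11.0)

    def test_to_raw_requires_normalized(self, raw_model):
        with pytest.raises(ValueError, match="normalized-dct"):
            gb.to_raw(raw_model)


class TestScore:
    def test_all_zero_features_give_intercept(self, raw_model):
        x = pd.DataFrame(0.0, index=["s"], columns=list(raw_model.weights))
        assert gb.score(raw_model, x).iloc[0] == raw_model.intercept

    def test_one_feature_hand_value(self):
        m = gb.LinearClassifier(1.0, {"G": 2.0}, "raw-dct")
        x = pd.DataFrame({"G": [3.0]}, index=["s"])
        assert gb.score(m, x).iloc[0] == 7.0

    def test_representation_equivalence(self, normalized_model):
        rng = np.random.default_rng(1)
        genes = list(normalized_model.weights)
        x = pd.DataFrame(rng.normal(-2, 2, (25, len(genes))),
                         index=[f"s{i}" for i in range(25)], columns=genes)
        mu = pd.Series({g: normalized_model.norm_params[g][0] for g in genes})
        sd = pd.Series({g: normalized_model.norm_params[g][1] for g in genes})
        z = (x - mu) / sd
        s_norm = gb.score(normalized_model, z)
        s_raw = gb.score(gb.to_raw(normalized_model), x)
        np.testing.assert_allclose(s_norm, s_raw, atol=1e-9)

    def test_missing_feature_error_lists_sample_and_feature(self, raw_model):
        x = pd.DataFrame(0.0, index=["s1", "s2"],
                         columns=list(raw_model.weights))
        x.loc["s2", "CACNA1E"] = np.nan
        with pytest.raises(ValueError, match="s2.*CACNA1E"):
            gb.score(raw_model, x)
        with pytest.raises(ValueError, match="CACNA1E"):
            gb.score(raw_model, x.drop(columns=["CACNA1E"]))
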