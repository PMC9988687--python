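"""Cross-validated evaluation of a bridged classifier.

Leave-one-out cross-validation refits the whole bridge (per-feature OLS +
substitution) without the held-out sample and scores that sample with the
inner model, so each pooled out-of-fold score comes from a model that never
saw it.  The pooled scores are compared against the original-platform
scores by ROC analysis: empirical AUC (Mann–Whitney identity), a DeLong
95% confidence interval, and the Youden operating point.  Headline runs
retain only high-quality RNA (RIN > 8.0, strictly) and exclude healthy
controls from the ROC; excluded samples remain scorable for bias checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .core import LinearClassifier
from .bridging import fit_bridge, reweight, score

__all__ = [
    "CvResult",
    "RocSummary",
    "loocv",
    "roc_metrics",
    "delong_auc_variance",
    "condition_summaries",
    "rin_bias_test",
    "rin_filter",
]


@dataclass
class CvResult:
    """Pooled out-of-fold bridged scores next to original-model scores."""

    bridged_scores: pd.Series
    original_scores: pd.Series
    n_folds: int
    failed_folds: list[str] = field(default_factory=list)


@dataclass
class RocSummary:
    auc: float
    ci_low: float
    ci_high: float
    youden_threshold: float
    sensitivity: float
    specificity: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def loocv(x_src: pd.DataFrame, x_tgt: pd.DataFrame,
          original: LinearClassifier) -> CvResult:
    """Leave-one-out cross-validated bridging.

    For each sample s the bridge is fit on all other samples
    (exactly-identified inner fits are admitted: with n−1 = K+1 samples
    the OLS solution is unique with zero residual df) and s is scored with
    the resulting inner model.  An inner-fold failure (e.g. rank
    deficiency once the sample is removed) is recorded; the run continues
    with that sample's score missing.  Requires n ≥ K + 2.
    """
    common = x_src.index.intersection(x_tgt.index)
    xs, xt = x_src.loc[common], x_tgt.loc[common]
    n, k = xt.shape
    if n < k + 2:
        raise ValueError(f"leave-one-out needs n >= K + 2 (n={n}, K={k})")
    orig_scores = score(original, xs)
    out, failed = {}, []
    for s in xs.index:
        rest = xs.index.drop(s)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                br = fit_bridge(xs.loc[rest], xt.loc[rest], min_residual_df=0)
            inner = reweight(original, br)
            out[s] = float(score(inner, xt.loc[[s]]).iloc[0])
        except ValueError as exc:
            failed.append(s)
            out[s] = np.nan
            warnings.warn(f"fold for sample {s!r} failed: {exc}", stacklevel=2)
    return CvResult(
        bridged_scores=pd.Series(out, name="bridged_score"),
        original_scores=orig_scores,
        n_folds=n,
        failed_folds=failed,
    )


def delong_auc_variance(scores, labels) -> tuple[float, float]:
    """Empirical AUC and its DeLong variance.

    Uses the structural-component (midrank) formulation: with m positives
    and n negatives, AUC = mean over positive×negative pairs of the
    indicator (ties ½), and var = var(V10)/m + var(V01)/n where V10/V01
    are the per-observation placement values.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n          # placements of positives
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m    # placements of negatives
    auc = float(v10.mean())
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) \
        + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    return auc, float(var)


def roc_metrics(scores, labels, ci_level: float = 0.95,
                ci_method: str = "delong",
                n_boot: int = 2000, seed: int | None = None) -> RocSummary:
    """ROC curve, AUC with confidence interval, and the Youden point.

    Higher score → positive class.  The CI is DeLong by default;
    ``ci_method="bootstrap"`` uses a stratified bootstrap of ``n_boot``
    resamples instead.  The Youden point maximizes sensitivity +
    specificity − 1; ties are broken toward higher specificity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("roc_metrics requires both classes present")
    ok = np.isfinite(scores)
    if not ok.all():
        warnings.warn(f"ignoring {np.sum(~ok)} non-finite score(s)",
                      stacklevel=2)
        scores, labels = scores[ok], labels[ok]
    fpr, tpr, thresholds = roc_curve(labels, scores)
    auc, var = delong_auc_variance(scores, labels)

    if ci_method == "delong":
        z = stats.norm.ppf(0.5 + ci_level / 2)
        half = z * np.sqrt(var)
        lo, hi = auc - half, auc + half
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos_i, neg_i = np.flatnonzero(labels), np.flatnonzero(~labels)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            idx = np.concatenate([rng.choice(pos_i, len(pos_i)),
                                  rng.choice(neg_i, len(neg_i))])
            reps[b], _ = delong_auc_variance(scores[idx], labels[idx])
        alpha = (1 - ci_level) / 2
        lo, hi = np.quantile(reps, [alpha, 1 - alpha])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    lo, hi = max(0.0, min(lo, auc)), min(1.0, max(hi, auc))

    j = tpr - fpr
    best = int(np.argmax(j))  # fpr ascending: first max has highest specificity
    return RocSummary(
        auc=auc, ci_low=float(lo), ci_high=float(hi),
        youden_threshold=float(thresholds[best]),
        sensitivity=float(tpr[best]), specificity=float(1 - fpr[best]),
        fpr=fpr, tpr=tpr, thresholds=thresholds,
    )


def condition_summaries(scores: pd.Series,
                        conditions: pd.Series) -> pd.DataFrame:
    """Per-condition n, median and interquartile range of classifier scores.

    Quartiles use linear interpolation (type-7), the default of the common
    statistical environments, so printed IQRs are directly comparable.
    """
    conditions = conditions.reindex(scores.index)
    rows = {}
    for cond, vals in scores.groupby(conditions):
        v = vals.dropna().to_numpy()
        q1, med, q3 = (np.quantile(v, [0.25, 0.5, 0.75]) if v.size
                       else (np.nan,) * 3)
        rows[cond] = {"n": v.size, "median": med, "q1": q1, "q3": q3}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("condition")


def rin_bias_test(scores: pd.Series, rin: pd.Series,
                  cutoff: float = 8.0) -> dict:
    """Two-sided Wilcoxon rank-sum test for a score bias across RIN strata.

    Compares scores of samples with RIN ≤ cutoff (or unquantifiable)
    against those with RIN > cutoff.  The exact null distribution is used
    when group sizes permit and there are no ties, otherwise the normal
    approximation with tie correction; the method used is reported.
    """
    rin = rin.reindex(scores.index)
    low = scores[(rin <= cutoff) | rin.isna()].dropna()
    high = scores[rin > cutoff].dropna()
    if low.empty or high.empty:
        raise ValueError("both RIN strata must be non-empty")
    pooled = np.concatenate([low, high])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact_ok = (not has_ties) and (len(low) <= 25 and len(high) <= 25)
    method = "exact" if exact_ok else "asymptotic"
    res = stats.mannwhitneyu(low, high, alternative="two-sided",
                             method=method)
    return {"p_value": float(res.pvalue), "statistic": float(res.statistic),
            "method": method, "n_low": int(len(low)), "n_high": int(len(high))}


def rin_filter(rin: pd.Series, cutoff: float = 8.0) -> pd.Index:
    """Sample ids passing the RNA-quality gate: RIN strictly > cutoff.

    Unquantifiable RIN (NaN) fails the gate.  Excluded samples are not
    deleted anywhere — they remain scorable for the RIN-bias analysis.
    """
    return rin.index[rin > cutoff]
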