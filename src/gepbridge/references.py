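"""Reference (housekeeping) gene screening for qRT-PCR assay design.

Candidate reference genes are screened on a discovery expression matrix by
three criteria:

1. moderate-to-high expression — mean log2 intensity inside a window
   (default [11, 15], inclusive);
2. no differential expression across disease conditions — one-way F-test
   p-value >= ``de_alpha`` (genes with p < alpha are excluded);
3. stability — no more than ``max_outliers`` samples flagged by the robust
   Z score 0.6745 · (x_i − median(x)) / MAD(x), |z| > ``z_threshold``,
   where MAD is the unscaled median absolute deviation.

Survivors are ranked by increasing sample variance (most stable first).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .core import ExpressionMatrix

__all__ = [
    "ReferenceScreenConfig",
    "robust_z",
    "count_outliers",
    "de_screen",
    "screen_references",
]


@dataclass
class ReferenceScreenConfig:
    """Thresholds for the three-criterion reference-gene screen.

    ``expr_window`` bounds the gene's mean log2 expression (inclusive);
    ``de_alpha`` is the differential-expression exclusion level;
    ``z_threshold`` the robust-Z outlier cutoff; ``max_outliers`` the
    largest tolerated outlier count ("more than max_outliers" excludes).
    ``two_sided`` counts outliers on |z| (both tails) rather than z alone;
    ``moderated`` switches the F-test to an empirical-Bayes moderated
    variant.
    """

    expr_window: tuple[float, float] = (11.0, 15.0)
    de_alpha: float = 0.05
    z_threshold: float = 3.5
    max_outliers: int = 3
    two_sided: bool = True
    moderated: bool = False

    def __post_init__(self) -> None:
        low, high = self.expr_window
        if not low < high:
            raise ValueError("expr_window must satisfy low < high")
        if not 0 < self.de_alpha < 1:
            raise ValueError("de_alpha must lie in (0, 1)")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be > 0")
        if self.max_outliers < 0:
            raise ValueError("max_outliers must be >= 0")


def robust_z(x) -> np.ndarray:
    """Robust Z scores 0.6745 · (x − median) / MAD.

    MAD is the unscaled median of absolute deviations from the median; the
    0.6745 factor makes the score comparable to an ordinary Z under
    normality.  A constant vector (MAD = 0) is degenerate and returns
    all-zero scores: a constant gene is maximally stable and can have no
    outliers.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("robust_z expects a 1-D vector of length >= 2")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return np.zeros_like(x)
    return 0.6745 * (x - med) / mad


def count_outliers(z, z_threshold: float = 3.5, two_sided: bool = True) -> int:
    """Number of entries whose robust Z exceeds the threshold."""
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("z must be finite")
    return int(np.sum(np.abs(z) > z_threshold if two_sided else z > z_threshold))


def _group_arrays(expr: ExpressionMatrix) -> list[np.ndarray]:
    groups = []
    for cond, idx in expr.condition.groupby(expr.condition).groups.items():
        if len(idx) < 2:
            raise ValueError(
                f"condition group {cond!r} has fewer than 2 samples")
        groups.append(expr.values.loc[idx].to_numpy())
    if len(groups) < 2:
        raise ValueError("de_screen requires at least 2 condition groups")
    return groups


def de_screen(expr: ExpressionMatrix, moderated: bool = False) -> pd.Series:
    """Per-gene p-value for any expression difference across conditions.

    A one-way fixed-effects F-test per gene, vectorized over genes.  With
    ``moderated=True`` the residual variances are squeezed toward a common
    prior fitted by an empirical-Bayes scaled-inverse-chi-squared model
    before forming the F statistic (adds stability at small n; immaterial
    at discovery-scale n).  Genes with zero total variance have no testable
    effect and report p = 1.0.
    """
    groups = _group_arrays(expr)
    n_tot = sum(g.shape[0] for g in groups)
    k = len(groups)
    grand = sum(g.sum(axis=0) for g in groups) / n_tot
    ss_between = sum(g.shape[0] * (g.mean(axis=0) - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean(axis=0)) ** 2).sum(axis=0) for g in groups)
    df1, df2 = k - 1, n_tot - k
    ms_between = ss_between / df1
    s2 = ss_within / df2

    if moderated:
        d0, s0_sq = _fit_variance_prior(s2[s2 > 0], df2)
        if np.isfinite(d0):
            s2_post = (d0 * s0_sq + df2 * s2) / (d0 + df2)
            df2_eff = df2 + d0
        else:  # no evidence of variance heterogeneity: complete pooling
            s2_post = np.where(s2 > 0, s0_sq, 0.0)
            df2_eff = np.inf
    else:
        s2_post, df2_eff = s2, df2

    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_between / s2_post
    p = np.where(
        ss_between + ss_within == 0, 1.0,
        stats.f.sf(f, df1, df2_eff if np.isfinite(df2_eff) else 1e9))
    # exact-fit genes (zero within-group variance but real group effect)
    p = np.where((s2_post == 0) & (ss_between > 0), 0.0, p)
    return pd.Series(p, index=expr.values.columns, name="de_p")


def _fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match a scaled-inv-chi2 prior to observed residual variances.

    Follows the standard empirical-Bayes approach of matching the mean and
    variance of log s² against the theoretical digamma/trigamma moments.
    """
    if s2.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    mean_e = e.mean()
    var_e = e.var(ddof=1) * s2.size / (s2.size - 1)
    excess = var_e - special.polygamma(1, df / 2)
    if excess <= 0:
        return np.inf, float(np.exp(mean_e))
    # invert trigamma(d0/2) = excess by monotone bisection
    lo, hi = 1e-6, 1e6
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if special.polygamma(1, mid / 2) > excess:
            lo = mid
        else:
            hi = mid
    d0 = np.sqrt(lo * hi)
    s0_sq = np.exp(mean_e + special.digamma(d0 / 2) - np.log(d0 / 2))
    return float(d0), float(s0_sq)


def screen_references(expr: ExpressionMatrix,
                      cfg: ReferenceScreenConfig | None = None) -> pd.DataFrame:
    """Screen every gene against the three reference-gene criteria.

    Returns a per-gene report with columns ``mean``, ``variance``, ``de_p``,
    ``n_outliers``, ``pass_window``, ``pass_de``, ``pass_outlier``,
    ``passed`` and ``rank`` (1-based over survivors, increasing variance,
    ties broken lexicographically on gene id; NaN for failures).  The full
    audit trail is retained for failing genes.
    """
    cfg = cfg or ReferenceScreenConfig()
    vals = expr.values
    mean = vals.mean(axis=0)
    variance = vals.var(axis=0, ddof=1)
    de_p = de_screen(expr, moderated=cfg.moderated)
    n_out = pd.Series(
        [count_outliers(robust_z(vals[g].to_numpy()), cfg.z_threshold,
                        cfg.two_sided) for g in vals.columns],
        index=vals.columns)

    low, high = cfg.expr_window
    report = pd.DataFrame({
        "mean": mean,
        "variance": variance,
        "de_p": de_p,
        "n_outliers": n_out,
        "pass_window": (mean >= low) & (mean <= high),
        "pass_de": de_p >= cfg.de_alpha,
        "pass_outlier": n_out <= cfg.max_outliers,
    })
    report["passed"] = (report.pass_window & report.pass_de
                        & report.pass_outlier)
    survivors = report.index[report.passed]
    order = sorted(survivors, key=lambda g: (report.at[g, "variance"], g))
    report["rank"] = pd.Series(
        {g: i + 1 for i, g in enumerate(order)}, dtype="float64"
    ).reindex(report.index)
    if not len(survivors):
        warnings.warn("reference screen retained no genes", stacklevel=2)
    return report
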