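"""Reweighting a fixed linear classifier across measurement platforms.

The bridge assumes each source-platform feature (microarray log2 intensity)
is linearly related to the target-platform features (qRT-PCR ΔCt).  For
each source feature j an ordinary least-squares regression

    X_src[:, j] ≈ β0_j + Σ_k β_jk · X_tgt[:, k]

is fit on paired samples over the *identical* set of included target
features k.  Substituting these fits into the original model
w0 + Σ_j w_j·X_src[:, j] yields the bridged classifier on the target
platform:

    intercept' = w0 + Σ_j w_j β0_j      weight'_k = Σ_j w_j β_jk

The estimator is unregularized OLS with intercept; a rank-deficient design
is a hard error naming the collinear features rather than a silent ridge
fallback, so bridged weights remain directly comparable to published
tables.  Conversions between the normalized-ΔCt and raw-ΔCt model
representations are exact affine reparameterizations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import LinearClassifier

__all__ = [
    "BridgeRegression",
    "BridgeRegressionSet",
    "fit_bridge",
    "reweight",
    "to_raw",
    "to_normalized",
    "score",
]


@dataclass
class BridgeRegression:
    """One source feature's OLS fit onto the target features."""

    source_feature: str
    intercept: float
    coefficients: pd.Series  # indexed by target feature
    stderr_intercept: float
    stderr: pd.Series
    r_squared: float
    r_squared_cv: float  # leave-one-out (PRESS) R²; NaN when undefined
    df_resid: int


@dataclass
class BridgeRegressionSet:
    """Per-source-feature regressions over one shared target-feature set."""

    regressions: dict[str, BridgeRegression]
    target_features: list[str]
    n_samples: int
    dropped_samples: list[str] = field(default_factory=list)

    def __getitem__(self, source_feature: str) -> BridgeRegression:
        return self.regressions[source_feature]

    def r_squared_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "r_squared": {j: r.r_squared for j, r in self.regressions.items()},
            "r_squared_cv": {j: r.r_squared_cv
                             for j, r in self.regressions.items()},
        })


def _check_rank(design: np.ndarray, names: list[str]) -> None:
    """Hard error on rank deficiency, naming the dependent columns."""
    rank = np.linalg.matrix_rank(design)
    if rank >= design.shape[1]:
        return
    # pivoted QR: columns past the numerical rank are the dependent ones
    from scipy.linalg import qr
    _, r, piv = qr(design, pivoting=True, mode="economic")
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    bad = [names[p] for p in piv[np.sum(diag > tol):]]
    raise ValueError(
        f"bridge design is rank-deficient (rank {rank} < {design.shape[1]}); "
        f"collinear feature(s): {bad}")


def fit_bridge(x_src: pd.DataFrame, x_tgt: pd.DataFrame,
               min_residual_df: int = 1) -> BridgeRegressionSet:
    """Fit per-source-feature OLS regressions onto the target features.

    Both inputs are sample × feature tables sharing a sample index.  Rows
    with any missing value in either table are dropped with a warning.
    Requires n ≥ K + 1 + ``min_residual_df`` where K is the number of
    target features; the default leaves at least one residual degree of
    freedom (``min_residual_df=0`` admits exactly-identified fits, used by
    leave-one-out inner folds).
    """
    common = x_src.index.intersection(x_tgt.index)
    if len(common) < len(x_src) or len(common) < len(x_tgt):
        raise ValueError("x_src and x_tgt must share their sample index")
    x_tgt = x_tgt.loc[x_src.index]
    complete = x_src.notna().all(axis=1) & x_tgt.notna().all(axis=1)
    dropped = list(x_src.index[~complete])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} sample(s) with missing "
                      f"feature values: {dropped}", stacklevel=2)
    xs, xt = x_src.loc[complete], x_tgt.loc[complete]

    n, k = xt.shape
    needed = k + 1 + min_residual_df
    if n < needed:
        raise ValueError(
            f"too few complete samples for the bridge: n={n} < {needed} "
            f"(K={k} target features + intercept + {min_residual_df} df)")
    design = sm.add_constant(xt.to_numpy(), has_constant="add")
    _check_rank(design, ["(intercept)"] + list(xt.columns))

    # leave-one-out residuals via the hat matrix (PRESS), shared across j
    pinv = np.linalg.pinv(design)
    hat = np.einsum("ij,ji->i", design, pinv)

    regs: dict[str, BridgeRegression] = {}
    for j in xs.columns:
        y = xs[j].to_numpy()
        fit = sm.OLS(y, design).fit()
        resid = y - fit.fittedvalues
        sst = float(np.sum((y - y.mean()) ** 2))
        if n - k - 1 > 0 and sst > 0 and np.all(hat < 1 - 1e-12):
            press = float(np.sum((resid / (1 - hat)) ** 2))
            r2cv = 1 - press / sst
        else:
            r2cv = np.nan
        regs[j] = BridgeRegression(
            source_feature=j,
            intercept=float(fit.params[0]),
            coefficients=pd.Series(fit.params[1:], index=xt.columns),
            stderr_intercept=float(fit.bse[0]),
            stderr=pd.Series(fit.bse[1:], index=xt.columns),
            r_squared=float(fit.rsquared) if sst > 0 else 1.0,
            r_squared_cv=r2cv,
            df_resid=int(fit.df_resid),
        )
    return BridgeRegressionSet(regs, list(xt.columns), n, dropped)


def reweight(original: LinearClassifier,
             bridge: BridgeRegressionSet) -> LinearClassifier:
    """Substitute the bridge regressions into the original model.

    Every weighted source feature must have a regression; the result is a
    raw-ΔCt-representation classifier over the bridge's target features.
    The substitution is linear in the original weights.
    """
    missing = [j for j in original.weights if j not in bridge.regressions]
    if missing:
        raise ValueError(
            f"no bridge regression for weighted source feature(s): {missing}")
    intercept = original.intercept
    weights = pd.Series(0.0, index=bridge.target_features)
    for j, w in original.weights.items():
        reg = bridge.regressions[j]
        intercept += w * reg.intercept
        weights = weights.add(w * reg.coefficients, fill_value=0.0)
    return LinearClassifier(
        intercept=float(intercept),
        weights={k: float(v) for k, v in weights.items()},
        representation="raw-dct",
    )


def to_raw(model: LinearClassifier) -> LinearClassifier:
    """Convert a normalized-ΔCt model to the equivalent raw-ΔCt model.

    With per-feature normalization (x − μ_k)/σ_k, the identical scores are
    produced by w_raw,k = w_k/σ_k and
    intercept_raw = intercept − Σ_k w_k·μ_k/σ_k.
    """
    if model.representation != "normalized-dct":
        raise ValueError("to_raw expects a normalized-dct model")
    assert model.norm_params is not None  # guaranteed by the invariant
    weights, intercept = {}, model.intercept
    for k, w in model.weights.items():
        mu, sd = model.norm_params[k]
        weights[k] = w / sd
        intercept -= w * mu / sd
    return LinearClassifier(intercept=float(intercept), weights=weights,
                            representation="raw-dct")


def to_normalized(model: LinearClassifier,
                  norm_params: dict[str, tuple[float, float]]
                  ) -> LinearClassifier:
    """Exact inverse of :func:`to_raw` given per-feature (mean, sd)."""
    if model.representation != "raw-dct":
        raise ValueError("to_normalized expects a raw-dct model")
    missing = set(model.weights) - set(norm_params)
    if missing:
        raise ValueError(f"norm_params missing for features: {sorted(missing)}")
    weights, intercept = {}, model.intercept
    for k, w in model.weights.items():
        mu, sd = norm_params[k]
        if sd <= 0:
            raise ValueError(f"sd must be > 0 for feature {k!r}")
        weights[k] = w * sd
        intercept += w * mu
    return LinearClassifier(
        intercept=float(intercept), weights=weights,
        representation="normalized-dct",
        norm_params={k: norm_params[k] for k in weights})


def score(model: LinearClassifier, features: pd.DataFrame) -> pd.Series:
    """Classifier score per sample: intercept + Σ_k w_k·x_sk.

    ``features`` must be in the model's representation (raw ΔCt for
    raw-dct, z-scored ΔCt for normalized-dct, log2 intensity for
    microarray-log2).  Higher score indicates the positive (KD) class.
    Missing weighted features are a hard error listing features and the
    affected samples.
    """
    absent = [k for k in model.weights if k not in features.columns]
    if absent:
        raise ValueError(f"features missing weighted column(s): {absent}")
    x = features[list(model.weights)]
    nan_rows = x.isna().any(axis=1)
    if nan_rows.any():
        detail = {
            s: list(x.columns[x.loc[s].isna()])
            for s in x.index[nan_rows]
        }
        raise ValueError(
            f"missing weighted feature values per sample: {detail}")
    w = pd.Series(model.weights)
    return (x @ w + model.intercept).rename("score")
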