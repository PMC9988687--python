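"""Data model and I/O for expression matrices, Ct tables and classifier weights.

The package moves data between two measurement platforms:

* a *source* platform reporting log2 intensities per (sample, gene)
  (``ExpressionMatrix``), and
* a *target* platform reporting qPCR cycle-threshold values per
  (sample, target) (``CtTable``), from which ΔCt values are derived
  (``DeltaCtMatrix``).

A ``LinearClassifier`` is an intercept plus per-feature weights, tagged with
the feature representation it applies to.  All tables are samples-in-rows,
features-in-columns; identifiers are case-sensitive and matched exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CtTable",
    "DeltaCtMatrix",
    "LinearClassifier",
    "CohortPair",
    "REPRESENTATIONS",
    "DEFAULT_UNDETERMINED_TOKENS",
    "read_expression",
    "write_expression",
    "read_ct",
    "write_ct",
    "read_classifier",
    "write_classifier",
    "load_published_classifier",
    "pair_cohort",
]

REPRESENTATIONS = ("microarray-log2", "normalized-dct", "raw-dct")

#: Tokens in a Ct export that denote a reaction that never crossed threshold.
DEFAULT_UNDETERMINED_TOKENS = ("Undetermined", "NA", "")


def _check_unique(ids: Iterable[str], what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dupes = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicated {what} identifiers: {dupes}")


@dataclass
class ExpressionMatrix:
    """Sample × gene table of log2 intensities with per-sample labels.

    Parameters
    ----------
    values
        DataFrame of finite log2 intensities, samples in rows.
    condition
        Categorical label per sample (e.g. KD, DB, DV, U, JIA, HSP, HC).
    site
        Optional collection-site label per sample.
    """

    values: pd.DataFrame
    condition: pd.Series
    site: pd.Series | None = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "sample")
        _check_unique(self.values.columns, "gene")
        self.values = self.values.astype(float)
        self.condition = self.condition.reindex(self.values.index)
        missing = self.condition.index[self.condition.isna()].tolist()
        if missing:
            raise ValueError(f"samples without a condition label: {missing}")
        bad = ~np.isfinite(self.values.to_numpy())
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                "non-finite expression value at "
                f"(sample {self.values.index[r]!r}, gene {self.values.columns[c]!r})"
            )
        if self.site is not None:
            self.site = self.site.reindex(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, samples: Iterable[str] | None = None,
               genes: Iterable[str] | None = None) -> "ExpressionMatrix":
        v = self.values
        if samples is not None:
            v = v.loc[list(samples)]
        if genes is not None:
            v = v[list(genes)]
        site = self.site.loc[v.index] if self.site is not None else None
        return ExpressionMatrix(v.copy(), self.condition.loc[v.index].copy(), site)


@dataclass
class CtTable:
    """Sample × target table of qPCR cycle-threshold values.

    Undetermined reactions (no amplification within ``max_cycles``) are held
    as NaN; ``undetermined`` exposes the flag matrix.  ``rin`` carries the
    per-sample RNA integrity number (1–10); NaN means unquantifiable.
    """

    ct: pd.DataFrame
    rin: pd.Series | None = None
    max_cycles: float = 40.0

    def __post_init__(self) -> None:
        _check_unique(self.ct.index, "sample")
        _check_unique(self.ct.columns, "target")
        self.ct = self.ct.astype(float)
        vals = self.ct.to_numpy()
        finite = np.isfinite(vals)
        if (vals[finite] <= 0).any():
            raise ValueError("Ct values must be positive")
        if (vals[finite] > self.max_cycles).any():
            r, c = np.argwhere(finite & (vals > self.max_cycles))[0]
            raise ValueError(
                f"Ct {vals[r, c]} exceeds max_cycles={self.max_cycles} at "
                f"(sample {self.ct.index[r]!r}, target {self.ct.columns[c]!r})"
            )
        if self.rin is None:
            self.rin = pd.Series(np.nan, index=self.ct.index, name="RIN")
        else:
            self.rin = self.rin.reindex(self.ct.index).astype(float)
            ok = self.rin.dropna().between(1, 10)
            if not ok.all():
                raise ValueError(f"RIN outside [1, 10] for samples: "
                                 f"{ok.index[~ok].tolist()}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def target_ids(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def undetermined(self) -> pd.DataFrame:
        return self.ct.isna()


@dataclass
class DeltaCtMatrix:
    """Sample × target ΔCt values (reference targets removed).

    ΔCt = ½(Ct_ref1 + Ct_ref2) − Ct_target, so higher expression (lower Ct)
    gives a higher ΔCt.  An entry is NaN iff the target Ct was undetermined.
    """

    values: pd.DataFrame
    reference_ids: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "sample")
        _check_unique(self.values.columns, "target")
        if self.reference_ids is not None:
            leaked = set(self.reference_ids) & set(self.values.columns)
            if leaked:
                raise ValueError(f"reference targets present as columns: {leaked}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def target_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class LinearClassifier:
    """Intercept + per-feature weights with a representation tag.

    ``representation`` declares which feature space the weights apply to:
    ``microarray-log2`` (log2 intensities), ``normalized-dct`` (z-scored
    ΔCt; requires per-feature ``norm_params`` (mean, sd)), or ``raw-dct``
    (raw ΔCt).
    """

    intercept: float
    weights: dict[str, float]
    representation: str
    norm_params: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.representation not in REPRESENTATIONS:
            raise ValueError(
                f"unknown representation {self.representation!r}; "
                f"expected one of {REPRESENTATIONS}")
        if not np.isfinite(self.intercept):
            raise ValueError("intercept must be finite")
        for k, w in self.weights.items():
            if not np.isfinite(w):
                raise ValueError(f"non-finite weight for feature {k!r}")
        if self.representation == "normalized-dct":
            if self.norm_params is None:
                raise ValueError(
                    "normalized-dct representation requires norm_params")
            if set(self.norm_params) != set(self.weights):
                raise ValueError(
                    "norm_params must cover exactly the weighted features")
        if self.norm_params is not None:
            for k, (mu, sd) in self.norm_params.items():
                if not (np.isfinite(mu) and np.isfinite(sd)):
                    raise ValueError(f"non-finite norm params for {k!r}")
                if sd <= 0:
                    raise ValueError(f"sd must be > 0 for feature {k!r}, got {sd}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.weights)


@dataclass
class CohortPair:
    """Paired samples measured on both platforms.

    ``pairing`` maps an expression-side sample id to a Ct-side sample id.
    Samples present on only one platform are recorded in
    ``unpaired_expression`` / ``unpaired_ct``, never silently dropped.
    """

    expression: ExpressionMatrix
    ct: CtTable
    pairing: dict[str, str]
    unpaired_expression: list[str] = field(default_factory=list)
    unpaired_ct: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in self.pairing.items():
            if a not in self.expression.values.index:
                raise ValueError(f"paired sample {a!r} absent from expression")
            if b not in self.ct.ct.index:
                raise ValueError(f"paired sample {b!r} absent from Ct table")
        if len(set(self.pairing.values())) != len(self.pairing):
            raise ValueError("pairing is not a bijection: duplicated Ct samples")


def pair_cohort(expression: ExpressionMatrix, ct: CtTable,
                pairing: Mapping[str, str] | None = None) -> CohortPair:
    """Pair samples across platforms by exact identifier match.

    With ``pairing=None`` the shared identifiers of the two tables are used.
    No fuzzy matching is attempted: silent mispairing is the worst failure
    mode of a bridging study.
    """
    if pairing is None:
        shared = [s for s in expression.sample_ids if s in set(ct.sample_ids)]
        pairing = {s: s for s in shared}
    else:
        pairing = dict(pairing)
    paired_e = set(pairing)
    paired_c = set(pairing.values())
    return CohortPair(
        expression=expression,
        ct=ct,
        pairing=pairing,
        unpaired_expression=[s for s in expression.sample_ids if s not in paired_e],
        unpaired_ct=[s for s in ct.sample_ids if s not in paired_c],
    )


# ---------------------------------------------------------------------------
# Delimited I/O.  TSV by default; .csv extension switches to comma.

def _sep_for(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return {"tsv": "\t", "csv": ","}[fmt]
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(path: str, meta_path: str, fmt: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix plus its metadata sidecar.

    ``path`` holds a delimited table with a header row of gene identifiers
    and one row per sample (first column = sample id).  ``meta_path`` holds
    per-sample metadata with at least a ``condition`` column and optionally
    ``site``.  Non-numeric cells and missing condition labels are hard
    errors naming the offending coordinates.
    """
    sep = _sep_for(path, fmt)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                      keep_default_na=False)
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna().to_numpy()
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric expression cell {raw.iat[r, c]!r} at "
            f"(sample {raw.index[r]!r}, gene {raw.columns[c]!r})")
    meta = pd.read_csv(meta_path, sep=_sep_for(meta_path, fmt), index_col=0,
                       dtype=str, keep_default_na=False)
    if "condition" not in meta.columns:
        raise ValueError(f"metadata file {meta_path} lacks a 'condition' column")
    cond = meta["condition"].replace("", np.nan).reindex(values.index)
    missing = cond.index[cond.isna()].tolist()
    if missing:
        raise ValueError(f"samples without a condition label: {missing}")
    site = meta["site"].reindex(values.index) if "site" in meta.columns else None
    values.index.name = values.columns.name = None
    cond = cond.rename(None)
    cond.index.name = None
    return ExpressionMatrix(values, cond, site)


def write_expression(em: ExpressionMatrix, path: str, meta_path: str,
                     fmt: str | None = None) -> None:
    em.values.to_csv(path, sep=_sep_for(path, fmt), index_label="sample")
    meta = pd.DataFrame({"condition": em.condition})
    if em.site is not None:
        meta["site"] = em.site
    meta.to_csv(meta_path, sep=_sep_for(meta_path, fmt), index_label="sample")


def read_ct(path: str, fmt: str | None = None,
            undetermined_tokens: Iterable[str] = DEFAULT_UNDETERMINED_TOKENS,
            max_cycles: float = 40.0, rin_column: str = "RIN") -> CtTable:
    """Read a Ct table from a delimited instrument export.

    Undetermined reactions are encoded by any token in
    ``undetermined_tokens`` and become NaN with the undetermined flag set.
    A ``rin_column``, when present, is split off as per-sample RIN
    (empty/token cells → unquantifiable).  Ct values above ``max_cycles``
    or non-positive are hard errors.
    """
    sep = _sep_for(path, fmt)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                      keep_default_na=False)
    tokens = set(undetermined_tokens)
    rin = None
    if rin_column in raw.columns:
        rin = pd.to_numeric(raw[rin_column].map(
            lambda s: np.nan if s in tokens else s), errors="coerce")
        raw = raw.drop(columns=[rin_column])
    ct = raw.map(lambda s: np.nan if s.strip() in tokens else s)
    ct = ct.apply(pd.to_numeric)  # non-numeric, non-token cells raise here
    ct.index.name = ct.columns.name = None
    if rin is not None:
        rin = rin.rename("RIN")
        rin.index.name = None
    return CtTable(ct, rin=rin, max_cycles=max_cycles)


def write_ct(table: CtTable, path: str, fmt: str | None = None,
             undetermined_token: str = "Undetermined") -> None:
    out = table.ct.astype(object).where(~table.ct.isna(), undetermined_token)
    if table.rin is not None and table.rin.notna().any():
        out = out.copy()
        out["RIN"] = table.rin
    out.to_csv(path, sep=_sep_for(path, fmt), index_label="sample")


# ---------------------------------------------------------------------------
# Classifier JSON:  {intercept, representation, weights:{id: w},
#                    norm:{id: {mean, sd}}}

def read_classifier(path) -> LinearClassifier:
    with open(path) as fh:
        doc = json.load(fh)
    return _classifier_from_doc(doc)


def _classifier_from_doc(doc: dict) -> LinearClassifier:
    norm = None
    if doc.get("norm"):
        norm = {k: (float(v["mean"]), float(v["sd"]))
                for k, v in doc["norm"].items()}
    return LinearClassifier(
        intercept=float(doc.get("intercept") or 0.0),
        weights={k: float(v) for k, v in doc["weights"].items()},
        representation=doc["representation"],
        norm_params=norm,
    )


def write_classifier(model: LinearClassifier, path) -> None:
    doc: dict = {
        "intercept": model.intercept,
        "representation": model.representation,
        "weights": model.weights,
    }
    if model.norm_params is not None:
        doc["norm"] = {k: {"mean": mu, "sd": sd}
                       for k, (mu, sd) in model.norm_params.items()}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


_PUBLISHED = {
    "original": "classifier_original.json",
    "normalized": "classifier_normalized.json",
    "raw": "classifier_raw.json",
}


def load_published_classifier(which: str = "normalized") -> LinearClassifier:
    """Load one of the packaged published KD classifier representations.

    ``original`` — the 13-probe microarray model (log2-intensity weights;
    the published table prints no intercept, stored as 0.0 — scoring and
    ROC are intercept-invariant).  ``normalized`` — the bridged KiDs-GEP
    model on mean/SD-normalized ΔCt (12 genes; DDIAS excluded as unstable).
    ``raw`` — the same bridged model on raw ΔCt, as published.
    """
    if which not in _PUBLISHED:
        raise ValueError(f"unknown published model {which!r}; "
                         f"expected one of {sorted(_PUBLISHED)}")
    ref = resources.files("gepbridge.data").joinpath(_PUBLISHED[which])
    return _classifier_from_doc(json.loads(ref.read_text()))
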