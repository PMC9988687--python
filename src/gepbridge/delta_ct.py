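"""ΔCt computation and assay-target stability assessment.

Target Ct values are expressed relative to the mean of two stably expressed
reference genes:

    ΔCt_target = ½(Ct_ref1 + Ct_ref2) − Ct_target

so a lower target Ct (more abundant transcript) gives a higher ΔCt.
Amplification efficiencies are assumed constant within a gene; an optional
per-gene efficiency scale hook exists but defaults to none.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .core import CtTable, DeltaCtMatrix

__all__ = ["FeatureStability", "compute_delta_ct", "assess_stability"]


@dataclass
class FeatureStability:
    """Per-target fraction of missing ΔCt values and the resulting
    include/exclude call at ``max_missing_frac``."""

    missing_fraction: pd.Series
    included: pd.Series
    max_missing_frac: float

    @property
    def excluded_targets(self) -> list[str]:
        return list(self.included.index[~self.included])

    @property
    def included_targets(self) -> list[str]:
        return list(self.included.index[self.included])


def compute_delta_ct(ct: CtTable, ref1: str, ref2: str,
                     efficiency: Mapping[str, float] | None = None
                     ) -> DeltaCtMatrix:
    """ΔCt per (sample, target) relative to two reference genes.

    Samples in which either reference Ct is undetermined are dropped with a
    warning — ΔCt is undefined without both anchors, and imputing one would
    silently distort any downstream bridge.  An undetermined target Ct
    yields a missing ΔCt; the sample is retained for its other targets.
    Reference columns are removed from the output.

    ``efficiency`` optionally scales each target's Ct by a per-gene
    amplification-efficiency factor before differencing (default: none,
    efficiencies assumed constant within a gene).
    """
    if ref1 == ref2:
        raise ValueError("ref1 and ref2 must be distinct reference targets")
    for ref in (ref1, ref2):
        if ref not in ct.ct.columns:
            raise ValueError(f"reference target {ref!r} absent from Ct table")

    refs_ok = ct.ct[ref1].notna() & ct.ct[ref2].notna()
    dropped = list(ct.ct.index[~refs_ok])
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} sample(s) with undetermined reference "
            f"Ct: {dropped}", stacklevel=2)
    kept = ct.ct.loc[refs_ok]
    if kept.empty:
        raise ValueError("no samples remain with both reference Cts determined")

    targets = [c for c in kept.columns if c not in (ref1, ref2)]
    tgt = kept[targets]
    if efficiency is not None:
        tgt = tgt.mul(pd.Series(efficiency).reindex(targets).fillna(1.0),
                      axis=1)
    ref_mean = 0.5 * (kept[ref1] + kept[ref2])
    delta = tgt.rsub(ref_mean, axis=0)
    return DeltaCtMatrix(delta, reference_ids=(ref1, ref2))


def assess_stability(dct: DeltaCtMatrix,
                     max_missing_frac: float = 0.05) -> FeatureStability:
    """Flag assay targets whose ΔCt is missing in too many samples.

    A target with a missing fraction above ``max_missing_frac`` is marked
    excluded — such a construct is not sufficiently reliable to serve as an
    explanatory term in a bridge regression.  Exclusions are logged.
    """
    if not 0 <= max_missing_frac <= 1:
        raise ValueError("max_missing_frac must lie in [0, 1]")
    frac = dct.values.isna().mean(axis=0)
    included = frac <= max_missing_frac
    excluded = list(included.index[~included])
    if excluded:
        warnings.warn(
            f"excluding unstable target(s) {excluded} "
            f"(missing fraction > {max_missing_frac})", stacklevel=2)
    return FeatureStability(missing_fraction=frac, included=included,
                            max_missing_frac=max_missing_frac)
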