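import warnings

import numpy as np
import pandas as pd
import pytest

import gepbridge as gb
from gepbridge.fixtures import GENE_TO_PROBE, REFERENCE_GENES


@pytest.fixture(scope="session")
def normalized_model():
    return gb.load_published_classifier("normalized")


@pytest.fixture(scope="session")
def raw_model():
    return gb.load_published_classifier("raw")


@pytest.fixture(scope="session")
def original_model():
    return gb.load_published_classifier("original")


@pytest.fixture
def small_expression():
    values = pd.DataFrame(
        [[12.0, 8.5], [11.5, 9.0], [13.0, 7.5], [12.5, 8.0]],
        index=["s1", "s2", "s3", "s4"], columns=["G1", "G2"])
    cond = pd.Series(["KD", "KD", "DV", "DV"], index=values.index)
    return gb.ExpressionMatrix(values, cond)


@pytest.fixture
def small_ct():
    ct = pd.DataFrame(
        {"T1": [21.0, 25.0, np.nan], "T2": [23.0, 24.0, 22.0],
         "R1": [20.0, 20.0, 20.0], "R2": [22.0, 22.0, 22.0]},
        index=["s1", "s2", "s3"])
    rin = pd.Series([9.0, 7.5, np.nan], index=ct.index)
    return gb.CtTable(ct, rin=rin)


def noiseless_config(**overrides) -> gb.SyntheticCohortConfig:
    """Generator settings where ΔCt is an exact affine map of the latent
    expression: every noise source off, no dropout, no contamination."""
    base = dict(array_noise_sd=0.0, pcr_noise_sd=0.0, ref_noise_sd=0.0,
                dropout_gene=None, contamination_gene=None,
                rin_unquantifiable_prob=0.0, seed=11)
    base.update(overrides)
    return gb.SyntheticCohortConfig(**base)


@pytest.fixture(scope="session")
def noiseless_cohort():
    return gb.generate_cohort(noiseless_config())


def paired_matrices(em, ct, original, drop_missing=True):
    """Source-probe and ΔCt feature tables on the shared samples."""
    dct = gb.compute_delta_ct(ct, *REFERENCE_GENES)
    x_src = em.values.rename(columns=GENE_TO_PROBE)[list(original.weights)]
    x_tgt = dct.values
    if drop_missing:
        keep = x_tgt.dropna().index
        x_src, x_tgt = x_src.loc[keep], x_tgt.loc[keep]
    return x_src, x_tgt


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="dropping .* sample")
        yield
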