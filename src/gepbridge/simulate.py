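"""Synthetic paired-platform cohorts and toy transcriptomes.

``generate_cohort`` emulates the statistical structure a bridging study
assumes: a latent per-sample expression level per gene (multivariate normal
within condition, with inter-gene co-regulation), observed on the
microarray as latent + noise and on the qPCR side through a gene-wise
affine map,

    ΔCt_g ≈ a_g + b_g · L_g + noise ,

realized as Ct_g = c0_g − b_g·L_g + noise against stably generated
reference-gene Cts.  Two published failure modes are reproduced on demand:
a *dropout* gene whose Ct is undetermined in a fraction of reactions (the
unstable-construct case) and a *contamination* gene whose ΔCt is inflated
in low-quality samples proportionally to (8 − RIN)⁺ (the intronless-gene
genomic-DNA case).  ``SyntheticTruth`` carries the latent matrix, the true
affine parameters, the noiseless true scores and the generator's analytic
AUC, giving tests an oracle side-channel.

``generate_transcriptome`` builds toy genes with 1–4 isoforms via exon
skipping, places microarray probes and junction-spanning qPCR amplicons to
realize configured match-set scenarios, and emits per-sample TPM tables
with isoform switching.

All randomness flows from the single ``seed`` in the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CtTable, ExpressionMatrix, LinearClassifier, load_published_classifier
from .bridging import to_raw
from .fixtures import CLASSIFIER_GENES, REFERENCE_GENES, UNSTABLE_GENE, INTRONLESS_GENE

__all__ = [
    "SyntheticCohortConfig",
    "SyntheticTruth",
    "generate_cohort",
    "generate_screen_cohort",
    "TranscriptomeSimConfig",
    "generate_transcriptome",
]

from scipy import stats

#: Per-condition sample counts of a bridging-sized cohort.
DEFAULT_N_PER_CONDITION = {
    "KD": 13, "DB": 9, "DV": 16, "U": 19, "JIA": 1, "HSP": 2, "HC": 12,
}


def _default_gene_params() -> tuple[list[str], pd.Series, pd.Series, pd.Series]:
    """Gene list with ΔCt-scale means/SDs taken from the published bridged
    model's normalization parameters, and weight signs for class offsets."""
    model = load_published_classifier("normalized")
    genes = list(CLASSIFIER_GENES)
    mu = pd.Series({g: model.norm_params[g][0] for g in model.weights})
    sd = pd.Series({g: model.norm_params[g][1] for g in model.weights})
    w = pd.Series(model.weights)
    # the unstable gene is absent from the bridged model; give it mid-range
    # marginals and a KD-up direction (its original microarray weight is +)
    mu[UNSTABLE_GENE], sd[UNSTABLE_GENE], w[UNSTABLE_GENE] = -3.0, 1.2, 0.5
    return genes, mu.reindex(genes), sd.reindex(genes), w.reindex(genes)


@dataclass
class SyntheticCohortConfig:
    """Knobs of the paired-cohort generator.

    The defaults describe a bridging-sized cohort: per-condition n as in a
    ~70-sample paired study, gene marginals (ΔCt mean/SD) from the
    published model's normalization parameters, exchangeable co-regulation
    ρ = 0.3, a KD mean shift per gene of ``kd_shift_sd`` latent SDs in the
    gene's weight direction (scaled so the generator's analytic AUC is
    ≈ 0.96), gene-wise affine platform maps with slopes spread over
    [0.7, 1.3], microarray noise 0.3 log2 units, qPCR noise 0.25 cycles,
    reference-gene noise 0.05 cycles, 50% undetermined rate on the
    dropout gene and a 0.5 cycle/RIN-unit contamination slope on the
    intronless gene.  RIN is drawn from a mixture populating both the
    ≤ 8 and > 8 strata (~78% above 8, matching the retained fraction of a
    typical archived-RNA cohort), with a small unquantifiable fraction.
    """

    n_per_condition: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_CONDITION))
    genes: list[str] | None = None
    delta_ct_mean: pd.Series | None = None   # per-gene ΔCt-scale mean
    delta_ct_sd: pd.Series | None = None     # per-gene ΔCt-scale SD
    weight_sign: pd.Series | None = None     # direction of the KD shift
    kd_shift_sd: float = 0.7365              # KD mean shift in latent SDs
    rho: float = 0.3                         # exchangeable co-regulation
    correlation: np.ndarray | None = None    # overrides rho when given
    affine_slope_range: tuple[float, float] = (0.7, 1.3)
    array_noise_sd: float = 0.3
    pcr_noise_sd: float = 0.25
    ref_noise_sd: float = 0.05
    ref_ct_levels: tuple[float, float] = (22.0, 24.0)
    dropout_gene: str | None = UNSTABLE_GENE
    dropout_prob: float = 0.5
    dropout_mechanism: str = "mcar"          # or "censor"
    contamination_gene: str | None = INTRONLESS_GENE
    contamination_slope: float = 0.5         # ΔCt cycles per RIN unit below 8
    rin_high_frac: float = 0.78
    rin_unquantifiable_prob: float = 0.04
    max_cycles: float = 40.0
    seed: int = 0

    def resolve(self):
        genes = self.genes
        mu, sd, w = self.delta_ct_mean, self.delta_ct_sd, self.weight_sign
        if genes is None:
            genes, dmu, dsd, dw = _default_gene_params()
            mu = dmu if mu is None else mu
            sd = dsd if sd is None else sd
            w = dw if w is None else w
        if mu is None or sd is None:
            raise ValueError("custom gene lists need delta_ct_mean and "
                             "delta_ct_sd")
        if w is None:
            w = pd.Series(1.0, index=genes)
        mu, sd, w = (s.reindex(genes).astype(float) for s in (mu, sd, w))
        if (sd <= 0).any():
            raise ValueError("delta_ct_sd must be positive")
        g = len(genes)
        if self.correlation is not None:
            corr = np.asarray(self.correlation, dtype=float)
        else:
            corr = np.full((g, g), self.rho)
            np.fill_diagonal(corr, 1.0)
        if corr.shape != (g, g) or not np.allclose(corr, corr.T):
            raise ValueError("correlation must be a symmetric gene×gene matrix")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError("correlation matrix is not positive semi-definite")
        return genes, mu, sd, w, corr


@dataclass
class SyntheticTruth:
    """Oracle side-channel: everything the generator knows.

    ``true_scores`` are the published raw-ΔCt model's scores on the
    *noiseless* ΔCt values (a_g + b_g·L_g); ``analytic_auc`` is the exact
    KD-vs-rest AUC of that score under the generator's class-conditional
    normal mixture.
    """

    latent: pd.DataFrame
    affine_intercept: pd.Series
    affine_slope: pd.Series
    noiseless_delta_ct: pd.DataFrame
    true_scores: pd.Series
    analytic_auc: float
    model: LinearClassifier
    seed: int


def _analytic_auc(model: LinearClassifier, genes: list[str],
                  cond_means: dict[str, pd.Series], cov: np.ndarray,
                  n_per_condition: dict[str, int]) -> float:
    """Exact KD-vs-rest AUC of the true score under the normal mixture.

    The score is linear in the latent ΔCt, hence normal within condition;
    the AUC against the non-KD mixture is the sample-weighted average of
    pairwise normal-normal AUCs Φ(Δmean / √(v_KD + v_c))."""
    w = pd.Series(model.weights).reindex(genes).fillna(0.0).to_numpy()
    var = float(w @ cov @ w)
    means = {c: float(w @ m.to_numpy()) for c, m in cond_means.items()}
    others = [(c, n) for c, n in n_per_condition.items() if c != "KD" and n > 0]
    tot = sum(n for _, n in others)
    if "KD" not in means or tot == 0:
        return float("nan")
    return float(sum(
        n / tot * stats.norm.cdf((means["KD"] - means[c]) / np.sqrt(2 * var))
        for c, n in others))


def generate_cohort(cfg: SyntheticCohortConfig | None = None
                    ) -> tuple[ExpressionMatrix, CtTable, pd.DataFrame,
                               SyntheticTruth]:
    """Generate a paired microarray/qRT-PCR cohort.

    Returns the microarray matrix, the Ct table (classifier targets + two
    reference targets, with RIN), a per-sample metadata frame and the
    :class:`SyntheticTruth` oracle.  Identical (config, seed) pairs give
    bit-identical outputs.
    """
    cfg = cfg or SyntheticCohortConfig()
    genes, mu, sd, wsign, corr = cfg.resolve()
    rng = np.random.default_rng(cfg.seed)
    g = len(genes)

    # gene-wise affine platform map: ΔCt = a + b·L on latent (array) scale.
    slope = pd.Series(np.linspace(*cfg.affine_slope_range, g), index=genes)
    latent_sd = (sd / slope).to_numpy()
    array_mean = pd.Series(np.linspace(7.0, 12.0, g), index=genes)
    intercept = mu - slope * array_mean

    cov = np.outer(latent_sd, latent_sd) * corr
    # KD shift along the weight direction, in latent-SD units
    kd_shift = np.sign(wsign.to_numpy()) * cfg.kd_shift_sd * latent_sd

    samples, conditions, blocks = [], [], []
    i = 0
    for cond, n in cfg.n_per_condition.items():
        if n == 0:
            continue
        mean = array_mean.to_numpy() + (kd_shift if cond == "KD" else 0.0)
        blocks.append(rng.multivariate_normal(mean, cov, size=n,
                                              method="cholesky"))
        samples += [f"S{j:03d}" for j in range(i, i + n)]
        conditions += [cond] * n
        i += n
    latent = pd.DataFrame(np.vstack(blocks), index=samples, columns=genes)
    condition = pd.Series(conditions, index=samples, name="condition")
    n_total = len(samples)

    expr = latent + rng.normal(0.0, cfg.array_noise_sd, latent.shape)
    expression = ExpressionMatrix(expr, condition.copy())

    # qPCR side: reference Cts near their nominal levels, targets through
    # the affine map; ΔCt recovers a + b·L up to reference/target noise.
    r1, r2 = cfg.ref_ct_levels
    ref1 = r1 + rng.normal(0.0, cfg.ref_noise_sd, n_total)
    ref2 = r2 + rng.normal(0.0, cfg.ref_noise_sd, n_total)
    refbar_nominal = 0.5 * (r1 + r2)
    noiseless_dct = latent.mul(slope, axis=1).add(intercept, axis=1)
    ct = refbar_nominal - noiseless_dct \
        + rng.normal(0.0, cfg.pcr_noise_sd, noiseless_dct.shape)

    # RIN: mixture over high/low strata plus an unquantifiable tail
    rin = np.where(rng.random(n_total) < cfg.rin_high_frac,
                   rng.uniform(8.1, 9.9, n_total),
                   rng.uniform(5.5, 8.0, n_total))
    rin[rng.random(n_total) < cfg.rin_unquantifiable_prob] = np.nan
    rin = pd.Series(np.round(rin, 1), index=samples, name="RIN")

    if cfg.contamination_gene is not None and cfg.contamination_gene in genes:
        # genomic contamination in degraded samples: extra template lowers
        # the Ct, inflating ΔCt by slope·(8 − RIN)⁺; unquantifiable RIN is
        # treated as degraded at the stratum floor
        deficit = np.clip(8.0 - rin.fillna(5.5).to_numpy(), 0.0, None)
        ct[cfg.contamination_gene] -= cfg.contamination_slope * deficit

    if cfg.dropout_gene is not None and cfg.dropout_gene in genes:
        col = ct[cfg.dropout_gene].to_numpy(copy=True)
        if cfg.dropout_mechanism == "mcar":
            col[rng.random(n_total) < cfg.dropout_prob] = np.nan
        elif cfg.dropout_mechanism == "censor":
            col[col > cfg.max_cycles] = np.nan
        else:
            raise ValueError(
                f"unknown dropout_mechanism {cfg.dropout_mechanism!r}")
        ct[cfg.dropout_gene] = col

    ct_full = pd.concat(
        [ct, pd.Series(ref1, index=samples, name=REFERENCE_GENES[0]),
         pd.Series(ref2, index=samples, name=REFERENCE_GENES[1])], axis=1)
    ct_full = ct_full.clip(lower=1.0, upper=cfg.max_cycles)
    ct_table = CtTable(ct_full, rin=rin, max_cycles=cfg.max_cycles)

    meta = pd.DataFrame({"condition": condition, "RIN": rin})

    model = to_raw(load_published_classifier("normalized"))
    score_feats = [k for k in model.weights]
    truth_scores = (noiseless_dct[score_feats] @ pd.Series(model.weights)
                    + model.intercept)
    cond_means = {}
    dct_cov_genes = [gn for gn in genes]
    b = slope.to_numpy()
    dct_cov = np.outer(b, b) * cov
    for cond in cfg.n_per_condition:
        if cfg.n_per_condition[cond] == 0:
            continue
        m = array_mean.to_numpy() + (kd_shift if cond == "KD" else 0.0)
        cond_means[cond] = pd.Series(intercept.to_numpy() + b * m, index=genes)
    analytic = _analytic_auc(model, dct_cov_genes, cond_means, dct_cov,
                             cfg.n_per_condition)

    truth = SyntheticTruth(
        latent=latent, affine_intercept=intercept, affine_slope=slope,
        noiseless_delta_ct=noiseless_dct,
        true_scores=truth_scores.rename("true_score"),
        analytic_auc=analytic, model=model, seed=cfg.seed)
    return expression, ct_table, meta, truth


def generate_screen_cohort(n_per_condition: dict[str, int] | None = None,
                           n_stable: int = 2, n_variable: int = 50,
                           stable_sd: float = 0.15,
                           seed: int = 0) -> tuple[ExpressionMatrix, list[str]]:
    """Discovery-style matrix with a few planted reference-gene candidates.

    ``n_stable`` genes are condition-invariant with means inside the
    [11, 15] screening window and small residual SD; ``n_variable`` genes
    carry condition effects, wider means (some outside the window) and
    larger SDs, so a correct screen ranks the planted genes first.
    Returns the matrix and the planted gene ids.
    """
    n_per_condition = n_per_condition or {"KD": 20, "DV": 20, "DB": 20}
    rng = np.random.default_rng(seed)
    n_total = sum(n_per_condition.values())
    cond = np.repeat(list(n_per_condition), list(n_per_condition.values()))
    cols, data = [], []
    for i in range(n_stable):
        cols.append(f"STABLE{i:02d}")
        data.append(rng.normal(rng.uniform(11.5, 14.5), stable_sd, n_total))
    for i in range(n_variable):
        cols.append(f"VAR{i:02d}")
        base = rng.uniform(9.0, 16.0)
        sd = rng.uniform(0.4, 1.2)
        offsets = rng.uniform(0.5, 1.5, len(n_per_condition)) \
            * rng.choice([-1.0, 1.0], len(n_per_condition))
        per_cond = dict(zip(n_per_condition, offsets))
        shift = np.array([per_cond[c] for c in cond])
        data.append(base + shift + rng.normal(0.0, sd, n_total))
    samples = [f"S{j:03d}" for j in range(n_total)]
    em = ExpressionMatrix(
        pd.DataFrame(np.column_stack(data), index=samples, columns=cols),
        pd.Series(cond, index=samples, name="condition"))
    return em, cols[:n_stable]


# ---------------------------------------------------------------------------
# Toy transcriptome generator

@dataclass
class TranscriptomeSimConfig:
    """Scenario-driven toy transcriptome.

    Each entry of ``scenarios`` is (gene, kind) with kind one of
    ``identical`` (one isoform, both platforms match it),
    ``platform_exclusive`` (two isoforms by exon skipping, each platform's
    probe matching a different one), ``partial`` (two isoforms, the
    microarray probe matching both, the amplicon only one) and
    ``intronless`` (single-exon gene; the amplicon cannot span a
    junction).  TPM tables carry per-sample isoform switching.
    """

    scenarios: list[tuple[str, str]] = field(default_factory=lambda: [
        ("GENE_ID", "identical"), ("GENE_SW", "platform_exclusive"),
        ("GENE_PART", "partial"), ("GENE_MONO", "intronless")])
    n_samples: int = 30
    exon_length: int = 120
    probe_length: int = 50
    seed: int = 0


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))


def generate_transcriptome(cfg: TranscriptomeSimConfig | None = None):
    """Build toy transcripts, probes and a TPM table for the scenarios.

    Returns ``(transcripts, tpm, probes, report)`` where ``probes`` maps
    probe id → (sequence, platform, gene) and ``report`` is a per-gene
    frame with the scenario, per-platform match counts and the intronless
    flag.  TPM columns are normalized to sum to 1e6.
    """
    from .transcripts import TranscriptModel  # local import avoids a cycle

    cfg = cfg or TranscriptomeSimConfig()
    rng = np.random.default_rng(cfg.seed)
    el, pl = cfg.exon_length, cfg.probe_length
    transcripts: list[TranscriptModel] = []
    probes: dict[str, tuple[str, str, str]] = {}
    rows = []
    tpm_rows: dict[str, np.ndarray] = {}
    samples = [f"R{j:02d}" for j in range(cfg.n_samples)]

    def junction_probe(left: str, right: str) -> str:
        return left[-(pl // 2):] + right[:pl - pl // 2]

    for gene, kind in cfg.scenarios:
        exons = [_rand_seq(rng, el) for _ in range(4)]
        base = np.exp(rng.normal(3.0, 0.8, cfg.n_samples))  # gene-level TPM
        if kind == "identical":
            t = f"{gene}-T1"
            transcripts.append(TranscriptModel(t, gene, exons[0] + exons[1]))
            probes[f"{gene}_array"] = (exons[1][10:10 + pl], "microarray", gene)
            probes[f"{gene}_pcr"] = (junction_probe(exons[0], exons[1]),
                                     "qrt-pcr", gene)
            tpm_rows[t] = base
            n_a = n_p = 1
            intronless = False
        elif kind in ("platform_exclusive", "partial"):
            t1, t2 = f"{gene}-T1", f"{gene}-T2"
            transcripts.append(
                TranscriptModel(t1, gene, exons[0] + exons[1] + exons[2]))
            transcripts.append(TranscriptModel(t2, gene, exons[0] + exons[2]))
            frac = rng.beta(2, 2, cfg.n_samples)  # isoform switching
            tpm_rows[t1], tpm_rows[t2] = base * frac, base * (1 - frac)
            if kind == "platform_exclusive":
                # array probe inside the skipped exon (T1 only); amplicon
                # spans the skip junction (T2 only)
                probes[f"{gene}_array"] = (exons[1][10:10 + pl],
                                           "microarray", gene)
                probes[f"{gene}_pcr"] = (junction_probe(exons[0], exons[2]),
                                         "qrt-pcr", gene)
                n_a = n_p = 1
            else:
                # array probe in the shared exon (both); amplicon spans the
                # junction retained only in T1
                probes[f"{gene}_array"] = (exons[0][10:10 + pl],
                                           "microarray", gene)
                probes[f"{gene}_pcr"] = (junction_probe(exons[1], exons[2]),
                                         "qrt-pcr", gene)
                n_a, n_p = 2, 1
            intronless = False
        elif kind == "intronless":
            t = f"{gene}-T1"
            seq = exons[0] + exons[1]
            transcripts.append(
                TranscriptModel(t, gene, seq, exons=[(1, len(seq))]))
            probes[f"{gene}_array"] = (seq[5:5 + pl], "microarray", gene)
            probes[f"{gene}_pcr"] = (seq[el - 10:el - 10 + pl], "qrt-pcr", gene)
            tpm_rows[t] = base
            n_a = n_p = 1
            intronless = True
        else:
            raise ValueError(f"unknown scenario kind {kind!r}")
        rows.append({"gene": gene, "scenario": kind,
                     "n_matched_array": n_a, "n_matched_pcr": n_p,
                     "intronless": intronless})

    tpm = pd.DataFrame(tpm_rows, index=samples).T
    tpm = tpm / tpm.sum(axis=0) * 1e6  # per-sample TPM closure
    report = pd.DataFrame(rows).set_index("gene")
    return transcripts, tpm, probes, report
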