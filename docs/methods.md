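# Methods

## The bridging model

Let X ∈ ℝ^{n×J} be paired samples' log2 intensities on the source platform
(J microarray probes) and D ∈ ℝ^{n×K} their ΔCt values on the target
platform (K included qPCR targets). The working assumption is that the two
representations of the same underlying transcript abundance are linearly
related, so each source feature admits a multiple-regression representation

    X[:, j] = β₀ⱼ + Σₖ βⱼₖ D[:, k] + εⱼ ,

fit by unregularized OLS with intercept, every regression using the
identical target-feature set. Given a fixed original classifier
s(x) = w₀ + Σⱼ wⱼ xⱼ, substituting the fitted expectations yields the
bridged classifier on the target platform:

    s′(d) = (w₀ + Σⱼ wⱼ β₀ⱼ) + Σₖ (Σⱼ wⱼ βⱼₖ) dₖ .

The substitution is linear in the original weights, and when the target
platform is an exact gene-wise affine transform of the source
(dₖ = aₖ + bₖ xₖ, bₖ ≠ 0, n > K + 1) the bridged scores equal the original
scores exactly — the oracle case used throughout the tests. Rank-deficient
designs are a hard error naming the collinear features rather than a
silent regularized fallback, so bridged weights remain comparable to
published coefficient tables. Regressing on the *continuous* source
expression rather than refitting against dichotomized disease labels is
the point of the method: the gene–outcome associations and the original
weights are taken as established, and only the platform map is estimated.

Because a dropped target feature (an unstable construct) is co-regulated
with the retained features, its contribution to each source feature is
partially absorbed by the remaining regressors; the per-source-feature R²
and leave-one-out (PRESS) R² reported by `fit_bridge` quantify how much of
each probe's variance the target assay captures.

### Model representations

A classifier is tagged with the feature space its weights apply to:
`microarray-log2`, `normalized-dct` (z-scored ΔCt, carrying per-feature
(μ, σ)), or `raw-dct`. The conversions

    w_raw,k = w_k / σ_k        intercept_raw = intercept − Σₖ w_k μ_k / σ_k

and their inverse are exact reparameterizations; scoring in either
representation agrees to ≤ 1e−9. Reported coefficients are rounded to
3 decimals only at the presentation layer. Note that a raw intercept
recomputed from *printed* 3-decimal (w, μ, σ) triples inherits their
rounding: first-order propagation of ±0.0005 per input across 12 genes
bounds the recomputed intercept's uncertainty at roughly ±0.01, so its
last printed digit is not determined by the printed inputs.

## ΔCt convention

ΔCt_target = ½(Ct_ref1 + Ct_ref2) − Ct_target. Lower Ct means more
template, so higher expression ⇒ higher ΔCt; the classifier score is
oriented so the positive (KD) class scores highest. Amplification
efficiency is assumed constant within a gene (a per-gene efficiency scale
hook exists, default off). Samples with an undetermined reference Ct are
dropped entirely — ΔCt is undefined without both anchors and imputing one
would silently distort the bridge — while an undetermined *target* Ct
yields a missing ΔCt with the sample retained for other targets. Targets
missing in more than `max_missing_frac` (default 0.05) of samples are
excluded from the bridge design as unstable.

## Reference-gene screen

Genes are retained iff (1) mean log2 expression lies in [11, 15]
(inclusive), (2) the across-condition F-test p ≥ 0.05, and (3) at most 3
samples are outliers by the robust Z score 0.6745·(xᵢ − median)/MAD with
|z| > 3.5 (MAD unscaled; a constant gene has MAD 0 and is treated as
zero-outlier — maximal stability). Survivors are ranked by increasing
variance, ties broken lexicographically. The outlier rule is applied on
|z| by default — a stability screen has no reason to tolerate low
outliers while rejecting high ones — with a one-sided variant behind the
`two_sided` config switch.

The DE criterion defaults to an ordinary one-way fixed-effects F-test; an
empirical-Bayes moderated variant (residual variances squeezed toward a
scaled-inverse-χ² prior fitted by moment-matching on log s², with the
prior df added to the denominator df) is available via `moderated=True`.
At discovery-scale n the two are practically identical for *variable*
genes, but for the recovery scenario of near-constant planted genes the
distinction matters: the DE criterion is a null test on a truly stable
gene, so an unmoderated per-gene test excludes each such gene at exactly
rate α, which caps the probability of jointly retaining two planted genes
at (1 − α)² ≈ 0.90. The moderated statistic pools variance information
across genes and does not discard near-constant genes on estimation noise;
the planted-recovery acceptance run therefore uses the moderated screen,
which is also the standard practice for expression screens of this kind
(limma-style moderation).

## Cross-validation and ROC

Leave-one-out CV refits the *whole* bridge (all J regressions plus the
substitution) without the held-out sample and scores that sample with the
inner model, so no fold's model has seen its test point. Inner folds admit
exactly-identified fits (n − 1 = K + 1, zero residual df); the outer run
requires n ≥ K + 2. Inner-fold failures are logged and skipped rather than
aborting the run. Out-of-fold scores are pooled into a single ROC.

AUC is the empirical Mann–Whitney statistic (ties ½); its confidence
interval uses the DeLong structural-components variance by default
(stratified bootstrap optional), truncated to [0, 1]. The Youden point
maximizes sensitivity + specificity − 1 with ties broken toward higher
specificity. Quantile summaries use linear interpolation (type-7).
Headline runs include only samples with RIN strictly > 8.0 and exclude
healthy controls from the ROC (positive class KD vs all retained febrile
conditions); excluded samples remain scorable, and the RIN-bias check is a
two-sided Wilcoxon rank-sum test between the ≤ 8.0/unquantifiable and
> 8.0 strata, exact when group sizes ≤ 25 and no ties occur (the method
used is reported).

## Probe–transcript overlap

Genome alignment with a splice-junction database is replaced by exact
substring matching of probes (and qPCR amplicons) against *spliced*
transcript sequences, which is equivalent for the purpose of determining a
probe's transcript collection and keeps the analysis desk-scale and
dependency-free; genomic exon coordinates (1-based closed, GTF convention)
are optional metadata. Both orientations are searched (a transcript
matches sense if it contains the probe, antisense if it contains the
reverse complement); aggregation sums TPM over the majority orientation of
each probe's matches. Probes must be ≥ 15 nt with ≤ 20% ambiguous bases;
matching is exact by default with an optional Hamming tolerance.
Cross-platform concordance is the R² of a simple regression of one
probe's per-sample aggregate on the other's, on raw TPM by default
(log2(TPM+1) optional).

## Synthetic data

`generate_cohort` draws a latent expression matrix L per condition from a
multivariate normal with exchangeable inter-gene correlation ρ = 0.3
(full matrix configurable, PSD-checked), observes the microarray as
L + N(0, 0.3²), and produces Ct values through gene-wise affine maps with
slopes spread over [0.7, 1.3] against two reference genes generated at
nominal levels 22 and 24 with SD 0.05, plus target noise SD 0.25. The
per-gene ΔCt means and SDs default to the published bridged model's
normalization parameters, so simulated ΔCt values live on a realistic
scale; per-condition sample counts default to a bridging-sized cohort
(13 KD, 9 DB, 16 DV, 19 U, 1 JIA, 2 HSP, 12 HC). The KD latent mean is
shifted along each gene's weight direction by 0.7365 latent SDs — the
value at which the generator's closed-form KD-vs-rest AUC (a
sample-weighted mixture of normal-normal pairwise AUCs) equals 0.96, the
performance regime the bridged assay is meant to operate in. Two failure
modes are on by default: the `DDIAS` target's Ct is undetermined with
probability 0.5 (missing-completely-at-random; a left-censoring-at-40-
cycles option reflects the low-abundance mechanism), and the intronless
`LINC02035` target's ΔCt is inflated by 0.5 cycles per RIN unit below 8.0,
mimicking genomic-DNA contamination in degraded samples. RIN is a mixture
with ~78% of samples above 8.0 plus a 4% unquantifiable tail, so both
quality strata are populated. All randomness flows from the single config
seed; `SyntheticTruth` exposes the latent matrix, true affine parameters,
noiseless true scores and the analytic AUC as an oracle for tests.

What the generator does *not* emulate: site batch effects, non-linear
platform relationships, probe cross-hybridization, amplification-
efficiency drift, and condition-specific covariance structure. Passing
tests therefore demonstrate the correctness of the estimators and
bookkeeping under the linear-map assumption, not clinical performance on
real cohorts.

`generate_transcriptome` builds toy genes (random exons of 120 nt,
isoforms by exon skipping) realizing four match-set scenarios — identical
sets, platform-exclusive isoforms, partial overlap, and an intronless gene
whose amplicon cannot span a junction — with per-sample isoform switching
(Beta(2, 2) fractions) and columns closed to 1e6 TPM.

## Numerical and acceptance-scale choices

- OLS via statsmodels; leave-one-out R² via the PRESS/hat-matrix identity,
  undefined (NaN) for exact fits.
- Coefficient-recovery checks place noise on the *source* side only with
  noiseless ΔCt, so the generative affine parameters are the true OLS
  estimands; noise on the regressors would attenuate OLS
  (errors-in-variables) and make "coverage of the generative value"
  ill-posed.
- Simulation-based checks use 200 replicates at bridging-cohort sizes
  (n = 80 for coefficient coverage, 60 for screen recovery) and n = 2000
  per class for null ROC calibration — large enough for the stated
  Monte-Carlo tolerances while keeping the default suite under a minute.
- The degenerate inputs policy: constant genes are maximally stable
  (screen), zero-variance aggregates give undefined R² with a warning
  (concordance), empty probe matches aggregate to zero with a warning.

## Known limitations

Bridging assumes linearity of the platform relationship per gene and
stable amplification efficiency within a gene; neither is verified by this
package beyond the per-feature R² diagnostics. The published headline
cross-validated performance of the bridged KD assay depends on the
original study's qRT-PCR measurements, which are not publicly deposited;
this package validates the machinery against synthetic cohorts with known
truth and against the published coefficient tables instead.
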