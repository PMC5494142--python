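# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and what the package's tests do and do not
establish.

## Models

### Per-feature association

For a feature with (processed, log2-scale) expression y and an outcome x ∈
{NP, NFT, AD}, the model is ordinary least squares

    y = β0 + β·x + γ'·C + ε,    C = (age, sex, study, nnls, pmi, rin)

with expression as the response and the outcome as a predictor. This
matches the convention of explaining an RNA's expression level by
demographic, technical and pathology variables; the reported variance
explained (squared partial correlation, r² = t²/(t²+df)) is symmetric in
(y, x) given C, while β itself is not — β is expression change per unit
outcome. AD is coded 0/1; NP and NFT are z-scaled by default so that
coefficients are comparable across outcomes (raw-scale mode available).
p-values are two-sided from the t distribution at residual df, and are
floored at the smallest positive double so that p ∈ (0, 1] always holds.
Complete cases only; no imputation at the modeling stage.

The Bonferroni family is the set of retained features of one class tested
against one outcome: 0.05/309 ≈ 1.6×10⁻⁴ for the default miRNA panel,
0.05/454 for the default lincRNA panel. A fixed user threshold (e.g.
0.00016 applied to both classes) is available via
`associate_all(..., fixed_threshold=...)` and the `paper_mimic_threshold`
config key, since published analyses sometimes reuse one panel's threshold
for another; the per-class family is the default.

The leave-one-covariate-out sensitivity table refits the AD model dropping
each covariate in turn plus once with no covariates. Its purpose is
diagnostic: a feature whose AD p-value collapses only when RIN is dropped
is flagged as quality-confounded, not disease-associated.

### Preprocessing

Background adjustment subtracts the per-probe background and marks values
at or below background as missing, on the reading that a sub-background
measurement is an unexpressed probe (thresholding instead of subtraction
is the other defensible reading of vendor guidance; subtraction is the
default here and the behavior is localized in `adjust_background`).
Call-rate filtering removes features with <95% non-missing values, then
samples at the same threshold against the retained features — feature
filtering first, so a sample is not penalized for probes that were going
to be dropped anyway. The low-expression filter removes features below 15
counts in at least half the samples, counting missing entries as below.
Residual missing entries (rare by construction after these filters) are
imputed to the per-feature minimum before normalization.

Quantile normalization maps every sample column onto the across-sample
mean order statistics after a log2(x+1) transform; ties within a column
receive the mean of their tied order statistics. All downstream models
operate on this scale. The transform choice is a config option: the
log scale is standard for count-like expression but is a choice, not a
given.

Batch adjustment is parametric empirical-Bayes ComBat: per-feature
standardization given the batch design (optionally plus biological
covariates), batch location/scale estimates shrunk toward across-feature
moment-matched priors, adjustment, then restoration of the pooled scale
and covariate effects. The default runs batch-only, the minimal reading;
covariates can be supplied. The implementation is numerically equivalent
to Bioconductor `sva::ComBat` (a test verifies agreement to 1e-6 on a
shared fixture). One point worth understanding: when the true batch
effect is identical across features, the EB step shrinks each feature's
batch mean only partway toward the prior (the prior variance is then
estimated from sampling noise alone), so per-feature batch-mean residuals
remain at sampling-noise scale while the systematic, across-feature shift
is removed essentially exactly. Tests and the acceptance script therefore
measure the systematic shift, and bound the per-feature residuals well
below the planted effect rather than at zero.

### Networks

A feature enters the network if the partial F-test of {NP, NFT, AD} in
the joint model (covariates plus all three pathology terms) has p < 0.05.
Edges are then chosen per feature by forward-only stepwise selection
under the Gaussian BIC, n·ln(RSS/n) + k·ln(n) with k the number of
estimated coefficients; the intercept and RIN are forced into every model
— RIN is an adjustment whose edges are suppressed from the export, not a
candidate — and the candidate order is fixed alphabetically so ties
resolve deterministically. Forward-only matches the procedure named;
the BIC formula is a choice (other constants exist) and is centralized in
`network.bic`. Under this BIC, a null candidate is accepted with
probability ≈ P(χ²₁ > ln n) ≈ 1% at n = 700; a selected network therefore
carries a small, quantifiable rate of chance edges, which is the floor
against which edge-recovery rates in the tests should be read. Feature
nodes are annotated significant vs suggestive by comparing the screen
p-value to the per-class Bonferroni threshold vs the nominal 0.05.

### Integration

miR-pathways are intersections of one miRNA's target-gene set with one
pathway gene set, kept at a minimum intersection of 3 (small enough to
keep toy fixtures workable; published sets of interest are larger).
Pathway aliases whose member sets coincide after intersection are merged,
names joined with ';'. Member-gene outcome z-statistics combine by
unweighted Stouffer (Σz/√k). The miRNA's one-sided p uses its own
association sign; the pathway's one-sided p uses the opposite sign by
default — repression logic: a miRNA diminished with disease should leave
its targets elevated — with a same-sign switch. The two one-sided
p-values combine as X = −2(ln p₁ + ln p₂) referred to χ²₄ (the
Fisher-family product for exactly two values; the combination function is
pluggable). Because genes within an annotated pathway are correlated, the
Stouffer z is over-dispersed across cohorts and the joint statistic is
anti-conservative: it is flagged "ranking only" everywhere and never
reported as a p-value. A test demonstrates the inflation directionally.

Effect decomposition fits gene ~ outcome + covariates and gene ~ outcome +
miRNA(s) + covariates; the explained fraction 1 − β_adjusted/β_total is
reported unclipped with a flag when outside [0, 1] and flagged undefined
when β_total is indistinguishable from zero. The incremental adjusted R²
of the miRNA block supports multi-miRNA comparisons (two miRNAs that each
explain part of a gene's variance can jointly explain more than either
alone). Note the estimate is attenuated when the mediator is measured
with error or distorted by coarse rank normalization; see below.

## The synthetic cohort generator

The generator defines the study conditions for every test. Defaults:
700 donors; age ~ N(88, 6.5); 64% female; study split 50/50; neuronal
proportion ~ Beta(8, 12); PMI ~ Gamma(3, 2.3) hours; RIN truncated-normal
(6.5, 1.2) on [2, 9]; cartridge batches of 96 assigned by random
permutation (at least two). NP and NFT are negative-binomial counts
(means 10 and 12, dispersion 2) sharing a Gaussian latent factor with
copula correlation 0.6 — pathology burdens are overdispersed counts and
strongly correlated. Pathologic AD is the deterministic rule
NP ≥ 4 AND NFT ≥ 7, a binary collapse of an intermediate/high-likelihood
autopsy criterion; the thresholds are parameters and the defaults yield
≈61% AD at the default burden distributions. An optional square-root
transform reports variance-stabilized burdens instead of counts, since
measurement scale conventions differ across studies.

miRNA counts are Poisson draws around exp(linear predictor) + background:
per-feature intercepts log-uniform over [ln 100, ln 5000], per-cartridge
shifts ~ N(0, 0.3), RIN slopes ~ N(0.2, 0.05) per RIN unit, biological
noise SD 0.5 (natural log), and per-feature backgrounds drawn once from
logN(3, 0.5) (≈20 counts). A planted feature's slope on the standardized
outcome is sized from the requested variance fraction v as
b = sign·sqrt(|v|/(1−|v|))·σ/sd(x⊥C), using the realized cohort's
covariate-residual outcome SD, so the post-preprocessing squared partial
correlation equals |v| in expectation; the sign encodes direction (the
default planted feature is diminished with AD). All randomness flows from
one integer seed through fixed `SeedSequence` spawn keys, so cohort,
miRNA and mRNA layers are independently reproducible.

mRNA abundances are Gaussian on a log-like scale; member genes of a
planted coherent miR-pathway load on the planted miRNA's standardized
log2 expression with a stated coefficient (default −0.5) plus a direct
outcome effect (default +0.15), and the generator records the implied
mediated share c·b/(c·b + d) from the realized draw. Null pathways and
random target sets draw from non-planted genes so the planted pathway is
the one annotated set carrying the signal. Targets and pathways are
emitted in standard TSV/GMT form.

What the generator does **not** emulate: real miRNA sequence content and
hairpin/arm nomenclature, positive-control scaling and ligation QC of the
real assay chemistry, longitudinal structure, cognition or imaging
phenotypes, and realistic co-expression beyond the planted couplings.
Passing tests therefore demonstrate that the procedures recover what they
are designed to recover under a faithful structural emulation — not that
any particular biological claim transfers to real tissue data.

## Numerical choices and problem sizes

- Multi-feature OLS is solved as one multi-response least-squares system
  per outcome when the matrix has no missing entries, with a per-feature
  complete-case fallback otherwise; designs with condition number above
  1e12 are rejected as singular.
- Quantile-normalization ties use the dense-rank-mean convention,
  vectorized with run-length grouping.
- ComBat's EB iterations stop at relative change 1e-4 (the reference
  implementation's default).
- The joint-score combination floors zero p-values at the smallest
  positive double with a warning.
- Stepwise ties break by fixed candidate order; the exhaustive best-subset
  oracle enumerates all 2^8 candidate subsets and is used in tests only.
- Statistical test fixtures use 150–700 samples, 10–1000 features,
  8–200 replicate seeds, chosen so each check has clear power while the
  suite stays quick; the acceptance script uses 700-sample cohorts
  throughout, 200 replicates for family-wise error and 50 seeds for the
  recovery rates.
- Two fixtures intentionally bypass parts of the normalization chain:
  network edge recovery and mediated-fraction recovery are measured on
  matrices normalized with a fine rank grid (≥100 features) or taken at
  the log scale directly, because quantile normalization with very few
  features is a coarse rank map that distorts planted linear couplings;
  the distortion is a property of rank normalization at tiny panel sizes,
  not of the selection or decomposition procedures under test.

## Known limitations

- The "one-sided Pearson" family combination is implemented as the
  two-value product-of-p χ²₄ form; other members of that family exist and
  the function is pluggable.
- ComBat is parametric-prior only; the non-parametric variant is out of
  scope.
- The RCC reader supports a documented simplified dialect (sectioned
  text, CodeSummary lines), not bit-level vendor files.
- Power statements are monotonicity properties (stronger planted effects
  are detected more often); no specific power figure is asserted because
  power-calculation conventions (α, model form) vary.
- Mediated-fraction estimates are attenuated under mediator measurement
  error; the tests quantify recovery under the generator's conditions
  where that error is small.
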