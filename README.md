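# mircortex

Covariate-adjusted analysis of cortical non-coding RNA (miRNA and lincRNA)
in relation to Alzheimer's disease neuropathology, as a tested and reusable
Python pipeline.

## The problem

Bulk expression of small RNAs measured in postmortem brain tissue is shaped
as much by technical and demographic factors — RNA integrity (RIN),
post-mortem interval (PMI), the neuronal fraction of the dissected tissue,
age, sex, processing batch — as by disease. Case/control comparisons that
ignore these factors produce spurious hits. This package implements the
full analysis chain for relating Nanostring-style miRNA counts (and
RNA-seq lincRNA counts) to quantitative neuropathology — neuritic plaque
burden (NP), neurofibrillary tangle burden (NFT) and a binary pathologic
AD diagnosis — with all of those confounders modeled explicitly:

1. **Preprocessing** (`mircortex.preprocess`): probe-background
   subtraction, 95% call-rate filters on features then samples, removal of
   features below 15 counts in at least half the samples (lincRNA: mean
   expected count < 5), log2 transform, quantile normalization to the mean
   order statistics, and parametric empirical-Bayes batch adjustment
   (ComBat) with cartridges as batches.
2. **Association** (`mircortex.association`): per feature, OLS of
   expression on one outcome plus the covariate set
   {age, sex, study, neuronal proportion, PMI, RIN}. Reported per test:
   β, SE(β), z = β/SE(β), the two-sided t-test p-value, and the variance
   explained as the squared partial correlation
   r² = t²/(t² + df). Family-wise control is Bonferroni over the features
   of one class against one outcome (0.05/309 ≈ 1.6×10⁻⁴ for a 309-miRNA
   panel). A leave-one-covariate-out sensitivity table quantifies
   confounding, RIN above all.
3. **Networks** (`mircortex.network`): features enter if a partial F-test
   of the pathology block {NP, NFT, AD} in the joint model is nominally
   significant; edges are then selected per feature by forward stepwise
   search under BIC = n·ln(RSS/n) + k·ln(n), with the intercept and RIN
   forced into every model and RIN edges suppressed from the export.
4. **Integration** (`mircortex.integration`): miR-pathways — intersections
   of a miRNA's predicted target genes with annotated pathway gene sets —
   are scored by combining member-gene z-statistics with Stouffer's method
   (Σz/√k), converting the miRNA and pathway evidence to one-sided
   p-values (opposite directions by default: a repressing miRNA that falls
   with disease should leave rising targets), and combining them as
   −2(ln p₁ + ln p₂) against χ²₄. The joint score ranks; it is not a
   calibrated p-value. Gene-level effects are further decomposed into the
   part explained by one or more miRNAs (1 − β_adjusted/β_total) with the
   miRNAs' incremental adjusted R².
5. **Synthetic cohorts** (`mircortex.simulate`): everything above is
   exercised against a generator that emulates the structure of a large
   prospective autopsy cohort — ~700 donors, mean age 88, 64% female,
   61% pathologic AD, RIN 2–9 with mean 6.5, correlated NP/NFT burdens,
   cartridge batches of 96 — with planted effects of known size, so every
   stage is testable for parameter recovery without any data download.

## Worked example

```python
import mircortex as mc

cohort = mc.generate_cohort(700, seed=11)
truth = mc.GroundTruth(seed=11)
truth.effects["miR-synth-0001"] = ("ad", -0.067)   # down in AD, 6.7% of variance
raw, background = mc.generate_mirna_counts(cohort, truth, 309, seed=11)
processed, report = mc.preprocess_mirna(raw, background)
assoc = mc.associate_all(processed, cohort)
hit = assoc.query("feature_id == 'miR-synth-0001' and outcome == 'ad'").iloc[0]
print(f"retained {processed.n_features} features x {processed.n_samples} samples")
print(f"Bonferroni threshold: {assoc.attrs['bonferroni_threshold']:.2g}")
print(f"miR-synth-0001 vs AD: beta={hit.beta:.3f}, z={hit.z:.2f}, "
      f"p={hit.p:.2g}, variance explained={hit.r2:.1%}")
print(f"significant feature-outcome pairs: {int(assoc.significant.sum())}")
```

prints

```
retained 309 features x 700 samples
Bonferroni threshold: 0.00016
miR-synth-0001 vs AD: beta=-0.418, z=-7.36, p=5.1e-13, variance explained=7.3%
significant feature-outcome pairs: 3
```

The planted feature is recovered at close to its designed effect size
(7.3% measured vs 6.7% planted for this seed; the mean across seeds sits
on the target) and passes the Bonferroni threshold; the three significant
feature×outcome pairs are that feature against AD and against the two
correlated pathology burdens.

The same stages are available from the shell:

```bash
mircortex simulate --out run --seed 11 --n-samples 700 --n-features 309
mircortex preprocess --counts run/mirna_raw.tsv --background run/background.tsv \
    --pheno run/cohort.csv --out run/processed.tsv
mircortex associate --expr run/processed.tsv --pheno run/cohort.csv \
    --out run/assoc.tsv
mircortex network --expr run/processed.tsv --pheno run/cohort.csv
mircortex run --seed 11 --out run_all        # end-to-end with summary.json
```

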