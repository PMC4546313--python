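# bloodsig

Robust blood-expression prognostic models from stable co-expression modules.

## The problem

Whole-blood mRNA profiles predict survival in castration-resistant prostate
cancer (CRPC), but signatures trained naively on one cohort tend to memorise
dataset-specific correlation structure: independently derived blood
signatures for the same disease can share no genes at all.  `bloodsig`
implements a module-based integrative strategy that selects signature genes
only from co-expression modules that *replicate* across independent
reference cohorts, so that the final model tracks reproducible biology
(myeloid vs lymphoid expression programs in blood) rather than noise.  It is
aimed at computational biologists building or auditing blood-based
prognostic scores across microarray, RNA-seq and qPCR platforms.

## The method

Given a labelled training cohort (high- vs low-risk patients with overall
survival) and two unlabelled reference cohorts of whole-blood expression:

1. **Candidate genes** — per-gene empirical-Bayes moderated t-test between
   risk groups; s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), t_g = logFC_g /
   (s̃_g √(1/n₁+1/n₂)), Benjamini–Hochberg FDR < 0.05, split into up- and
   down-regulated lists.
2. **Stable co-expression modules** — per direction and per reference
   cohort: Pearson correlation → soft-thresholded adjacency a_ij =
   |cor_ij|^β → topological overlap matrix → average-linkage clustering of
   1 − TOM with a fixed-height cut.  Modules from the two cohorts are
   matched by one-sided Fisher's exact overlap; matches with p < 0.01 are
   *stable modules*, ranked by −log p, and the up/down lists are truncated
   to equal length.
3. **Functional cores** — each stable module is intersected with its most
   significantly enriched canonical pathway (Fisher p < 10⁻⁴), falling back
   to the best hematopoietic cell-type signature otherwise.
4. **Representative genes** — the most differentially expressed core gene
   whose mean expression exceeds the transcriptome median, one per module.
5. **Model** — Gaussian naïve Bayes over the top-k up + top-k down
   representatives; k chosen by leave-one-out cross-validation, scoring
   candidates by the log-rank separation of LOO-predicted risk groups
   (posterior dichotomized at 0.5).

Validation cohorts on other platforms are mapped onto the training scale by
per-gene median/MAD affine calibration.  A fixed four-gene qPCR logistic
score is included:

    s = −27.28 − 3.43·MCM2 − 0.68·PROS1 + 3.06·CD22 + 3.49·TMEM66
    score = exp(s)/(1 + exp(s)),   high risk iff score ≥ 0.5

with gene values on the delta-Ct scale (18S-normalized; lower Ct = more
transcript).  Survival evaluation machinery (Kaplan–Meier, log-rank,
Efron-tie Cox PH, concordance index, uni/bivariate score reports) is
provided, and a synthetic multi-cohort generator plants known modules,
effects and hazards so every stage can be tested without patient data.

## Worked example

Run the whole pipeline on a synthetic study (two reference cohorts of 200
samples, a 30+30 training cohort with two up- and two down-regulated
prognostic modules at hazard ratio 3, and an RNA-seq validation view):

```python
from bloodsig import run_synthetic_study
from bloodsig.simulate import SimulationConfig

res = run_synthetic_study(SimulationConfig(seed=7))
```

which at this seed prints (via the fields of `res`):

```
candidates: 95 up, 62 down
stable modules: [('up', 'M1', 'M1', 2.12e-25), ('up', 'M2', 'M2', 2.12e-25),
                 ('down', 'M1', 'M1', 2.22e-18), ('down', 'M2', 'M2', 2.22e-18)]
representatives: ['G0000', 'G0030', 'G0060', 'G0090']
selected k = 1  model genes: ['G0000', 'G0060']
LOO-CV log-rank p = 2.4e-05, HR = 3.79
calibrated-validation rank corr = 0.993
```

Reading: the candidate lists capture the 120 planted prognostic genes and
the 30 unshared-module genes with a handful of false positives; module detection and
Fisher matching call exactly the four planted modules stable (overlap
p ≈ 10⁻²⁵/10⁻¹⁸); the four planted driver genes (G0000, G0030, G0060,
G0090) are selected as representatives; LOO-CV prefers a single gene pair
here, whose predicted risk groups separate training survival at log-rank
p = 2.4×10⁻⁵ (HR 3.79); and after median/MAD calibration the naïve-Bayes
scores of the distorted RNA-seq view rank-correlate at 0.993 with the
undistorted view.

The fixed qPCR score behaves per its formula:

```python
>>> from bloodsig import four_gene_score
>>> four_gene_score(-7, -1, 1, 1)   # s = 3.96
0.9813
>>> four_gene_score(-9, -1, -2, -1) # s = -5.34
0.0048
```

A `bloodsig` CLI exposes the stages individually
(`simulate`, `de`, `modules`, `stability`, `calibrate`, `train`, `score`,
`evaluate`); run `bloodsig --help`.

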