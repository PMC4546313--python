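# Methods

This note documents the statistical models, the defaults and the design
decisions behind `bloodsig`, in the order the pipeline runs.

## Moderated t differential expression (`bloodsig.diffexp`)

Two-group (high- vs low-risk) contrast only.  Per gene, the pooled residual
variance s²_g with d_g = n₁+n₂−2 degrees of freedom is shrunk towards a
prior (d₀, s₀²) under the standard scaled-inverse-chi-square hierarchy:

    s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g)
    t_g  = (x̄_high − x̄_low) / (s̃_g·√(1/n₁ + 1/n₂)) ~ t(d₀ + d_g) under H₀.

The prior is estimated by closed-form moment matching on
e_g = log s²_g − ψ(d_g/2) + log(d_g/2) (unbiased for log σ²_g): the excess
of var(e) over ψ′(d_g/2) identifies d₀ through a Newton inversion of the
trigamma function, and s₀² follows from mean(e).  Two deliberate choices:

* d₀ is capped at 10⁶ to represent an effectively infinite prior; the
  cap makes the d₀ → ∞ limit (a z-like statistic with variance s₀²)
  reachable through the ordinary code path.
* When the log variances are *under*-dispersed (var(e) ≤ ψ′(d_g/2), e.g.
  all sample variances equal), s₀² is set to the geometric mean of the
  sample variances rather than the bias-corrected moment estimate.  In
  that degenerate case shrinkage to the common variance is then exact, so
  equal-variance data is a fixed point and the moderated t coincides with
  the ordinary pooled t — the behaviour one wants from a shrinkage
  estimator with nothing to shrink.

Genes with zero variance in both groups get p = 1 with a warning.  Ranks
order by ascending p with ties broken by |logFC| descending, then gene id,
so they are a deterministic permutation.  BH adjustment is delegated to
statsmodels.  Candidate lists use strict fdr < cutoff (default 0.05).

## Co-expression modules (`bloodsig.coexpression`)

Unsigned weighted network: a_ij = |cor_ij|^β with Pearson correlation
(zero-variance genes get correlation 0 with a warning rather than an
error, because both synthetic and real blood data produce them).  The
topological overlap matrix is

    TOM_ij = (Σ_{u≠i,j} a_iu·a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij),

computed by matrix algebra but tested against a literal triple loop.
Module detection clusters 1 − TOM by average linkage and cuts the tree at
a fixed height (default 0.99) keeping branches with ≥ `min_module_size`
(default 10) genes; everything else is "grey".  A fixed-height cut was
chosen over hybrid dynamic tree cutting deliberately: it is deterministic,
has two interpretable knobs, and recovers planted blocks reliably; the
trade-off is less sensitivity to nested sub-modules, which the pipeline
does not need.  The soft threshold β can be fixed (default 6, the common
unsigned default) or selected as the smallest candidate whose scale-free
fit R² ≥ 0.8 (signed fit index: log₁₀ p(k) regressed on log₁₀ k over 10
connectivity bins), falling back to 6 with a warning.

## Cross-cohort stability (`bloodsig.stability`)

Module overlaps between the two reference cohorts are tested with the
one-sided hypergeometric tail P(X ≥ k) within the universe of candidate
genes present in both assignments (grey genes count in the universe but
never pair).  Each cohort-1 module is matched to its best cohort-2 partner
(smallest p; ties by larger overlap, then label); matches below alpha
(default 0.01) are stable modules ranked by −log p.  The stable gene set
is the *intersection* of the matched pair — genes co-clustered in both
cohorts is the defensible definition of "stable membership".  Matching is
anchored on cohort-1 modules and is intentionally not bijective: two
cohort-1 modules may share a best partner.  Balancing truncates the longer
of the up/down lists from the bottom; if either direction has no stable
module, both lists are emptied (a paired model requires both directions)
with a warning.

## Annotation (`bloodsig.annotation`)

Enrichment reuses the same Fisher tail against two GMT collections
(canonical pathways, hematopoietic cell-type overexpression signatures).
The enrichment universe is all genes measured in the training cohort — a
module's enrichment is judged against the assay background, not the
candidate pool.  No multiplicity adjustment is applied inside `enrich`:
the functional-core rule uses the fixed 10⁻⁴ pathway threshold (a
Bonferroni-style family-wise 0.1 for collections of about a thousand
sets), and the cell-type fallback deliberately has no second threshold —
the best cell-type signature is accepted as-is when no pathway qualifies.

## Model construction (`bloodsig.model`)

The representative of a core is its smallest-p gene among those whose
mean training expression exceeds the median of all genes' means.  "Higher
than half of genes in the genome" is ambiguous between mean, median and
per-sample ranks; the mean-vs-median-of-means reading is stable and
deterministic, and a fallback (smallest-p core gene, flagged) covers cores
with no abundant gene.

The classifier is Gaussian naïve Bayes with unbiased per-class variances
floored at 10⁻⁹ (degenerate one-value folds in LOO would otherwise
produce zero variances) and priors equal to class frequencies; posteriors
are computed in log space so extreme inputs stay in (0,1).  Candidate
model sizes are *paired nested subsets* — top-k up + top-k down
representatives in module-rank order — because pairing up- and
down-regulated genes makes the score robust to monotone normalisation
shifts.  LOO-CV refits the classifier on n−1 samples per fold (the
held-out label never enters its own fold, which a fold-injection test
asserts), dichotomizes the held-out posteriors at 0.5 and compares
candidate k by the log-rank p of the predicted groups on training
survival; ties prefer larger hazard ratio, then smaller k.  A k whose
folds hit a near-singleton class is skipped with a warning; if no size
separates at p < 0.05 the selected model is still returned, flagged
non-significant.

The fixed four-gene qPCR score is the printed logistic model over
delta-Ct values of MCM2, PROS1, CD22 and TMEM66 (intercept −27.28,
weights −3.43, −0.68, +3.06, +3.49, cutoff 0.5), evaluated with an
overflow-safe sigmoid.  `fit_platform_logistic` refits the same shape on
any cohort's survival extremes (deaths before 12 months vs survival past
24 months, both windows configurable) by Newton/IRLS maximum likelihood
(|Δβ| < 10⁻⁸ or 100 iterations); perfect separation is detected by
non-convergence or exploding coefficients and resolved by a small ridge
penalty (10⁻⁴) with a flag.

## Cross-platform calibration (`bloodsig.crossplatform`)

Per gene, validation values are affinely mapped so their median and raw
MAD equal the training cohort's: gain = MAD_train/MAD_val, offset =
med_train − gain·med_val.  Raw (unscaled) MAD is used on both sides — the
1.4826 normal-consistency constant cancels only if applied consistently,
so omitting it everywhere is self-consistent.  The map is exactly
invariant to any prior affine distortion of the validation data (the
property the platform adjustment exists for) and monotone per gene.
Zero-MAD genes get a shift-only map with a warning.  The same code path
serves RNA-seq log2 FPKM and qPCR delta-Ct views; the calibrated matrix
carries the training platform tag.  The training reference distribution
is taken over all training samples.

## Survival evaluation (`bloodsig.survival`)

Cox proportional-hazards fits use lifelines with Efron tie handling
(month-resolution survival data produces heavy ties; Efron is the better
approximation), with a small-ridge retry on convergence failure.  The
log-rank statistic, the Kaplan–Meier product-limit estimator and the
Efron score-test-at-zero are implemented in-package: they are cheap, they
are needed inside cross-validation loops, and they serve as in-repo
oracles (score test at β = 0 with a binary covariate and no ties equals
the log-rank chi-square; both are asserted against each other and against
hand-computed examples).  The concordance index counts comparable pairs
under censoring with score ties worth 0.5, higher score = higher risk.
Score reports dichotomize at a fixed cutoff (0.5 for posterior-type
scores) and flag, rather than test, degenerate splits and collinear
co-scores.

## Synthetic data (`bloodsig.simulate`)

One latent factor per module: gene value = baseline + σ(√r·f + √(1−r)·ε),
giving expected within-module pairwise correlation r and unit marginal
variance at σ = 1.  This is the simplest generator whose block correlation,
group shifts and hazard ratio are all recoverable by independent
estimators.  Defaults encode the study conditions the tests assume:

* reference cohorts n = 200 each; training 30 high + 30 low; validation 25;
* 2 up + 2 down prognostic modules of 30 genes, within-correlation 0.7,
  effects +1.5/+1.2 and −1.5/−1.2 sd (the planted-recovery regime: weaker
  effects let whole modules miss the FDR cut jointly, because the shared
  factor makes a module's observed shift fluctuate as one);
* one shared null-effect module and one unshared module as negative
  controls for the differential-expression and stability stages;
* exponential survival with baseline hazard ln2/24 per month (24-month
  low-risk median), hazard ratio 3 for the high-risk group, independent
  exponential censoring at rate 1/120 (≈ 80 % events, matching
  heavily-evented advanced-cancer cohorts);
* platform views: per-gene affine distortion (gain ~ N(1, 0.1), offset
  ~ N(0, 0.5) for RNA-seq; delta-Ct = a − b·expression + noise with b > 0
  for qPCR, so the simulated Ct falls as expression rises) plus N(0, 0.2)
  measurement noise.

Each module's first gene is its *driver*: effect boosted 1.5× and baseline
abundance forced above the transcriptome median, giving the
representative-gene stage a ground truth.  All randomness flows from the
single config seed through per-role spawned streams, so identical configs
produce identical cohorts.

What the generator does **not** emulate: probe-level microarray artifacts,
batch effects beyond per-gene affine distortion, cell-type deconvolution
structure, correlated censoring, or non-proportional hazards.  Passing
tests therefore demonstrate that the machinery recovers the structure the
method assumes — not that real whole-blood cohorts satisfy those
assumptions.

## Problem sizes and stochastic checks

The test suite and acceptance script run at desk scale: 800-gene cohorts,
240-gene stability replicates, 2000-gene null calibration, 250 BH
replicates, 200 Cox null fits — sizes at which every check completes in
seconds while the Monte-Carlo error of each asserted rate is accounted
for explicitly (type-I band 0.04–0.06 at 2000 genes; FDR bound 0.05 plus
two MC standard errors).  The end-to-end survival-separation check is
intrinsically stochastic — at hazard ratio 3 with 60 patients, even the
true group labels separate at log-rank p < 0.01 in only ~85–90 % of
draws — so it is asserted over five replicate studies (majority at
p < 0.01, all at p < 0.05) rather than on a single draw.

## Known limitations

* The moderated t supports only the two-class design the pipeline needs —
  no covariates, array weights or multi-factor contrasts.
* Module detection targets candidate lists of 10²–10³ genes; no
  block-wise decomposition for >20k-gene networks.
* Stability is defined for exactly two reference cohorts.
* The Cox layer excludes time-dependent covariates, competing risks and
  frailty terms.
* Gene identifiers are opaque case-sensitive strings; no symbol mapping.
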