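# Methods

This note documents the models behind `cfmethyl`, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical conventions. Everything quantitative stated here is computed by
the test suite or the example scripts.

## Marker model and pattern calling

A marker is an amplicon (0-based, half-open coordinates) with ≥2 CpG sites
whose unmethylated state is specific to one cell type. After bisulfite
conversion, an unmethylated CpG cytosine reads T and a methylated one reads
C; cytosines outside CpG context are unmethylated in genomic DNA and must
read T, so residual non-CpG Cs measure conversion failure per molecule.

Calling conventions:

- Per CpG: T → unmethylated, C → methylated, any other base → missing.
- A molecule fails conversion QC when more than 10% of non-CpG reference
  cytosines still read C, and fails the missingness cap when more than 20%
  of its CpG calls are missing. Both thresholds are configurable
  (`QuantConfig`); failing molecules are flagged and excluded from counts,
  never silently dropped from the pattern list.
- The unmethylated-molecule rule defaults to *all observed CpGs
  unmethylated*. This maximizes specificity — a doubly-noised molecule must
  flip every CpG to be miscounted — at a small sensitivity cost; an integer
  threshold k is available for sensitivity-oriented analyses.
- Reads are assigned to loci by a `marker_id:` read-name tag when present,
  otherwise by bisulfite-aware matching of the first 15 bases against the
  locus reference (a reference C matches read C or T). Alignment-based
  assignment is out of scope.
- Undefined quantities (no QC-passing molecules, all markers of a tissue
  missing) propagate as NaN, never as 0: zero is a biological claim about
  the sample, NaN is an assay failure.

"Methylation blocks" are treated as the full CpG set of each amplicon; we
average *fractions* (not concentrations) over a tissue's markers, as an
unweighted mean over markers with data.

## Absolute quantification

GE/mL = fraction × total cfDNA (ng/mL) × 1000 / 3.3, i.e. 3.3 pg per
haploid genome (≈303 genome equivalents per ng). The constant is
configurable and recorded in outputs; concentration is linear in both the
fraction and the total, which the tests assert.

## Spike-in detection limit

`detection_limit` simulates mixtures of a target tissue into a fully
methylated leukocyte background over a fraction ladder, with matched 0%
controls. It works at the molecule-count level: under the all-or-none
methylation model, the number of molecules at a marker meeting the
unmethylated rule is Binomial with success probability
f·(1−r_fail)^C + (1−f)·r_conv^C, where r_fail is the bisulfite failure rate
(unmethylated C still reads C), r_conv the inappropriate conversion rate
(methylated C reads T), and C the marker's CpG count. This is exactly the
distribution the read-level pipeline induces, which the mixture-recovery
tests verify against the read path and its truth table.

A replicate is *detected* when its one-sided rank p-value against the
control distribution is ≤ α (default 0.05). Ranks are randomized across
ties (conditional Monte Carlo): with default noise the control distribution
is degenerate at 0 (a fully methylated molecule passes the all-CpGs rule
with probability r_conv^C ≈ 10⁻¹²), and a naive empirical-quantile test
would have false-detection rate 0 instead of α. The randomized rank test is
exact under the null regardless of ties, which the calibration tests
confirm (rate 0.05 ± 0.03). The reported limit is the smallest ladder
fraction with detection rate ≥ 0.95; the report includes the full rate
table, the null false-detection rate and the linearity slope of estimated
vs true fraction. At the default setting (5 markers, 10,000 reads/marker,
both noise rates 0.005) the limit is 0.10% — the assay's expected signal at
0.1% is ≈49 molecules across the panel against an essentially empty
background, so detection is limited by the ladder's lower end, not by depth.

Default noise rates of 0.005 reflect typical targeted bisulfite assay
performance; both are bounded at 0.1 and configurable.

## Synthetic cohort generator

`generate_cohort` emulates the statistical structure of an HCT case-control
study: three groups (healthy controls, transplanted without cGVHD,
transplanted with clinically evident cGVHD; default 25/36/65), 17 features
(5 biochemistry, total cfDNA, 11 cell-type cfDNA concentrations), NIH-style
organ scores (0–3 for skin, GI, liver, lung) with severity coupled to the
maximum score, days post-transplant (log-normal, median ≈780, floor 101),
and completely-at-random missingness.

Each feature is log-normal:
log x = log(baseline median) + hct_shift·1[transplanted] +
effect·1[cGVHD] + organ_delta·score + λ·L + σ·ε, with a shared per-sample
latent factor L ~ N(0,1) ("cell-death burden") inducing positive
inter-feature correlation, σ = 0.6, λ = 0.3. Baseline medians are ordinary
clinical values (ALT 20 IU/L, total cfDNA 5 ng/mL, ...). GI/liver/lung and
T/CD8/neutrophil cfDNA are shifted up (+0.3–0.4 log units) in both
transplanted groups, reflecting persistent post-transplant tissue turnover
without label signal. Organ scores add 0.15 log units per point to the
matching organ's cfDNA.

Disease signal is planted on exactly three features — ALT, total cfDNA and
monocyte cfDNA — at +0.8 log units each. These magnitudes are calibration
values, not estimates from any dataset: they were fixed by a grid search so
that the three-feature classifier's cross-validated AUC lands near the 0.8
working target (measured ≈0.86–0.88) and the trio tops the Shapley ranking
in ~90% of cohort draws. The default missingness rate 8/101 makes the
expected complete-case count among the 101 transplanted samples 93.

What the generator does *not* emulate: missingness that depends on disease
state, measurement error in biochemistry, longitudinal structure, treatment
effects, or any real covariance beyond the single latent factor. Passing
tests on this cohort validate pipeline mechanics — ranking, constrained
fitting, fold bookkeeping, metric arithmetic — not the biology or the
clinical performance of any marker set.

## Statistics

Mann-Whitney U is two-tailed and unpaired; the exact null distribution is
used when n₁·n₂ ≤ 400 with no ties, otherwise the normal approximation with
tie and continuity corrections (the exact/approximate switch is a package
choice; common GUI statistics packages do not publish theirs). When U
equals its null mean the two-tailed p is set to 1 exactly. The Spearman
matrix uses midranks on pairwise-complete observations (≥3 pairs), stars at
p < 0.05/0.01/0.001, and leaves constant-feature pairs NaN. No
multiple-testing correction is applied by default, matching the
presentation style of single-cohort clinical studies; Benjamini-Hochberg
adjustment is available (`comparisons_frame(..., adjust=True)`).

## Classifier

The model is Bernoulli logistic regression maximized under box constraints
β ≥ 0 (intercept free) with a weak L2 ridge (λ = 10⁻⁴ on standardized
features) via L-BFGS-B. The ridge guarantees a unique finite optimum under
complete separation, which is detected (perfect in-sample classification
with runaway coefficients) and flagged. Coefficients at the active bound
are exactly zero. An unconstrained mode supports the overfitting-comparison
analysis; at large n with nonnegative true effects the two agree, which the
tests check against scikit-learn's penalty-free fit.

Features are z-scored with training-fold statistics only — never the test
fold — both for comparable Shapley magnitudes and for optimizer stability.
Shapley attributions use the interventional formulation with the training
set as background; for a linear log-odds model this reduces to
φ_ij = β_j(x_ij − x̄_j^bg), satisfying efficiency per sample. An exhaustive
2^p coalition enumeration is included as a verification oracle (tested to
1e-9 at p = 12). Ranking is by descending mean |φ|; exact ties break
lexicographically and set a flag.

Cross-validation is stratified 5-fold, repeated (default 20 repeats) with
seeded fold assignment; stratification is essential at 36/65 class
imbalance and n ≈ 93. Threshold metrics use probability 0.5; AUC is
threshold-free (trapezoidal, ties counted ½, equal to positive-negative
pair counting). Undefined ratios (empty confusion-matrix denominators) are
NaN, flagged, and excluded from aggregation. The feature sweep evaluates
nested top-k sets (default k = 1..7) and selects the set with the highest
mean fold AUC, breaking exact ties toward fewer features.

A note on metric definitions: the standard identities are implemented —
sensitivity = recall = TP/(TP+FN), specificity = TN/(TN+FP),
PPV = precision = TP/(TP+FP), NPV = TN/(TN+FN) — since published variants
of these formulas are sometimes printed with the labels interchanged.

## Best-set selection stability

The maximal-mean-AUC rule is kept deliberately simple, and its stability
was characterized rather than hidden. At n ≈ 93 complete cases the
third-ranked feature's true out-of-sample AUC gain is small (≈ +0.02) and
varies between cohort draws by about as much; measured through 5-fold CV
(training folds of ~74) the gain shrinks further, so the argmax over nested
set sizes identifies exactly the three planted features in only ~55% of
cohort draws at the shipped calibration — most misses select the top-2 set.
One-standard-error and forward-stepwise selection variants were evaluated
and do not improve this; the limit is informational (the increment is
comparable to its own sampling noise at this n), not algorithmic. Users
comparing nested sets on cohorts of this size should read the whole sweep
table, not just the argmax.

## Problem sizes in the test suite

Monte-Carlo checks use sizes chosen for statistical resolution: 1000
replicates for type-I-error calibration (binomial SE ≈ 0.007 at α = 0.05),
50 replicates per ladder fraction in the detection-limit assay, 100 cohort
seeds for end-to-end replication with 10 CV repeats per sweep (10 vs 20
repeats was checked to leave best-set selection statistically unchanged),
and n = 2000 for coefficient-recovery checks (SE ≈ 0.06 per coefficient).

## Known limitations

- Read assignment assumes amplicon-positioned reads; no alignment, indel
  handling, UMI deduplication or quality-score use.
- The all-or-none methylation model ignores genuinely hemimethylated or
  partially methylated molecules; real backgrounds are noisier than
  r_conv^C, so real detection limits will be higher than the simulated one.
- The GE conversion treats cfDNA as uniformly diploid genome mass.
- The classifier is diagnostic only; no calibration curves, no
  longitudinal or prognostic modeling.
- The correlation matrix and group tests are presented uncorrected by
  default; with 17 features the pairwise matrix involves 136 tests.
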