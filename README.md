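# cfmethyl

Tissue-of-origin analysis of circulating cell-free DNA (cfDNA) by targeted
bisulfite amplicon methylation markers, with a diagnostic classifier for
chronic graft-versus-host disease (cGVHD) after hematopoietic stem cell
transplantation (HCT).

Dying cells shed DNA into plasma. Because CpG methylation is cell-type
specific, a genomic locus whose CpGs are unmethylated in exactly one cell
type acts as a marker: a sequenced plasma molecule that is unmethylated at
every CpG of that locus very likely came from that cell type. Counting such
molecules per marker, averaging markers per tissue, and scaling by the total
cfDNA concentration yields the absolute amount of DNA each tissue is
shedding — a window into organ damage that ordinary blood chemistry cannot
see. In cGVHD, allo-immune attack on skin, gut, liver and lung (and high
immune-cell turnover) elevates these signals, so they can be combined with
standard biochemistry into a blood-based disease classifier.

The package is aimed at computational biologists who work with targeted
methylation sequencing of plasma and want a tested, reusable implementation
of this analysis chain, including synthetic data generators that make every
stage testable without patient data.

## What it computes

**Quantification.** For marker locus $m$ with $C_m$ CpGs, each QC-passing
molecule is called unmethylated when all of its observed CpGs read T after
bisulfite conversion. With $n_m$ molecules of which $u_m$ are unmethylated,
the tissue fraction for cell type $t$ with marker set $M_t$ and its absolute
concentration are

$$f_t = \frac{1}{|M_t|}\sum_{m \in M_t} \frac{u_m}{n_m},\qquad
c_t = f_t \cdot \mathrm{cfDNA}_{\mathrm{total}}\ (\mathrm{ng/mL})
\cdot \frac{1000}{3.3}\ \mathrm{GE/mL},$$

using 3.3 pg per haploid genome. A spike-in simulation estimates the
smallest mixture fraction the panel detects reliably (one-sided exceedance
of the 0% control distribution at $\alpha=0.05$, detection rate $\ge 0.95$).

**Cohort statistics.** Two-tailed unpaired Mann-Whitney U tests between
groups (exact null distribution for small tie-free samples) and a
pairwise-complete Spearman correlation matrix with significance stars.

**Classifier.** Multivariate logistic regression on 17 features (GGTp, ALP,
ALT, AST, TBil, total cfDNA, and cfDNA of skin, lung, GI, liver,
neutrophils, monocytes, eosinophils, B, T, CD8⁺, and regulatory T cells)
with all slopes constrained nonnegative,
$\max_\beta \ \ell(\beta_0, \beta) \ \text{s.t.}\ \beta \ge 0$,
reflecting the prior that disease only raises these markers. Features are
ranked by mean absolute interventional Shapley value, which for a linear
log-odds model is $\phi_{ij} = \beta_j (x_{ij} - \bar{x}_j)$, and nested
top-$k$ feature sets are compared by repeated stratified 5-fold
cross-validation (accuracy, sensitivity, specificity, PPV, NPV, ROC/AUC).

## Worked example

`examples/04_classifier.py` generates the default synthetic cohort
(25 healthy controls, 36 transplanted without cGVHD, 65 with; ~8% of
samples missing a feature), builds the complete-case feature matrix, ranks
features by Shapley value and cross-validates nested feature sets:

```
complete cases: 92 of 101 transplanted samples (58 with cGVHD)

mean |Shapley| (log-odds units), top 7:
cf_monocyte          1.265
alt                  0.893
cfdna_total_ng_ml    0.770
cf_skin              0.247
...
      auc_mean  auc_sd  specificity_mean  ppv_mean  sensitivity_mean
size
1        0.851   0.090             0.710     0.833             0.793
2        0.861   0.085             0.807     0.891             0.876
3        0.880   0.084             0.787     0.882             0.874
4        0.873   0.082             0.807     0.889             0.856
...
best set (max mean AUC, ties to fewer features): ['cf_monocyte', 'alt', 'cfdna_total_ng_ml']
```

The three features that carry planted signal in the generator (monocyte
cfDNA, ALT, total cfDNA) top the ranking; the cross-validated AUC peaks
once all three are included (0.88 here) and adding further features only
adds noise. The other examples cover the detection-limit assay
(`01_detection_limit.py`, prints the detection-rate ladder and the 0.10%
limit at 10,000 reads/marker), FASTQ-to-tissue-profile quantification
(`02_quantify_mixture.py`) and group statistics with the correlation matrix
(`03_cohort_statistics.py`).

## Layout

- `src/cfmethyl/panel.py` — marker-panel model, TSV/BED I/O, validation
- `src/cfmethyl/synthetic.py` — spike-in read simulator and cohort generator
- `src/cfmethyl/quant.py` — pattern calling, fractions, GE/mL, detection limit
- `src/cfmethyl/stats.py` — Mann-Whitney, Spearman matrix, group summaries
- `src/cfmethyl/model.py` — constrained LR, Shapley, CV, feature sweep
- `docs/methods.md` — model assumptions, parameter choices, limitations
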