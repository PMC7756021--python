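# Methods

## Scope and strategy

The package implements a composition-aware differential-expression analysis
for neurodegenerative brain transcriptomes and validates it entirely on
synthetic data with planted ground truth. Every quantitative claim in the
README and in `results/` is produced by code in this repository at run
time; nothing is copied from external analyses. The synthetic generator is
first-class, tested code: its role is to reproduce the *statistical
structure* of the real study designs closely enough that parameter recovery
on it is informative about the method, and its known departures from real
data are listed under Limitations.

## Generative model

**Single-cell reference.** Four cell types (astrocyte, microglia, neuron,
oligodendrocyte), 120–150 cells each. Gene baseline rates are log-normal
(median 50 relative units, log-SD 1.2). Counts per cell are
negative-binomial with dispersion 0.3 and mean proportional to
`rate[gene,type] × library_scale × mrna_content[type]`, library ≈ 1e5
counts over a 2000-gene panel (Smart-seq-like coverage of ~50 reads per
gene). mRNA content is 2.0 for neurons vs 1.0 for glia, reflecting neuronal
RNA content being roughly twice glial; consequently all estimated fractions
are mRNA shares, not cell shares. Optional planted degenerate cells (5% of
library, 25× mitochondrial rates) and mislabeled cells exercise the QC.

**Marker structure.** 15% of genes are "composition-driven": an 8×
(log2 = 3) neuron-vs-glia expression ratio, half neuron-high, half
neuron-low. A further 15% of null-class genes are single-type markers (8×)
assigned round-robin so every type is identifiable. Two modeling details
matter and were corrected during development: (a) marker rows are rescaled
so their *overall* bulk abundance matches the gene's baseline — markers are
enriched in a type, not more abundant in tissue; without this rescale,
neuron markers monopolize the top expression quantiles and quantile
normalization pins them there, erasing their composition signal; (b)
mitochondrial flags are drawn only from non-marker genes, since
mitochondrial genes are housekeeping — flagging markers as mitochondrial
makes entire cell types fail the mito-fraction QC.

**Bulk cohorts.** Four designs mirror the study arms: AD discovery
71 vs 32, AD validation 9 vs 14, PD RNA-seq 15 vs 26 (male-only, with an
unknown two-level batch), PD microarray 8 vs 10 (male-only, degradation
slope instead of RIN). Cell-level fractions are Dirichlet with
concentration 12 around means (astro .14, micro .04, neuron .70, oligo .12)
for controls and a shifted neuronal mean of .60 for AD-like diseased arms;
PD-like arms share the control distribution. Concentration 12 puts the
neuronal mRNA share at SD ≈ 0.11 with range ≈ 0.35–0.9, matching the wide
spread reported for such cohorts and producing occasional samples below the
0.40 neuronal-share filter, which the sample-QC stage must handle.
Expected expression per sample is the content-weighted mixture of type
rates times `2**(planted log2 effects)`; RNA-seq counts are
negative-binomial (dispersion 0.1, i.e. a biological CV of ~0.32, typical
of post-mortem human tissue) at log-normal depths around 2e6;
microarray-like cohorts are log2 intensities with Gaussian noise (SD 0.3).

**Planted gene classes** (fractions of the panel): systemic 10%
(±1 log2 on the disease indicator, all cell types), composition-driven 15%
(above; no disease coefficient), interaction 5% (±1 log2 on the product of
centered disease and centered neuronal fraction), covariate-only 10%
(age 0.01/yr, sex 0.25, RIN-group 0.30, batch 0.50, degradation-group 0.40,
all log2), null 60%. The truth table accompanying every cohort records all
planted coefficients, so each downstream stage can be scored without hidden
state.

**Chimeric mixtures.** Read-level pooling of cell-type-specific read
sets -- the standard chimeric-library validation design -- is emulated at
count level: pool each type's cells into a count
profile, allocate the depth multinomially to types by the mixture row, then
multinomially to genes by the pooled profile — equivalent in distribution
at gene resolution. Rows are interpreted as cell fractions; when an
`mrna_content` map is supplied, read shares are `fraction × content`, which
is what makes low-content types recover *below* their cell share. Benchmark
conditions: 300 mixtures, Dirichlet α = (1.6, 0.5, 4.4, 1.5) (brain-like
means, scarce microglia), depth 3.5e5 — 35M-read chimeric libraries
scaled down by 100 to desk scale; full depth is a parameter.

**Perturbagen panel.** 200 compounds × 3 cell lines. Planted reversers
carry `z = −k·standardized(score) + noise`, mimickers the positive sign,
neuronal confounders track the neuronal-proportion score vector, the rest
are noise; planted compounds are "launched", neutral compounds mix
launched/clinical/preclinical.

## Analysis pipeline choices

- **Cell QC:** robust z = (value − median) / (1.4826 · MAD), library size
  and expressed-gene counts on log10 scale; remove z < −3 (library,
  genes) or z > 3 (mito). Zero-MAD metrics yield z = 0 at the median and
  ±inf elsewhere and are flagged. Re-running QC after filtering recomputes
  medians, so filtering is deliberately not idempotent.
- **Gene filters:** single-cell, mean CPM strictly > 1; bulk, CPM > 10/L in
  at least N samples with L the minimum library in millions and N the
  smallest group.
- **Variance decomposition:** lowess (frac 0.3) of per-gene variance of
  log2(CPM+1) against the mean is the technical trend; biological =
  total − trend exactly. Retention requires biological > 0 and a one-sided
  F-ratio (total/trend, df = n−1 on both sides, a conservative choice) at
  BH FDR < 0.05.
- **NSC classifier:** pooled within-class SDs offset by their median (s0),
  `m_k = sqrt(1/n_k − 1/n)`, soft-thresholded standardized centroid
  deviations, uniform priors, ties to the first type in declared order.
  The shrinkage delta defaults to the largest value attaining minimal
  stratified 5-fold CV error on a 0–4 grid.
- **Signature:** per-type mean CPM over QC-passing cells, restricted to
  variance-retained genes whose top type mean is ≥ 2× the second —
  a deterministic, testable marker criterion. A warning reports any
  declared type left without specific markers.
- **Deconvolution:** NNLS on a per-gene row-scaled system (each gene's row
  and the mixture divided by the signature row mean). Count noise is
  approximately multiplicative, so row scaling is the natural weighted
  least squares; it raised fraction recovery from r ≈ 0.87 to ≈ 0.99 on the
  mixture benchmark. Coefficients are clipped at zero (NNLS enforces this;
  the ν-SVR backend clips explicitly) and normalized to sum 1. The ν-SVR
  backend (linear kernel, ν ∈ {0.25, 0.5, 0.75} chosen by reconstruction
  correlation on z-scored data) is retained for comparison; NNLS is the
  default and dominates it on noiseless fixtures. Per-sample significance
  permutes the sample's gene values, re-deconvolves, and reports
  `p = (1 + #{null fit r ≥ observed}) / (1 + n_perm)` (never exactly zero),
  100 permutations by default.
- **Normalization contract:** log2(CPM + 0.5) followed by classic quantile
  normalization (rank → cross-sample mean of sorted values, ties averaged).
  Precision weights of the voom procedure are not reproduced: the
  downstream models are ordinary least squares on normalized values, and
  the weights are an internality of that implementation. Quantile
  normalization is exactly idempotent on tie-free columns; with ties the
  pooled reference can shift marginally on re-normalization.
- **Covariate encoding:** RIN dichotomized high (strictly >) at 8.5 / 7.3 /
  7.8 per cohort profile, degradation slope at 5; disease and neuronal
  share mean-centered (which provably lowers the disease–interaction
  design correlation on unbalanced arms); interaction = product of the
  centered columns, AD profile only. The "unknown batch" is a user-declared
  covariate; a PC1-sign split helper is provided and clearly labeled a
  heuristic.
- **Moderation:** residual variances are shrunk once per gene and applied
  to all coefficients. The prior (d0, s0²) comes from moment matching on
  log s² with Newton trigamma inversion (tolerance 1e-8); non-positive
  excess variance yields the d0 = ∞ branch (full shrinkage, handled without
  overflow). Moderated t uses `s̃² = (d0·s0² + d·s²)/(d0 + d)` and d0 + d
  degrees of freedom. The B statistic uses prior DE proportion 0.01 and a
  coefficient prior variance set from the top decile of |moderated t|
  (median excess of t² over 1, returned to the coefficient scale) — the
  hyperparameters are conventions, and B is reported for ranking only.
- **Permutation statistics:** the cross-dataset null shuffles the disease
  column within each cohort and refits with all other covariates fixed;
  each gene is compared to its own null (no pooling). The cross-disease
  null re-pairs the two score vectors by shuffling one of them and pools
  products over permutations and genes. "More extreme" defaults to
  two-sided on |product|: under a symmetric product null this makes the
  permutation FDR uniform, so null calibration holds at every level,
  whereas a sign-directional rule doubles the null call rate (FDR ~
  U(0, 0.5)). The directional variant remains available via
  `tail="directional"`. Contradictory genes are neutralized by the combined
  score's sign rule (S = 0), not by the FDR. Zero FDRs are floored at 1e-5
  before logs, capping |S| at 5. An exhaustive mode enumerates all label
  assignments for small cohorts and scores every cross-pairing.
- **GSEA:** genes ranked by decreasing statistic, ties broken by gene id;
  hit increments |stat|^weight (weight 1 default, 0 = classic KS), miss
  decrements 1/(N−m); the score is the maximum-magnitude running deviation,
  in [−1, 1]. Significance by gene-label permutation (random same-size
  sets) with +1-corrected p per direction and BH across sets within each
  direction; equal-size sets share a null by default (cheap), with
  independent nulls available for calibration studies. Combined-score
  input keeps contradictory genes at exactly 0; all-zero weight sets fall
  back to uniform increments.
- **Drug screen:** Spearman rho per condition over shared genes (≥ 30),
  averaged dose → cell line → compound; the composition filter uses the
  mean of per-condition |rho| against the neuronal scores (the stricter
  reading) and is applied *before* top-k selection. Reversal and induction
  sets are taken disjointly (reversal first), ties broken by compound id.
  The cross-disease map ranks shared compounds by their correlation with
  the cross-disease combined score (signed log FDR of the concordance
  test — using the raw score *product* would be blind to jointly
  down-regulated genes).

## Problem sizes

Experiments run at: 2000-gene, 480-cell references; the four cohort designs
above; 300 mixtures at depth 3.5e5; 1000 permutations for the t-product
null (500 genes), 1e5 for the cross-disease null (2000 genes), 800 random
sets × 1000 permutations for GSEA calibration; 200-compound panels. These
sizes give Monte-Carlo errors comfortably inside the properties being
checked while a full validation sweep completes in well under a minute.
Larger values are plain parameters.

## Limitations

- The generator plants effects that match the fitted model's functional
  form (log-linear in covariates, linear interaction in centered
  variables); it cannot reveal misspecification biases that real data
  might show. The bulk expression of a mixture is, however, genuinely
  nonlinear in the neuronal share, so the composition coefficient is
  fitted against a realistic curved signal.
- Quantile normalization couples genes: with a large marker mass, rank
  displacement leaks a small composition signal into null genes. At the
  default marker fraction this leakage stays at the few-percent level on
  the neuronal coefficient; panels dominated by markers would show more.
- No sequence-level simulation, no probe-level microarray model, no
  cross-platform gene-ID harmonization (exact string match; a mapping
  table hook exists in the pipeline), no absolute cell counts — fractions
  are mRNA shares throughout, and no correction by mRNA content is
  attempted.
- CIBERSORTx's proprietary batch-normalization modes are not reproduced;
  cross-platform deconvolution should be interpreted with that caveat.
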