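# Methods

## Overview

`condcoloc` implements a two-stage strategy for connecting GWAS risk loci to
the genes they may act through:

1. **Conditional cis-eQTL mapping.**  For each gene, variants within the cis
   window (gene body ± 1 Mb) are tested one at a time against
   covariate-adjusted expression by ordinary least squares.  Genome-wide
   significance is controlled with a Benjamini–Hochberg (BH) step-up cutoff
   computed over all first-pass cis tests pooled per chromosome at 5% FDR.
   Genes with a significant first-pass signal enter forward stepwise
   selection: the best variant joins the model, the cis window is re-scanned
   conditioning on it, and further variants are added while their conditional
   p-value stays below the *same fixed cutoff* (the FDR is not re-assessed at
   later steps).  Each selected signal is then isolated by an "all-but-one"
   scan — a cis-wide regression conditioning on every selected eSNP except
   the focal one — which yields summary statistics for that signal alone.

2. **Empirical-Bayes colocalization.**  Each isolated eQTL signature is
   compared with a GWAS signature over the same region under five
   hypotheses: H0 (neither trait associated), H1 (GWAS only), H2 (eQTL
   only), H3 (both, distinct causal variants), H4 (both, one shared causal
   variant).  Per-SNP evidence is a Wakefield asymptotic Bayes factor (WABF)
   from the signed z-score and sampling variance V, averaged on the
   Bayes-factor scale over effect-prior variances W ∈ {0.01, 0.1, 0.5}.
   With a uniform prior on causal position, per-SNP Bayes factors a_j
   (GWAS) and b_j (eQTL) aggregate to locus Bayes factors

       BF(H1) = Σ a_j / K            BF(H2) = Σ b_j / K
       BF(H4) = Σ a_j b_j / K        BF(H3) = (Σa_j Σb_j − Σ a_j b_j) / (K(K−1))

   relative to H0 (BF ≡ 1).  The five mixture proportions Π0..Π4 are
   estimated once from all loci by maximum likelihood and reused as priors
   in the per-locus posterior PPH_i ∝ Π_i · BF(H_i).

## Model assumptions

* One causal variant per trait per locus (the standard coloc assumption).
  Regions with several independent signals violate it — which is exactly why
  the all-but-one conditional scans exist: each isolated signature is
  single-causal by construction.
* The effect prior is Normal(0, W) on the trait scale; averaging over three
  W values makes the evidence robust to effect-size scale.
* Summary statistics of the two traits come from non-overlapping samples
  (no correction for sample overlap is applied).
* Case-control effect sizes are log odds ratios; V then uses
  1/(2·N·s·(1−s)·2·maf·(1−maf)) with s the case fraction.

## Parameters that matter

| parameter | default | notes |
| --- | --- | --- |
| cis window | gene body ± 1 Mb | window for both mapping and coloc |
| FDR (first pass) | 5%, BH per chromosome | cutoff reused for later steps |
| max stepwise steps | 10 | configurable; collinearity guard at r² > 0.99 |
| WABF prior variances | {0.01, 0.1, 0.5} | arithmetic BF-scale average |
| hypothesis priors | empirical (EM) or fixed (0.989, 0.005, 0.005, 0.0005, 0.0005) | per-SNP (p1, p2, p12) conversion available |
| EM tolerance / floor | 1e-8 / 1e-6 | floor keeps the simplex interior |
| GWAS locus definition | p < 1e-6, r² ≥ 0.6 to lead, merged | exclusion list (e.g. MHC) applied after merge |
| palindromic policy | keep if both MAF < 0.42, else drop | see below |
| Storey λ grid | 0.05–0.95 step 0.05, cubic-spline smoothing | π0 read at λ = 0.95 |

## Numerical choices

* All Bayes-factor arithmetic is on the natural-log scale with log-sum-exp;
  BF(H3) uses a guarded log-difference and is −∞ for K = 1 (two distinct
  causal positions cannot exist).
* Per-variant regressions use Frisch–Waugh–Lovell residualization with
  residual degrees of freedom n − p_covariates − 1; this is algebraically
  identical to the full-model OLS coefficient, standard error and t-test
  (verified against statsmodels at 1e−10), not an approximation.
* Stepwise ties at the minimum p are broken by distance to the gene TSS,
  then variant id, so reruns are deterministic.
* A monomorphic dosage yields beta 0, p 1 (flagged); a perfect fit yields
  p clipped to the smallest positive float rather than 0.
* EM log-likelihood is asserted non-decreasing each iteration (1e−9 slack
  for the prior floor's renormalization at machine precision).
* z-scores use beta/se when both are present, else the two-sided Normal
  quantile of p signed by beta.
* Duplicate variants at one position keep the smaller p; the drop is logged.
* Palindromic (A/T, C/G) variants cannot be strand-resolved from allele
  labels.  The record schema carries a minor-allele frequency only, so
  "frequency-informative" is defined as both traits' MAF below 0.42; such
  variants are kept and matched by allele labels, others are dropped.

## What the synthetic data emulate — and what they do not

Genotypes are diploid dosages from block-structured latent-Gaussian
haplotypes: within a block of 10 variants the latent correlation is ρ = 0.7
(dosage-scale r² ≈ 0.2–0.45), blocks are independent, MAF is uniform on
[0.05, 0.5].  Expression and GWAS traits are linear in the planted causal
dosages plus Gaussian noise.  Two effect-size regimes exist:

* `effect_mode="variance"` (default) plants a fixed effect at a stated
  variance explained (default 10% per signal) — the controlled-experiment
  regime used for power and discrimination studies.  At 10% VE and n = 500
  the causal z-score is ≈ 7, comfortably above the fixed stepwise threshold;
  at 5% VE the per-signal power at p < 1e−5 is only ≈ 0.76, so recovery
  studies use the 10% default.
* `effect_mode="prior"` draws each causal effect from Normal(0, w) with w
  drawn uniformly from the same grid the analysis averages over,
  {0.01, 0.1, 0.5} — the exact generative counterpart of the averaged-WABF
  model.  Genome-wide mixture-recovery experiments must use this regime:
  with fixed-magnitude effects (or a single w off the analysis grid) the
  five-hypothesis mixture likelihood is misspecified and its MLE provably
  tilts — we verified a converged point beating the true proportions by
  hundreds of log-likelihood units in the fixed-effect regime.  Cohorts must
  also be large enough that even the w = 0.01 draws are strong
  (z² ≈ 2·n·maf(1−maf)·w), and the causal signal's share of trait variance
  small, since that share deflates realized z-scores relative to the model.

Genome-wide prior-recovery runs therefore use 2,000 loci of 30 SNPs with
cohorts of 5,000 per trait.  These are scaled-down but statistically
faithful stand-ins for real data; what they do **not** emulate: realistic allele-frequency
spectra, long-range LD and recombination-rate variation, expression count
noise and covariate structure, sample overlap between traits, and
polygenic background.  Passing tests therefore demonstrate correctness of
the machinery and calibration under the model's own assumptions, not
performance on any specific cohort.

A known property of the five-hypothesis mixture MLE at this scale: the
H1-vs-H3 (and H2-vs-H3/H4) contrast rests entirely on the null trait's
Bayes-factor profile, whose expectation is 1 under the null; identification
comes from its sub-unit median, so component estimates retain sampling
variability of a few percentage points even at 2,000 loci.

## Replication and π1

Discovery stepwise models are refit as joint regressions in a replication
cohort; a model whose any eSNP is missing there is omitted entirely
(conditioning on an absent marker is undefined).  The share of true
associations among replication p-values is Storey's π1 = 1 − π0 with the
λ-grid spline smoother.

## Tau specificity

Raw expression (counts/CPM/FPKM; never residualized expression, which can
be negative) is summarized per context as log2(stat + 1) — median for
tissue and developmental panels, mean for single-cell panels — and
τ = Σ(1 − x_i/max x)/(n − 1).  Genes missing a context lose it from n
rather than being zero-filled (configurable).

## Known limitations

* No liftover, rsID resolution, INFO filtering, or multi-trait (> 2)
  colocalization; no LD-based fine-mapping (credible sets) — by design the
  method never consumes a reference LD matrix.
* Sample overlap between GWAS and eQTL cohorts is not modeled.
* The locus definition's r² comes from whatever dosage panel the caller
  supplies; a mismatched panel gives mis-sized loci.
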