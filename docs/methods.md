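# Methods

## Model and procedure

The pipeline estimates per-gene expression variability (EV) from a genes ×
samples matrix of raw RNA-seq counts with per-sample metadata (donor group,
treatment dose, matched-triplet id, covariates), under the following
assumptions:

* counts are adequately described by a negative-binomial law per gene and
  stratum, so variability scales with expression (var = μ + φμ²);
* a gene's biological variability of interest is the *excess* spread of its
  normalized counts around the median, after removing the variability
  expected at its expression level;
* unimodal expression: genes occupying two discrete states (on/off between
  donors, strong between-phenotype differential expression) are screened
  out beforehand, because a MAD around a single median mis-describes them;
* the reference donor group (N0) defines "normal" variability; other
  groups are classified against the reference interval, not their own.

Stages, per dose (treatment) stratum:

1. **Normalization.** Median-of-ratios size factors: genes with strictly
   positive counts in all samples form the reference set; a sample's factor
   is the median over those genes of count / geometric mean (computed in log
   space). No variance stabilization is applied afterwards: the EV is kept
   in normalized-count units, so EV magnitudes are directly interpretable on
   the count scale.
2. **Bimodality exclusion** (donor groups pooled per dose). Per gene, a
   two-component normal mixture is fitted by EM to log(count/s) restricted
   to counts ≥ eps; the bimodality index BI = √(π(1−π))·|μ₁−μ₂|/σ_pooled
   with σ_pooled = √(πσ₁² + (1−π)σ₂²) generalizes the classical index to
   unequal component SDs and reduces to it when σ₁ = σ₂. Genes with
   BI ≥ threshold are excluded from that dose's universe.
3. **EV.** Per group × dose: MAD_obs is the median of B bootstrap MADs
   (scaled, constant 1.4826); MAD_pred is a loess of MAD_obs on
   log1p(median expression) fitted within the stratum; EV = MAD_obs −
   MAD_pred. The loess absorbs the mean–variability trend, making EV
   approximately independent of expression magnitude, which is the entire
   point of the statistic.
4. **Classification.** The closed interval median_EV(ref) ± k·MAD_EV(ref)
   (k = 3; MAD_EV again a bootstrap median) is estimated per dose from the
   reference group and applied to every group. EV below/above the interval
   → hypo/hyper; inside or on a boundary → non (boundary-to-non is the
   conservative choice; the interval definition does not dictate one).
5. **Cross-validation.** R times, every donor group is halved at random
   (triplet-stratified when triplet ids exist, so a matched triplet's three
   donors stay in the same half; individual-level splitting is a flag); the
   EV + interval + labelling pipeline is rerun per half with thresholds
   re-estimated from the half's reference samples. The gene universe
   (bimodality filter) stays fixed within splits. A repeat is a success
   when both halves reproduce the whole-data label. One-sided binomial
   p-values (success probability 0.5 under the null) are BH-adjusted per
   group × dose; unconfirmed labels revert to non-variable.
6. **Comparison and downstream.** CV = SD/mean and d = MAD/median are
   computed per stratum and each metric's association with median
   expression is quantified with Kendall's tau-b (tie-corrected — count
   medians tie frequently); tau is reported per group × dose and pooled
   across groups per dose. Confirmed hypo/hyper sets are intersected
   UpSet-style (exclusive membership patterns partitioning the union), and
   over-representation of classified or intersection-unique sets against a
   GMT collection uses the upper-tail hypergeometric test with the
   dose-specific post-filter universe as background and BH adjustment
   within each query.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `B` | 1000 | bootstrap iterations for MAD_obs and MAD_EV |
| `mad_constant` | 1.4826 | normal-consistency scaling of the MAD |
| `loess_span`, `loess_degree` | 0.75, 2 | conventional loess defaults; span is the fraction of genes per local window |
| `bi_threshold` | 1.1 (1.3 stratified) | bimodality exclusion cut-off; the higher value compensates for the noisier index at reduced sample sizes, and stratified pipeline runs switch to it automatically unless overridden |
| `eps`, `zero_percent_thr` | 10, 0.2 | counts below eps are left-censored out of the EM; genes with > 20% such counts cannot be assessed and are retained, flagged ineligible |
| `k` | 3 | interval half-width in reference MAD_EV units |
| `R`, `alpha` | 10, 0.05 | cross-validation repeats and FDR level; note the smallest achievable binomial p is 2⁻ᴿ, so R < 5 can never confirm anything at α = 0.05 |

## The synthetic-data generator

`simulate_counts` emulates the matched case–control irradiation design the
pipeline targets: three donor groups (reference first) × three doses ×
`samples_per_group` matched triplets; negative-binomial counts with
baseline log-means uniform on `mean_log_mu_range` (default log 20 … log
2000, a realistic bulk RNA-seq spread), dispersion trend φ(μ) = a/μ + b
(default a = 3, b = 0.05, chosen so the raw MAD correlates strongly with
expression — the structure the loess stage must remove), and per-sample
size factors uniform on 0.7–1.4. Planted truth:

* **hyper/hypo** genes (defaults 5% each) get their dispersion multiplied /
  divided by 8 in exactly one non-reference group (creating group-exclusive
  sets), at every dose;
* **bimodal** genes (2%) mix two log-means ±`bimodal_shift`/2 (default 1.5)
  with equal weight in all groups; an approximate true BI is recorded via
  the delta method (var log X ≈ 1/μ + φ);
* **DE** genes (5%) get a log-mean shift of ±0.7 in one non-reference
  group.

Dispersion effects are planted only in genes whose baseline log-mean lies
above `effect_expr_quantile` (default 0.5) of the configured range. This is
an identifiability statement, not a convenience: the classification
interval is an absolute EV range anchored at the reference group's median
gene, while the sampling noise of a MAD scales with the gene's own
expression, so an 8-fold dispersion change in a near-noise-floor gene is
statistically invisible at 52 samples per group. Measured
sensitivity-by-expression is near zero below the middle of the log-mean
range and near one above it; planting effects where the design can resolve
them keeps the generator's truth meaningful.

What the generator does **not** emulate: batch effects, library-preparation
artifacts, gene–gene correlation, length bias, or read-level data. Passing
tests therefore demonstrate the pipeline's statistical behaviour under its
own model assumptions, not robustness to real-data artifacts.

All randomness flows from a single seed through named per-stage streams
(numpy `SeedSequence`); per-gene bootstrap streams are keyed by
(seed, group, dose, gene id), so results are independent of gene-subset
composition and identical configurations reproduce artifacts byte for byte.

## Numerical choices

* **EM** (bimodality): initialization from the exact 1-D 2-means split of
  the gene's log values plus four shared random perturbations of a
  symmetric split; convergence at relative log-likelihood change < 1e−8 or
  500 iterations; σ floored at 1e−4 against degenerate spikes; ties between
  restarts broken toward balanced mixing proportions; per-gene
  log-likelihood monotonicity is tracked and exposed. The batch
  implementation runs all genes simultaneously with converged genes
  compacted out, and is exactly equivalent to per-gene fitting.
* **Loess**: tricube weights over the ⌈span·n⌉ nearest neighbours, local
  polynomial via weighted least squares centred at the evaluation point;
  above 500 points the fit is evaluated on a 200-knot quantile grid and
  interpolated linearly, with linear extrapolation beyond the range. The
  fit is linear in the response, so EV is exactly invariant to adding a
  constant to every gene's MAD_obs.
* **Bootstrap**: input sorted before resampling, making MAD_obs invariant
  to sample permutations at a fixed seed.
* **Degenerate inputs**: zero-width reference intervals (all reference EVs
  equal) classify any unequal EV as hypo/hyper without error; genes with
  undefined CV (mean 0) or d (median 0) are flagged NaN, not raised.

## Design decisions taken where the procedure was genuinely open

* The loess response/predictor pair (MAD_obs vs log1p median expression)
  and per-stratum fitting; pooled fitting across groups is available via
  the API by passing a pooled stratum.
* The mixture is fitted on pooled donor groups per dose (a per-group mode
  is available through `filter_bimodal` on a group-restricted matrix).
* Whole-data labels are computed once and reused as the concordance anchor
  inside cross-validation, rather than re-derived per repeat.
* BH adjustment per group × dose stratum, with a pooled flag
  (`pool_bh=True`).
* Counts below eps are dropped (left-censored) rather than imputed;
  ineligible genes are retained rather than excluded, since bimodality
  cannot be assessed for them.

## Problem sizes used by the test and acceptance runs

Decorrelation is demonstrated on 5000 genes × 52 samples/group × 3 groups
× 3 doses at B = 1000; class recovery on 2000 genes × 52 samples/group at
one dose with B = 200, R = 5; bimodality screening on 1000 genes with 5%
planted bimodal genes at the pooled scale of 156 samples; determinism on a
150-gene end-to-end double run. These sizes give stable statistics in a
few minutes on one core.

## Known limitations

* Because EV is an absolute-scale statistic with a global reference
  interval, detection power for dispersion changes grows with expression;
  hypo-variability is intrinsically harder to detect than
  hyper-variability (the downward EV shift is bounded by the Poisson
  floor).
* On data spanning a wide expression range, the heteroscedastic sampling
  noise of EV puts more than the nominal share of reference-group genes
  outside the ±3·MAD_EV interval (≈ 80–87% non rather than > 90%); this
  matches the behaviour of the interval on real data of this design.
* The EM does not model the left-censoring it applies (counts < eps are
  dropped, not integrated over); with heavy censoring the index is simply
  not computed.
* Kendall tau, BH and the hypergeometric test are delegated to
  scipy/statsmodels; the package's own tests verify them against
  brute-force oracles.
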