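# evarseq

Expression variability (EV) analysis for RNA-seq count data.

Most RNA-seq studies compare *mean* expression between groups. This package
quantifies a complementary signal: how *variable* a gene's expression is
across donors, decoupled from how highly the gene is expressed. Naive
variability measures — the coefficient of variation (CV = SD/mean) or the
standardized MAD (d = MAD/median) — are strongly anti-correlated with
expression magnitude on count data, so "variable gene" lists built from them
are largely "lowly expressed gene" lists. The EV statistic removes that
confounding and supports robust hypo-/hyper-variable gene classification
between donor groups, e.g. in matched case–control irradiation designs.

It is aimed at statistical-genomics practitioners who work from Python with
a genes × samples count matrix and per-sample metadata (donor group, dose or
treatment, matched-unit id, covariates).

## The statistic

For each gene, within a donor-group × treatment stratum of size-factor
normalized counts (median-of-ratios normalization):

1. **MAD_obs** — the median over B = 1000 bootstrap resamples of the scaled
   median absolute deviation (constant 1.4826) of the gene's values;
2. **MAD_pred** — a loess (local polynomial regression, degree 2, span 0.75)
   of MAD_obs on log1p(median expression), fitted across the stratum's genes
   and evaluated at this gene's median expression;
3. **EV = MAD_obs − MAD_pred.**

Before EV computation, genes expressed in two discrete states are removed
per dose: a two-component log-normal mixture is fitted per gene by EM
(counts ≥ eps = 10, ineligible if more than 20% fall below), and genes with
bimodality index

    BI = sqrt(π(1−π)) · |μ₁−μ₂| / σ_pooled  ≥ 1.1

are excluded (1.3 for reduced, stratified designs).

Genes are then classified per group × dose against an interval anchored in
the reference group N0:

    hypo  if EV < median_EV(N0) − 3·MAD_EV(N0)
    hyper if EV > median_EV(N0) + 3·MAD_EV(N0)
    non   otherwise,

with MAD_EV again a bootstrap median. Labels are confirmed by split-half
cross-validation: each donor group is halved at random R = 10 times, the
whole pipeline is rerun per half, and a gene's label is kept only when
concordance across splits beats a fair coin (one-sided binomial test,
Benjamini–Hochberg FDR at 0.05); unconfirmed labels revert to non-variable.
Downstream, classified sets are intersected UpSet-style and tested for
over-representation against GMT gene-set collections with the upper-tail
hypergeometric test, using the dose-specific post-filter gene universe as
background.

Because real datasets of this design are rarely public, the package ships a
first-class synthetic-data generator (`evarseq.simulate`) producing
negative-binomial counts with a mean–dispersion trend, per-sample size
factors, matched triplets, and planted hyper-variable, hypo-variable,
bimodal and differentially expressed genes with known truth — every stage is
testable end to end.

## Worked example

```python
import evarseq as ev
from evarseq.ev import EVConfig

cfg = ev.SimConfig(
    n_genes=800, samples_per_group=52, doses=("0",),
    frac_hyper=0.05, frac_hypo=0.05, frac_bimodal=0, frac_de=0, seed=4,
)
counts, metadata, truth = ev.simulate_counts(cfg)
s = ev.compute_size_factors(counts)
cls = ev.crossvalidate(
    counts, metadata, s, list(counts.index), EVConfig(B=200, seed=4),
    reference_group="N0", R=5, seed=4,
)
print(cls.groupby("group")["label_confirmed"].value_counts().unstack(fill_value=0))
```

prints

```
label_confirmed  hyper  hypo  non
group
N0                   4     4  792
N1                  21    35  744
N2+                 20    28  752
```

The planted dispersion effects sit in the non-reference groups, and the
cross-validated classification recovers them there (confirmed-hyper
sensitivity 1.00, confirmed-hypo 0.95 against the generator's truth in this
run), while the reference group stays almost entirely non-variable. On
trend-only data the decorrelation is visible directly: tau(CV, median
expression) ≈ −0.68 versus tau(EV, median expression) ≈ −0.03
(`examples/02_expression_variability.py`).

The `examples/` directory has one short script per capability: simulation,
EV + metric comparison, bimodality screening, classification with
cross-validation, enrichment, and the full pipeline. A thin CLI mirrors the
pipeline (`evarseq simulate`, `evarseq run-all --config cfg.yaml`, ...).

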