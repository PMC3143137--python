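# pathmeta

Cross-cohort profiling of oncogenic pathway activation in tumour expression
data. `pathmeta` implements the complete analytical workflow of a
multi-cohort biomarker study in ovarian carcinoma — but every stage is a
reusable, tested library function that works on any collection of
pre-normalized log-scale expression matrices:

- **Signature activation scoring** — for a gene signature with signed
  regression coefficients, the per-sample score is
  `raw_s = b0 + Σ_g w_g · x_{g,s}` over the signature genes present in the
  dataset, standardized to median 0 / SD 1 for cross-platform comparability.
- **Informative-gene filtering** — the two microarray filters used on the
  source cohorts: keep genes with maximum log expression ≥ 7 and
  across-sample variance ≥ 0.5, or with expression ≥ log2(100) in ≥ 25% of
  samples; plus highest-mean probe-to-gene collapse.
- **Perturbation-score derivation** — PCA on a small gene panel in a
  treated-vs-naive experiment, a label-permutation test of the Euclidean
  distance between class centroids in the PC1–PC2 plane, and conversion of
  the PC1 loadings into an activation score validated by Mann–Whitney group
  comparison and correlation with incubation time (the VEGF-A/HUVEC design).
- **Survival association** — univariate Cox proportional hazards for the
  continuous standardized score (Newton–Raphson on the Breslow partial
  likelihood, Efron optional), reporting the hazard ratio per SD with Wald
  95% CI.
- **Random-effects meta-analysis** — DerSimonian–Laird pooling of Pearson
  correlations (SE = (1 − ρ²)/√(n − 1); raw-ρ or Fisher-z scale) and of log
  hazard ratios, with Q, τ², per-study weights and numeric forest tables.
- **Synthetic multi-cohort generator** — six cohorts of unequal size and
  platform coverage driven by correlated latent pathway activations that
  also drive exponential survival and chemoresponse labels, so the whole
  pipeline is testable end to end without any downloads.

## Worked example

Pooling the published per-cohort correlations between the β-Catenin
activation score and the wound-healing-response (WHR) signature
(`python examples/pool_published_correlations.py`):

```
beta-Catenin vs WHR
         study  estimate    se  ci_low  ci_high  weight_pct     q    df  tau2
        Quebec     0.650 0.132   0.390    0.910       2.032   NaN   NaN   NaN
North Carolina     0.810 0.033   0.745    0.875      31.967   NaN   NaN   NaN
     Melbourne     0.730 0.036   0.659    0.801      26.809   NaN   NaN   NaN
       Niigata     0.770 0.039   0.694    0.846      23.457   NaN   NaN   NaN
      Boston A     0.830 0.062   0.708    0.952       9.213   NaN   NaN   NaN
      Boston B     0.750 0.074   0.605    0.895       6.522   NaN   NaN   NaN
        pooled     0.774 0.019   0.737    0.811     100.000 4.419 5.000 0.000
pooled rho = 0.774 [0.737, 0.811], Q = 4.42 on 5 df, tau2 = 0.0000
```

Each row is one cohort's Pearson ρ with its CI and random-effects weight;
the pooled row is the DerSimonian–Laird consensus correlation across 464
patients, with Q and τ² quantifying between-cohort heterogeneity (here
essentially none).

The other example scripts cover the remaining capabilities, each printing
and explaining its numbers:

- `examples/score_and_standardize.py` — filtering, scoring and
  standardization on a synthetic cohort, with recovery of the true latent
  activation (ρ ≈ 0.99 at default noise).
- `examples/derive_perturbation_score.py` — PCA derivation, permutation
  test, and validation of a perturbation-response score on an independent
  simulated experiment.
- `examples/end_to_end_meta_analysis.py` — the manifest-driven pipeline on
  six synthetic cohorts: pooled correlations, pooled hazard ratios
  (recovering the planted protective pathway, pooled HR ≈ 0.77 with CI
  excluding 1), chemoresponse comparisons and the final signature
  classification.

A thin CLI wraps the pipeline for shell use:

```sh
pathmeta simulate --out sim/ --seed 1
pathmeta run --manifest sim/manifest.yaml --out results/ --seed 1
pathmeta derive-score --train sim/huvec_expression.tsv \
    --train-labels sim/huvec_labels.tsv --panel sim/panel.txt \
    --permutations 10000 --seed 1 --out derived/
```

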