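# Methods

## The analytical model

`pathmeta` treats a pathway gene signature as a linear read-out of
expression: each signature gene carries a signed regression coefficient
(sign = direction of the gene's association with pathway activation,
magnitude = weight) and the per-sample raw score is the intercept plus the
coefficient-weighted sum of log-scale expression over the signature genes
measured on that platform. Genes absent from a dataset are skipped rather
than imputed; the number actually used is recorded per dataset so coverage
loss across platforms is auditable.

Scores are standardized per dataset by median-centering and dividing by the
sample SD (n − 1 denominator). Standardization serves two purposes: it puts
scores from different platforms on one scale (so a Cox hazard ratio is "per
SD of activation" everywhere), and it makes the intercept mathematically
inert — any constant is absorbed by the median. The intercept is therefore
honoured in raw scores (some published signatures scale their weighted sums
through an intercept) but provably cannot affect any downstream statistic,
which is also checked by a shift-invariance test. Scores are analysed as
continuous variables throughout; no dichotomization is offered on the
pipeline path.

## Informative-gene filters

Two filters reproduce the conventions used on the source cohorts, applied
before scoring:

- **expression/variance filter** (`filter_expr_variance`): keep genes with
  aggregate log expression ≥ 7 and across-sample variance ≥ 0.5 (unbiased,
  n − 1). The aggregation of "log expression ≥ 7" over samples is not fully
  determined by the source description; the default is the per-gene
  **maximum** (a gene strongly expressed in any subgroup is informative),
  with `mean` and `min` available so other conventions can be matched
  empirically against a known survivor count.
- **presence filter** (`filter_expr_presence`): keep genes with expression
  ≥ log2(100) in ≥ 25% of samples. Both comparisons are inclusive.

Both filters only change membership, never values, and are idempotent.
Probe-to-gene collapse keeps the probe with the highest mean expression
(deterministic; ties broken by lexicographically smallest probe id).

## Perturbation-score derivation

Given a treated-vs-naive experiment and a small gene panel, the panel is
first reduced to informatively measured genes via the presence filter (the
source procedure's signal-to-noise criterion is unspecified; the presence
filter is the package's concrete stand-in and is configurable). PCA is run
on the covariance of the panel expression — covariance rather than
correlation because log-scale microarray panels are already on a common
scale; a correlation-based switch exists. The score model is the unit-norm
PC1 loading vector. PC sign indeterminacy is resolved by requiring the
treated-mean score ≥ naive-mean score, which makes the derived quantity an
*activation* score by construction; the orientation flag flips loadings and
scores jointly, and rank-based group tests and |ρ| are invariant to it.

Class segregation is tested by permuting treatment labels with the PC1–PC2
embedding fixed and comparing the observed Euclidean distance between class
centroids to its permutation null. The p-value uses the add-one estimator
p = (1 + #{null ≥ observed})/(B + 1), so p ∈ [1/(B+1), 1], never zero, and
is exactly reproducible given (B, seed). B defaults to 10,000. The embedding
distance uses exactly two components, matching the 2-D representation the
derivation is defined on. The ten-gene panel used in the original
VEGF-A/HUVEC derivation ships as `VEGF_PANEL`.

## Survival association

The univariate Cox model is maximized by Newton–Raphson on the partial
likelihood with Breslow tie handling (Efron available); with continuous
standardized scores ties are rare and the two agree closely. Convergence is
declared when the Newton step falls below 1e-8 (at most 50 iterations);
steps are clamped to ±5 for stability far from the optimum, and |β| > 20 is
treated as monotone likelihood ("separation detected") since e^20 per SD is
beyond any biologically meaningful hazard ratio. The SE comes from the
observed information at the optimum; CIs and p-values are Wald-based because
the pooling stage consumes a (log-HR, SE) pair. Cohorts with different
endpoints (PFS vs OS) are pooled together by default, mirroring the design
the package reimplements; endpoint labels are carried as metadata and a flag
allows stratified pooling.

## Random-effects meta-analysis

Study effects are pooled with the DerSimonian–Laird moment estimator: fixed
weights w_i = 1/se_i², Q = Σ w_i(θ_i − θ_fixed)², τ² = max(0, (Q − df)/C)
with C = Σw − Σw²/Σw, random weights 1/(se_i² + τ²). Correlations pool by
default on the **raw ρ scale** with the study-level standard error
SE = (1 − ρ²)/√(n − 1) — the formula is stated on the ρ scale by the
methodology this package follows — with Fisher-z (variance 1/(n − 3),
back-transformed pooled value) available by flag; the two agree within 0.02
for small effects (|ρ| ≤ 0.3, n ≥ 50), which is tested. Hazard ratios pool
on the log scale and are reported exponentiated. 95% CIs use the
conventional 1.96 normal quantile on the pooling scale. A single study
passes through with τ² = 0 and a CI from its own SE.

The exact random-effects variant of the original meta-analysis software is
unreported; independent DerSimonian–Laird computations on the published
per-cohort inputs land within about 0.05–0.07 of the printed pooled
correlations, which is the tolerance used when those values are checked.

Across the default panel of 20 pathway signatures, correlation significance
is flagged at the Bonferroni threshold 0.05/20 = 0.0025.

## Synthetic data generator

`generate_collection` emulates the statistical structure the analysis
assumes, not microarray physics. Per sample, latent activations (one per
signature) are standard normal with a common configurable correlation
(default 0.6) emulating pathway/prognostic-signature coupling; signature
genes occupy disjoint blocks with ±1 coefficients and expression
baseline + effect·a·sign + Gaussian noise. Survival is exponential with
hazard ∝ exp(Σ β_k a_k) and independent exponential censoring tuned to the
target censoring fraction (default 0.3); chemoresponse labels are Bernoulli
with log-odds proportional to a proliferation-like latent, generated for the
first (smallest) cohort as in the design being emulated. Platform
heterogeneity enters through per-dataset random gene dropout (default 15%)
and a per-dataset noise multiplier.

Default study conditions: six cohorts of sizes (20, 107, 165, 110, 26, 36)
— the sizes of the cohorts in the study the pipeline re-implements — one
pathway plus three prognostic signatures of 20 genes each out of 500 genes
total, activation effect 1.0 log2-units per SD of latent activation, noise
SD 0.5, and a protective pathway with true log-HR −0.3 per SD. The gene
count is kept at 500 (rather than array scale) because signature scoring
touches only signature genes; background genes exist to exercise the
filters. Gene baselines (mean 9, SD 1 log2 units) sit above the filter
thresholds so signature genes survive filtering, as informative genes do on
real arrays.

The time-course generator (`generate_huvec_experiment`) shifts panel genes
linearly with incubation time in treated samples only, with a fixed
alternating up/down response direction — the direction is biology shared by
every experiment, deliberately not seed-dependent, so a score model derived
on one simulated experiment transfers to another. Treated incubation times
cycle the nonzero grid points (4, 8, 24 h); naive samples sit at 0 h. The
maximal shift defaults to 2 log2-units at 24 h, i.e. a mean treated-group
shift of about twice the noise SD — a strong, saturating perturbation
response.

What the generator does **not** emulate: probe-level effects, batch and
normalization artifacts, non-proportional hazards, informative censoring,
non-Gaussian expression noise, and signatures whose genes overlap. Passing
tests therefore demonstrate correctness of the statistical machinery under
the model's own assumptions, not robustness to real-data violations of
them.

## Numerical choices and degenerate inputs

- Standardization requires ≥ 2 samples and a nonzero SD ("degenerate score
  distribution" otherwise); scoring requires ≥ 1 overlapping gene, with the
  signature and dataset named in the error.
- Mann–Whitney comparisons use exact enumeration when the combined n ≤ 20
  with no ties, else the normal approximation with tie and continuity
  correction.
- Numerically perfect correlations are clamped to ±(1 − 1e-12) so the SE
  stays positive and the record remains poolable.
- Probe-collapse and filter tie-breaks are deterministic (lexicographic /
  inclusive comparisons), and every stochastic step takes an explicit seed;
  reports rerun from the same manifest and seed are byte-identical.

## Scope and limitations

Reproducing the numbers that depend on the original microarray accessions
(informative-probe counts of specific cohorts, the observed HUVEC centroid
distance 2.185, score medians, the incubation-time correlation) requires
those downloads and is out of scope; the package exposes the exact filter
defaults (7 / 0.5; log2(100) / 25%), the aggregation switch, the ten-gene
panel and the derivation options needed to attempt them. The published
coefficient tables of the oncogenic and prognostic signatures are external
supplements: they are consumed as ordinary signature files, and sources that
publish only up/down gene lists can be used via ±1 coefficients
(`GeneSignature.from_gene_lists`). Multivariate or stratified Cox models,
proportionality diagnostics, publication-bias diagnostics and figure
rendering are out of scope; forest output is a numeric table.
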