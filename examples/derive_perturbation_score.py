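"""Derive an activation score from a treated-vs-naive perturbation time course.

Simulates a cell-line experiment in which panel genes shift with incubation
time under treatment, fits a PCA on the panel, tests treated/naive
segregation with a label-permutation test on the centroid distance, converts
PC1 loadings into an activation score, and validates the score on an
independent experiment from the same biology.
"""

from pathmeta import SimulationConfig, generate_huvec_experiment, run_vegf_derivation

train = generate_huvec_experiment(SimulationConfig(seed=11))
validate = generate_huvec_experiment(SimulationConfig(seed=12))
panel = [g for g in train.dataset.gene_ids if g.startswith("PG")]

report = run_vegf_derivation(train, panel, [validate], B=10_000, seed=11)

perm = report.permutation
print(
    f"centroid distance: observed {perm.observed_distance:.3f} vs "
    f"null mean {perm.expected_distance:.3f} (p = {perm.p_value:.2e}) — "
    "a small p says treated and naive samples segregate in the PC1-PC2 plane"
)
print(report.validation.to_string(index=False, float_format="%.4f"))
print(
    "median_treated > median_naive and a positive time_rho mean the derived "
    "score rises with treatment and with incubation time"
)
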