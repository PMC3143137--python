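"""Pool the published six-cohort correlations of the beta-Catenin score.

Each ovarian carcinoma cohort reports a Pearson correlation between the
beta-Catenin pathway activation score and a prognostic signature score
(WHR/IGS/GGI).  Study standard errors use SE = (1 - rho^2)/sqrt(n - 1) and
the studies are combined under a DerSimonian-Laird random-effects model.
The pooled rho is the cross-platform consensus strength of the association;
tau2 quantifies the between-cohort heterogeneity around it.
"""

from pathmeta import forest_table, pool_random_effects
from pathmeta.published import beta_catenin_effects

for prognostic in ("WHR", "IGS", "GGI"):
    effects = beta_catenin_effects(prognostic)
    pooled = pool_random_effects(effects, scale="raw_rho")
    print(f"\nbeta-Catenin vs {prognostic}")
    print(forest_table(pooled, effects).to_string(index=False, float_format="%.3f"))
    print(
        f"pooled rho = {pooled.pooled_natural:.3f} "
        f"[{pooled.ci95_natural[0]:.3f}, {pooled.ci95_natural[1]:.3f}], "
        f"Q = {pooled.q:.2f} on {pooled.df} df, tau2 = {pooled.tau2:.4f}"
    )
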