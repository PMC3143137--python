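"""Published six-cohort inputs for the worked meta-analysis example.

These are the per-cohort Pearson correlations between the beta-Catenin
pathway activation score and the three prognostic signatures (wound healing
response WHR, invasiveness gene signature IGS, genomic grade index GGI), as
reported for a meta-analysis of six advanced serous ovarian carcinoma
cohorts, together with each cohort's sample size and endpoint.  They serve
as ready-made study-level effects for the pooling machinery; no expression
data is involved.
"""

from __future__ import annotations

from .meta import EffectRecord, correlation_se

__all__ = [
    "OVARIAN_COHORTS",
    "BETA_CATENIN_RHO",
    "beta_catenin_effects",
]

#: (cohort, n, platform, endpoint) of the six ovarian carcinoma cohorts
OVARIAN_COHORTS = (
    ("Quebec", 20, "Agilent Human 1A (v2)", "PFS"),
    ("North Carolina", 107, "Affymetrix U133_plus2", "OS"),
    ("Melbourne", 165, "Affymetrix U133_plus2", "PFS"),
    ("Niigata", 110, "Agilent Whole Human Genome", "PFS"),
    ("Boston A", 26, "Affymetrix U133_plus2", "PFS"),
    ("Boston B", 36, "Affymetrix U95_A2", "PFS"),
)

#: per-cohort Pearson rho of the beta-Catenin score vs each prognostic signature
BETA_CATENIN_RHO = {
    "WHR": (0.65, 0.81, 0.73, 0.77, 0.83, 0.75),
    "IGS": (0.62, 0.89, 0.54, 0.73, 0.48, 0.56),
    "GGI": (0.67, 0.60, 0.79, 0.79, 0.87, 0.26),
}


def beta_catenin_effects(prognostic: str) -> list[EffectRecord]:
    """Study-level correlation effects of the beta-Catenin score against one
    prognostic signature (``WHR``/``IGS``/``GGI``), with standard errors from
    SE = (1 - rho^2)/sqrt(n - 1)."""
    if prognostic not in BETA_CATENIN_RHO:
        raise KeyError(f"prognostic must be one of {sorted(BETA_CATENIN_RHO)}")
    return [
        EffectRecord(
            study=name,
            kind="correlation",
            estimate=rho,
            se=correlation_se(rho, n),
            n=n,
        )
        for (name, n, _, _), rho in zip(OVARIAN_COHORTS, BETA_CATENIN_RHO[prognostic])
    ]
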