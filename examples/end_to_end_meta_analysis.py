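"""Full pipeline on a synthetic six-cohort collection.

Simulates six cohorts of realistic, unequal sizes in which a protective
pathway (true log-HR -0.3 per SD of activation) also correlates with three
proliferation-like prognostic signatures, writes them to disk in the TSV
formats the pipeline reads, and runs the manifest-driven meta-analysis:
filtering, scoring, per-cohort correlations and Cox fits, random-effects
pooling, chemoresponse comparisons and the final signature classification.
"""

import tempfile
from pathlib import Path

from pathmeta import (
    AnalysisManifest,
    DatasetSpec,
    SimulationConfig,
    generate_collection,
    run_meta_pipeline,
    write_clinical_table,
    write_expression_matrix,
    write_signatures,
)

coll = generate_collection(SimulationConfig(seed=1))

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    specs = []
    for ds, clin in zip(coll.datasets, coll.clinical):
        write_expression_matrix(ds, tmp / f"{ds.name}.tsv")
        write_clinical_table(clin, tmp / f"{ds.name}_clinical.tsv")
        specs.append(
            DatasetSpec(
                name=ds.name,
                expression=str(tmp / f"{ds.name}.tsv"),
                clinical=str(tmp / f"{ds.name}_clinical.tsv"),
            )
        )
    write_signatures(coll.signatures, tmp / "signatures.tsv")
    manifest = AnalysisManifest(datasets=specs, signatures=str(tmp / "signatures.tsv"), seed=1)
    report = run_meta_pipeline(manifest)

print("pooled correlations (pathway score vs prognostic signatures):")
print(report.pooled_correlations.to_string(index=False, float_format="%.3f"))
print("\npooled hazard ratios (per SD of standardized score):")
print(report.pooled_hazards.to_string(index=False, float_format="%.3f"))
print("\nchemoresponse comparisons in the labelled cohort:")
print(report.chemoresponse.to_string(index=False, float_format="%.3f"))
print("\nsignature classification:")
print(report.summary.to_string(index=False))
print(
    "\npooled_hr < 1 with a CI excluding 1 recovers the protective effect "
    "the generator planted; 'both' flags signatures that are survival-"
    "associated and correlated with all three prognostic signatures"
)
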