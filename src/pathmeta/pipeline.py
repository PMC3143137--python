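"""Manifest-driven orchestration of the full meta-analytic workflow.

``run_meta_pipeline`` takes a manifest naming expression/clinical file pairs
and a signature file, then per dataset: filters informative genes, scores
every signature, standardizes; per pathway signature: correlates with each
prognostic signature, fits a univariate Cox model against the dataset's
endpoint; pools correlations and hazard ratios across datasets under a
random-effects model; compares scores between chemoresponse groups where
labels exist; and classifies signatures by survival association and
prognostic-signature correlation.  All outputs are plain TSV plus a JSON
run-metadata file, and are byte-identical across reruns with the same
manifest and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    ClinicalTable,
    ExpressionDataset,
    LOG2_100,
    filter_expr_presence,
    filter_expr_variance,
    read_clinical_table,
    read_expression_matrix,
    read_signatures,
)
from .meta import (
    EffectRecord,
    bonferroni_threshold,
    forest_table,
    pearson_correlation,
    pool_hazard_ratios,
    pool_random_effects,
)
from .scoring import (
    ActivationScoreSet,
    compare_groups,
    score_signature,
    standardize_scores,
)
from .survival import fit_cox_univariate
from .vegf import (
    PerturbationExperiment,
    apply_derived_score,
    centroid_permutation_test,
    correlate_with_time,
    fit_pca_panel,
)

logger = logging.getLogger("pathmeta")

__all__ = [
    "DatasetSpec",
    "PipelineOptions",
    "AnalysisManifest",
    "PipelineReport",
    "run_meta_pipeline",
    "run_vegf_derivation",
]


@dataclass
class DatasetSpec:
    name: str
    expression: str
    clinical: str | None = None
    endpoint: str | None = None
    dialect: str = "tsv_genes_by_samples"
    platform: str = ""


@dataclass
class PipelineOptions:
    pooling_scale: str = "raw_rho"
    permutations: int = 10_000
    prognostic: Sequence[str] = ("WHR", "GGI", "IGS")
    apply_variance_filter: bool = True
    apply_presence_filter: bool = True
    min_log_expr: float = 7.0
    min_variance: float = 0.5
    presence_threshold: float = LOG2_100
    presence_fraction: float = 0.25
    expr_aggregate: str = "max"
    cox_ties: str = "breslow"
    n_tests: int = 20
    endpoint_stratified: bool = False


@dataclass
class AnalysisManifest:
    datasets: list[DatasetSpec]
    signatures: str
    output_dir: str | None = None
    panel: str | None = None
    seed: int = 0
    options: PipelineOptions = field(default_factory=PipelineOptions)

    def __post_init__(self) -> None:
        names = [d.name for d in self.datasets]
        if len(set(names)) != len(names):
            raise ValueError("dataset names must be unique")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisManifest":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        ds = []
        for entry in raw.get("datasets", []):
            entry = dict(entry)
            entry["expression"] = str(base / entry["expression"])
            if entry.get("clinical"):
                entry["clinical"] = str(base / entry["clinical"])
            ds.append(DatasetSpec(**entry))
        opts = PipelineOptions(**raw.get("options", {}))
        return cls(
            datasets=ds,
            signatures=str(base / raw["signatures"]),
            panel=str(base / raw["panel"]) if raw.get("panel") else None,
            output_dir=raw.get("output_dir"),
            seed=int(raw.get("seed", 0)),
            options=opts,
        )

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("output_dir", None)  # where results land is not analysis config
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineReport:
    """All result tables of one pipeline run."""

    scores: pd.DataFrame
    correlations: pd.DataFrame
    pooled_correlations: pd.DataFrame
    survival: pd.DataFrame
    pooled_hazards: pd.DataFrame
    forest: pd.DataFrame
    chemoresponse: pd.DataFrame
    summary: pd.DataFrame
    coverage: pd.DataFrame
    metadata: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "scores": self.scores,
            "correlations": self.correlations,
            "pooled_correlations": self.pooled_correlations,
            "survival": self.survival,
            "pooled_hazards": self.pooled_hazards,
            "forest": self.forest,
            "chemoresponse": self.chemoresponse,
            "summary": self.summary,
            "coverage": self.coverage,
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in self.tables().items():
            frame.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.10g")
        with open(out / "run_metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True)


def _apply_filters(ds: ExpressionDataset, opt: PipelineOptions) -> ExpressionDataset:
    if opt.apply_variance_filter:
        ds = filter_expr_variance(
            ds, opt.min_log_expr, opt.min_variance, aggregate=opt.expr_aggregate
        )
    if opt.apply_presence_filter:
        ds = filter_expr_presence(ds, opt.presence_threshold, opt.presence_fraction)
    return ds


def _load_dataset(spec: DatasetSpec) -> tuple[ExpressionDataset, ClinicalTable | None]:
    try:
        ds = read_expression_matrix(
            spec.expression, dialect=spec.dialect, name=spec.name, platform=spec.platform
        )
        clin = read_clinical_table(spec.clinical) if spec.clinical else None
    except Exception as exc:  # abort with a named error per spec contract
        raise RuntimeError(f"failed to load dataset {spec.name!r}: {exc}") from exc
    return ds, clin


def run_meta_pipeline(
    manifest: AnalysisManifest,
    datasets: Sequence[ExpressionDataset] | None = None,
    clinical: Sequence[ClinicalTable | None] | None = None,
) -> PipelineReport:
    """Run the full score -> correlate -> survival -> pool -> report workflow.

    ``datasets``/``clinical`` may be passed directly (already-loaded objects,
    e.g. from the simulator), otherwise they are read from the manifest
    paths.  Returns the report bundle; if the manifest names an output
    directory the TSVs and run metadata are also written there.
    """
    opt = manifest.options
    signatures = read_signatures(manifest.signatures)
    prognostic = [s for s in opt.prognostic if s in signatures]
    pathways = [s for s in signatures if s not in set(prognostic)]

    if datasets is None:
        loaded = [_load_dataset(spec) for spec in manifest.datasets]
        datasets = [ds for ds, _ in loaded]
        clinical = [cl for _, cl in loaded]
    elif clinical is None:
        clinical = [None] * len(datasets)

    score_rows, coverage_rows = [], []
    corr_records: dict[tuple[str, str], list[EffectRecord]] = {}
    hr_effects: dict[str, list] = {}
    surv_rows, chemo_rows = [], []

    for spec, ds, clin in zip(manifest.datasets, datasets, clinical):
        filtered = _apply_filters(ds, opt)
        scored = {}
        for sig_name, sig in signatures.items():
            try:
                scores = standardize_scores(score_signature(filtered, sig))
            except ValueError as exc:
                logger.warning(
                    "signature %s skipped on dataset %s: %s", sig_name, ds.name, exc
                )
                continue
            scored[sig_name] = scores
            score_rows.append(scores.to_frame().assign(dataset=ds.name))
            coverage_rows.append(
                {
                    "dataset": ds.name,
                    "signature": sig_name,
                    "genes_in_signature": len(sig.entries),
                    "genes_used": scores.genes_used,
                }
            )

        for pw in pathways:
            if pw not in scored:
                continue
            for pg in prognostic:
                if pg not in scored:
                    continue
                rec = pearson_correlation(
                    scored[pw].standardized, scored[pg].standardized, study=ds.name
                )
                corr_records.setdefault((pw, pg), []).append(rec)

        if clin is not None:
            aligned = clin.aligned_to(filtered.sample_ids)
            has_surv = aligned["time"].notna() & aligned["event"].notna()
            endpoint = spec.endpoint or (
                aligned["endpoint"].dropna().iloc[0] if aligned["endpoint"].notna().any() else "PFS"
            )
            for sig_name, scores in scored.items():
                mask = has_surv.to_numpy()
                if mask.sum() < 3:
                    continue
                try:
                    eff = fit_cox_univariate(
                        scores.standardized[mask],
                        aligned["time"].to_numpy(dtype=float)[mask],
                        aligned["event"].to_numpy(dtype=float)[mask],
                        ties=opt.cox_ties,
                        study=ds.name,
                        signature=sig_name,
                    )
                except ValueError as exc:
                    logger.warning(
                        "Cox fit skipped for %s on %s: %s", sig_name, ds.name, exc
                    )
                    continue
                hr_effects.setdefault(sig_name, []).append(eff)
                surv_rows.append(
                    {
                        "dataset": ds.name,
                        "signature": sig_name,
                        "endpoint": endpoint,
                        "n": eff.n,
                        "events": eff.events,
                        "log_hr": eff.log_hr,
                        "se": eff.se,
                        "hr": eff.hr,
                        "ci_low": eff.ci95[0],
                        "ci_high": eff.ci95[1],
                        "p": eff.p_value,
                    }
                )

            chemo = aligned["chemoresponse"].fillna("unknown")
            labelled = chemo.isin(["sensitive", "resistant"]).to_numpy()
            if labelled.sum() >= 4 and len(set(chemo[labelled])) == 2:
                for sig_name, scores in scored.items():
                    subset = ActivationScoreSet(
                        signature=sig_name,
                        sample_ids=[s for s, m in zip(scores.sample_ids, labelled) if m],
                        raw=scores.raw[labelled],
                        standardized=scores.standardized[labelled],
                        genes_used=scores.genes_used,
                    )
                    cmp = compare_groups(subset, chemo[labelled].to_numpy())
                    chemo_rows.append(
                        {
                            "dataset": ds.name,
                            "signature": sig_name,
                            "median_sensitive": cmp.medians.get("sensitive", np.nan),
                            "median_resistant": cmp.medians.get("resistant", np.nan),
                            "n_sensitive": cmp.n_per_group.get("sensitive", 0),
                            "n_resistant": cmp.n_per_group.get("resistant", 0),
                            "u_statistic": cmp.statistic,
                            "p": cmp.p_value,
                        }
                    )

    threshold = bonferroni_threshold(opt.n_tests)
    pooled_corr_rows = []
    for (pw, pg), recs in sorted(corr_records.items()):
        pooled = pool_random_effects(recs, scale=opt.pooling_scale)
        pooled_corr_rows.append(
            {
                "pathway": pw,
                "prognostic": pg,
                "n_studies": len(recs),
                "pooled_rho": pooled.pooled_natural,
                "ci_low": pooled.ci95_natural[0],
                "ci_high": pooled.ci95_natural[1],
                "q": pooled.q,
                "tau2": pooled.tau2,
                "p": pooled.p_value,
                "significant": pooled.p_value < threshold,
            }
        )

    pooled_hr_rows, forest_frames = [], []
    for sig_name, effs in sorted(hr_effects.items()):
        pooled = pool_hazard_ratios(effs)
        pooled_hr_rows.append(
            {
                "signature": sig_name,
                "n_studies": len(effs),
                "pooled_hr": pooled.pooled_natural,
                "ci_low": pooled.ci95_natural[0],
                "ci_high": pooled.ci95_natural[1],
                "q": pooled.q,
                "tau2": pooled.tau2,
                "p": pooled.p_value,
            }
        )
        recs = [
            EffectRecord(study=e.study, kind="log_hr", estimate=e.log_hr, se=e.se, n=e.n)
            for e in effs
        ]
        forest_frames.append(forest_table(pooled, recs).assign(signature=sig_name))

    pooled_corr = pd.DataFrame(
        pooled_corr_rows,
        columns=[
            "pathway", "prognostic", "n_studies", "pooled_rho", "ci_low",
            "ci_high", "q", "tau2", "p", "significant",
        ],
    )
    pooled_hr = pd.DataFrame(
        pooled_hr_rows,
        columns=["signature", "n_studies", "pooled_hr", "ci_low", "ci_high", "q", "tau2", "p"],
    )

    # Venn-style classification of pathway signatures
    summary_rows = []
    for pw in pathways:
        hr_row = pooled_hr[pooled_hr["signature"] == pw]
        surv_assoc = bool(len(hr_row)) and bool((hr_row["p"] < 0.05).iloc[0])
        sub = pooled_corr[pooled_corr["pathway"] == pw]
        corr_all = len(sub) == len(prognostic) and bool(sub["significant"].all()) and len(prognostic) > 0
        summary_rows.append(
            {
                "signature": pw,
                "survival_associated": surv_assoc,
                "correlated_all_prognostic": corr_all,
                "both": surv_assoc and corr_all,
            }
        )

    metadata = {
        "package": "pathmeta",
        "version": __version__,
        "seed": manifest.seed,
        "config_hash": manifest.config_hash(),
        "n_datasets": len(manifest.datasets),
        "signatures": list(signatures),
        "prognostic": list(prognostic),
        "pooling_scale": opt.pooling_scale,
        "bonferroni_threshold": threshold,
    }

    report = PipelineReport(
        scores=(
            pd.concat(score_rows, ignore_index=True)
            if score_rows
            else pd.DataFrame(columns=["sample_id", "signature", "raw", "standardized", "genes_used", "dataset"])
        ),
        correlations=pd.DataFrame(
            [
                {
                    "dataset": r.study,
                    "pathway": pw,
                    "prognostic": pg,
                    "rho": r.estimate,
                    "n": r.n,
                    "se": r.se,
                    "p": r.p_value,
                }
                for (pw, pg), recs in sorted(corr_records.items())
                for r in recs
            ],
            columns=["dataset", "pathway", "prognostic", "rho", "n", "se", "p"],
        ),
        pooled_correlations=pooled_corr,
        survival=pd.DataFrame(
            surv_rows,
            columns=[
                "dataset", "signature", "endpoint", "n", "events", "log_hr",
                "se", "hr", "ci_low", "ci_high", "p",
            ],
        ),
        pooled_hazards=pooled_hr,
        forest=(
            pd.concat(forest_frames, ignore_index=True)
            if forest_frames
            else pd.DataFrame(columns=["study", "estimate", "se", "ci_low", "ci_high", "weight_pct", "q", "df", "tau2", "signature"])
        ),
        chemoresponse=pd.DataFrame(
            chemo_rows,
            columns=[
                "dataset", "signature", "median_sensitive", "median_resistant",
                "n_sensitive", "n_resistant", "u_statistic", "p",
            ],
        ),
        summary=pd.DataFrame(
            summary_rows,
            columns=["signature", "survival_associated", "correlated_all_prognostic", "both"],
        ),
        coverage=pd.DataFrame(
            coverage_rows,
            columns=["dataset", "signature", "genes_in_signature", "genes_used"],
        ),
        metadata=metadata,
    )
    if manifest.output_dir:
        report.write(manifest.output_dir)
    return report


@dataclass
class DerivationReport:
    """Score-model derivation plus per-experiment validation statistics."""

    model: object
    permutation: object
    validation: pd.DataFrame
    metadata: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.model.to_frame().to_csv(out / "score_model.tsv", sep="\t", index=False, float_format="%.10g")
        self.validation.to_csv(out / "validation.tsv", sep="\t", index=False, float_format="%.10g")
        with open(out / "derivation_metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True)


def run_vegf_derivation(
    train: PerturbationExperiment,
    panel: Sequence[str],
    validation: Sequence[PerturbationExperiment] = (),
    B: int = 10_000,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> DerivationReport:
    """Derive the activation score on a training experiment and validate it.

    Fits the PCA panel model on ``train``, runs the centroid permutation test
    on the training embedding, then applies the model to the training set and
    every validation experiment, reporting group medians, the Mann-Whitney
    comparison and (where times exist) the score/incubation-time correlation.
    """
    model, embedding = fit_pca_panel(train, panel)
    perm = centroid_permutation_test(
        embedding, train.treatment.to_numpy(), B=B, seed=seed
    )
    rows = []
    for role, exp in [("training", train)] + [("validation", v) for v in validation]:
        scores = apply_derived_score(model, exp.dataset)
        labels = exp.treatment.to_numpy()
        usable = np.isin(labels, ("treated", "naive"))
        subset = ActivationScoreSet(
            signature=scores.signature,
            sample_ids=[s for s, m in zip(scores.sample_ids, usable) if m],
            raw=scores.raw[usable],
            genes_used=scores.genes_used,
        )
        cmp = compare_groups(subset, labels[usable])
        row = {
            "role": role,
            "experiment": exp.dataset.name,
            "median_treated": cmp.medians.get("treated", np.nan),
            "median_naive": cmp.medians.get("naive", np.nan),
            "mw_p": cmp.p_value,
            "time_rho": np.nan,
            "time_p": np.nan,
        }
        if exp.time is not None and exp.time.notna().sum() >= 3:
            rec = correlate_with_time(scores, exp.time)
            row["time_rho"], row["time_p"] = rec.estimate, rec.p_value
        rows.append(row)
    validation_frame = pd.DataFrame(
        rows,
        columns=["role", "experiment", "median_treated", "median_naive", "mw_p", "time_rho", "time_p"],
    )
    metadata = {
        "panel_size_requested": len(list(panel)),
        "panel_size_used": len(model.genes),
        "observed_distance": perm.observed_distance,
        "expected_distance": perm.expected_distance,
        "permutation_p": perm.p_value,
        "n_permutations": perm.n_permutations,
        "seed": seed,
    }
    report = DerivationReport(
        model=model, permutation=perm, validation=validation_frame, metadata=metadata
    )
    if out_dir:
        report.write(out_dir)
    return report
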