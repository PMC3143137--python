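"""Derivation of an activation score from a perturbation experiment.

Given expression of a small gene panel in treated versus naive samples
(e.g. VEGF-A-stimulated versus untreated HUVEC cultures), the procedure is:

1. restrict the panel to informatively measured genes (presence filter),
2. PCA on the panel expression (samples as observations, genes as variables),
3. test treated/naive segregation by permuting class labels and comparing the
   observed Euclidean distance between class centroids in the PC1-PC2 plane
   with its permutation null,
4. use the PC1 loadings as signature coefficients: the activation score of a
   sample is the loadings-weighted sum of its panel-gene expression, with the
   sign convention that treated samples score higher than naive ones,
5. validate by comparing treated/naive score distributions and by correlating
   scores with incubation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import ExpressionDataset, filter_expr_presence
from .meta import EffectRecord, pearson_correlation
from .scoring import ActivationScoreSet

__all__ = [
    "VEGF_PANEL",
    "PerturbationExperiment",
    "DerivedScoreModel",
    "PermutationTestResult",
    "fit_pca_panel",
    "centroid_permutation_test",
    "apply_derived_score",
    "correlate_with_time",
]

#: the ten informatively measured genes of the published 13-gene VEGF-A panel
VEGF_PANEL = (
    "FABP5",
    "UCHL1",
    "PLOD",
    "DDIT4",
    "VEGF",
    "ADM",
    "ANGPTL4",
    "NDRG1",
    "NP",
    "SLC16A3",
)

TREATMENT_LEVELS = ("treated", "naive", "other")


@dataclass
class PerturbationExperiment:
    """An expression dataset with per-sample treatment labels and optional
    incubation times (hours)."""

    dataset: ExpressionDataset
    treatment: pd.Series
    time: pd.Series | None = None

    def __post_init__(self) -> None:
        samples = self.dataset.sample_ids
        self.treatment = self.treatment.reindex(samples)
        if self.treatment.isna().any():
            missing = list(self.treatment.index[self.treatment.isna()])[:5]
            raise ValueError(f"treatment labels missing for samples {missing}")
        bad = set(self.treatment) - set(TREATMENT_LEVELS)
        if bad:
            raise ValueError(f"unknown treatment labels {sorted(bad)}")
        if self.time is not None:
            self.time = self.time.reindex(samples).astype(float)
            if (self.time.dropna() < 0).any():
                raise ValueError("incubation times must be nonnegative")

    def mask(self, label: str) -> np.ndarray:
        return (self.treatment == label).to_numpy()


@dataclass
class DerivedScoreModel:
    """PC1-loading score model: unit-norm loadings over the informative panel
    genes, oriented so that treated samples score at least as high as naive."""

    name: str
    genes: list[str]
    loadings: np.ndarray
    orientation: int = 1

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        if len(self.genes) != len(self.loadings):
            raise ValueError("genes and loadings differ in length")
        if not np.isfinite(self.loadings).all():
            raise ValueError("loadings must be finite")
        if self.orientation not in (1, -1):
            raise ValueError("orientation must be +1 or -1")
        norm = np.linalg.norm(self.loadings)
        if not np.isclose(norm, 1.0, atol=1e-8):
            raise ValueError("loadings must have unit Euclidean norm")

    def flipped(self) -> "DerivedScoreModel":
        return replace(self, loadings=-self.loadings, orientation=-self.orientation)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "loading": self.loadings})


@dataclass
class PermutationTestResult:
    """Label-permutation test of the between-class centroid distance."""

    observed_distance: float
    expected_distance: float
    p_value: float
    n_permutations: int
    seed: int


def fit_pca_panel(
    exp: PerturbationExperiment,
    panel: Sequence[str],
    informative: bool = True,
    use_correlation: bool = False,
) -> tuple[DerivedScoreModel, pd.DataFrame]:
    """PCA of panel-gene expression; returns the PC1-loading score model and
    the 2-D sample embedding (columns PC1, PC2).

    The panel is first reduced to genes present in the dataset and, when
    ``informative`` is set, passing the presence filter.  Components are
    computed from the gene-gene covariance of the (column-centered) panel
    expression; ``use_correlation`` standardizes each gene to unit variance
    first.  The PC1 sign is chosen so the treated-mean score is >= the
    naive-mean score.
    """
    ds = exp.dataset.subset_genes(panel)
    missing = sorted(set(panel) - set(ds.gene_ids))
    if informative and ds.n_genes:
        ds = filter_expr_presence(ds)
    if ds.n_genes < 2:
        raise ValueError(
            f"fewer than 2 informative panel genes in dataset {exp.dataset.name!r}"
            + (f" (missing: {missing})" if missing else "")
        )
    if ds.n_samples < 3:
        raise ValueError("PCA needs at least 3 samples")
    genes = ds.gene_ids
    X = ds.matrix.to_numpy(dtype=float).T  # samples x genes
    if use_correlation:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    n_comp = min(2, len(genes), ds.n_samples - 1)
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(X)
    if coords.shape[1] < 2:  # degenerate rank: pad a zero second axis
        coords = np.column_stack([coords, np.zeros(len(coords))])
    loadings = pca.components_[0]

    model = DerivedScoreModel(name="derived_activation", genes=genes, loadings=loadings)
    treated, naive = exp.mask("treated"), exp.mask("naive")
    if treated.any() and naive.any():
        if coords[treated, 0].mean() < coords[naive, 0].mean():
            model = model.flipped()
            coords = coords.copy()
            coords[:, 0] = -coords[:, 0]
    embedding = pd.DataFrame(coords[:, :2], index=ds.sample_ids, columns=["PC1", "PC2"])
    return model, embedding


def centroid_permutation_test(
    embedding: pd.DataFrame | np.ndarray,
    labels: Sequence[str],
    B: int = 10_000,
    seed: int = 0,
) -> PermutationTestResult:
    """Permutation test of the Euclidean distance between class centroids.

    The embedding stays fixed while class labels are reassigned uniformly at
    random ``B`` times; p = (1 + #{null >= observed}) / (B + 1), so p lies in
    [1/(B+1), 1] and is exactly reproducible given (B, seed).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    coords = np.asarray(embedding, dtype=float)
    labels = np.asarray(labels)
    if len(labels) != len(coords):
        raise ValueError("labels and embedding differ in length")
    levels = sorted(pd.unique(labels))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 class labels, got {levels}")
    in_a = labels == levels[0]
    n, n_a = len(coords), int(in_a.sum())
    if n_a == 0 or n_a == n:
        raise ValueError("both classes must be nonempty")

    def dist(mask: np.ndarray) -> float:
        return float(
            np.linalg.norm(coords[mask].mean(axis=0) - coords[~mask].mean(axis=0))
        )

    observed = dist(in_a)
    rng = np.random.default_rng(seed)
    # B random permutations: first n_a positions of each shuffled index row
    idx = np.argsort(rng.random((B, n)), axis=1)[:, :n_a]
    sums_a = coords[idx].sum(axis=1)  # B x 2
    total = coords.sum(axis=0)
    cent_a = sums_a / n_a
    cent_b = (total - sums_a) / (n - n_a)
    null = np.linalg.norm(cent_a - cent_b, axis=1)
    p = (1.0 + float(np.sum(null >= observed - 1e-12))) / (B + 1.0)
    return PermutationTestResult(
        observed_distance=observed,
        expected_distance=float(null.mean()),
        p_value=p,
        n_permutations=B,
        seed=seed,
    )


def apply_derived_score(model: DerivedScoreModel, ds: ExpressionDataset) -> ActivationScoreSet:
    """Loadings-weighted sum of panel-gene expression per sample.

    Model genes absent from the dataset are skipped; the stored loadings
    already carry the orientation.
    """
    present = [g for g in model.genes if g in ds.matrix.index]
    if not present:
        raise ValueError(
            f"model {model.name!r} shares no genes with dataset {ds.name!r}"
        )
    w = np.asarray([model.loadings[model.genes.index(g)] for g in present])
    raw = w @ ds.matrix.loc[present].to_numpy(dtype=float)
    return ActivationScoreSet(
        signature=model.name, sample_ids=ds.sample_ids, raw=raw, genes_used=len(present)
    )


def correlate_with_time(
    scores: ActivationScoreSet, time: Sequence[float] | pd.Series
) -> EffectRecord:
    """Pearson correlation between activation scores and incubation time.

    Samples without a recorded time are dropped; at least 3 timed samples are
    required.
    """
    if isinstance(time, pd.Series):
        time = time.reindex(scores.sample_ids).to_numpy(dtype=float)
    else:
        time = np.asarray(time, dtype=float)
    mask = np.isfinite(time)
    if mask.sum() < 3:
        raise ValueError("need at least 3 samples with a recorded time")
    return pearson_correlation(
        scores.raw[mask], time[mask], study=scores.signature + "_vs_time"
    )
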