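"""Per-sample activation scores for weighted gene signatures.

A signature is a set of (gene, signed regression coefficient) pairs plus an
intercept.  The raw activation score of a sample is the intercept plus the
sum over signature genes present in the dataset of coefficient times log
expression.  Scores are standardized for cross-dataset comparability by
median-centering and scaling the sample standard deviation to 1; because the
median absorbs any constant, the intercept never affects downstream
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionDataset

__all__ = [
    "GeneSignature",
    "ActivationScoreSet",
    "GroupComparison",
    "score_signature",
    "standardize_scores",
    "compare_groups",
]


@dataclass
class GeneSignature:
    """Named weight vector over genes: coefficient sign is the direction of
    the gene's effect on pathway activation, magnitude its weight."""

    name: str
    entries: Mapping[str, float]
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError(f"signature {self.name!r} has no entries")
        vals = np.asarray(list(self.entries.values()), dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError(f"signature {self.name!r} has non-finite coefficients")
        if not np.isfinite(self.intercept):
            raise ValueError(f"signature {self.name!r} has a non-finite intercept")

    @property
    def genes(self) -> list[str]:
        return list(self.entries)

    @classmethod
    def from_gene_lists(
        cls, name: str, up: Sequence[str] = (), down: Sequence[str] = ()
    ) -> "GeneSignature":
        """Build a +1/-1 signature from up/down gene lists (for sources that
        publish membership without coefficients)."""
        entries = {g: 1.0 for g in up}
        entries.update({g: -1.0 for g in down})
        return cls(name=name, entries=entries)


@dataclass
class ActivationScoreSet:
    """Raw and (optionally) standardized per-sample scores for one signature."""

    signature: str
    sample_ids: list[str]
    raw: np.ndarray
    standardized: np.ndarray | None = None
    genes_used: int = 0

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if len(self.sample_ids) != len(self.raw):
            raise ValueError("sample_ids and raw scores differ in length")
        if self.standardized is not None:
            self.standardized = np.asarray(self.standardized, dtype=float)
            if len(self.standardized) != len(self.raw):
                raise ValueError("raw and standardized scores differ in length")

    @property
    def values(self) -> np.ndarray:
        """Standardized scores when available, raw otherwise."""
        return self.raw if self.standardized is None else self.standardized

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "signature": self.signature,
                "raw": self.raw,
                "standardized": (
                    self.standardized if self.standardized is not None else np.nan
                ),
                "genes_used": self.genes_used,
            }
        )


@dataclass
class GroupComparison:
    """Two-group Mann-Whitney comparison of score distributions."""

    statistic: float
    p_value: float
    medians: dict[str, float]
    n_per_group: dict[str, int]
    method: str = "exact"


def score_signature(ds: ExpressionDataset, sig: GeneSignature) -> ActivationScoreSet:
    """Weighted-sum activation score per sample.

    raw_s = intercept + sum over signature genes present in ``ds`` of
    coefficient * expression.  Signature genes missing from the dataset are
    skipped (cross-platform coverage loss); the count actually used is
    recorded.  Standardization is a separate pass
    (:func:`standardize_scores`).
    """
    present = [g for g in sig.entries if g in ds.matrix.index]
    if not present:
        raise ValueError(
            f"signature {sig.name!r} shares no genes with dataset {ds.name!r}"
        )
    coefs = np.asarray([sig.entries[g] for g in present], dtype=float)
    sub = ds.matrix.loc[present].to_numpy(dtype=float)
    raw = sig.intercept + coefs @ sub
    return ActivationScoreSet(
        signature=sig.name,
        sample_ids=ds.sample_ids,
        raw=raw,
        genes_used=len(present),
    )


def standardize_scores(scores: ActivationScoreSet) -> ActivationScoreSet:
    """Median-center and scale to unit standard deviation (n-1 denominator).

    The result has median exactly 0 and SD exactly 1; a degenerate (zero-SD)
    raw distribution is an error.
    """
    raw = scores.raw
    if len(raw) < 2:
        raise ValueError("standardization needs at least 2 samples")
    sd = raw.std(ddof=1)
    if sd == 0:
        raise ValueError(f"degenerate score distribution for {scores.signature!r}")
    standardized = (raw - np.median(raw)) / sd
    return replace(scores, standardized=standardized)


def compare_groups(
    scores: ActivationScoreSet, labels: Sequence[str]
) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of scores between two labelled groups.

    Exact enumeration when the combined sample size is <= 20 and there are no
    ties; otherwise the normal approximation with tie and continuity
    correction.  Group labels enter only through membership, so the result is
    symmetric under label swap.
    """
    labels = np.asarray(labels)
    values = scores.values
    if len(labels) != len(values):
        raise ValueError("labels and scores differ in length")
    levels = sorted(pd.unique(labels))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 group labels, got {levels}")
    a = values[labels == levels[0]]
    b = values[labels == levels[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    n = len(a) + len(b)
    has_ties = len(np.unique(values)) < n
    method = "exact" if (n <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        medians={levels[0]: float(np.median(a)), levels[1]: float(np.median(b))},
        n_per_group={levels[0]: int(len(a)), levels[1]: int(len(b))},
        method=method,
    )
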