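"""Random-effects meta-analysis of correlations and log hazard ratios.

Study-level effects are pooled with the DerSimonian-Laird moment estimator.
Correlations can be pooled on the raw rho scale — using the standard error
SE = (1 - rho^2) / sqrt(n - 1) — or on the Fisher-z scale with variance
1/(n - 3).  Hazard ratios are pooled on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectRecord",
    "MetaPoolResult",
    "correlation_se",
    "pearson_correlation",
    "pool_random_effects",
    "pool_hazard_ratios",
    "forest_table",
    "bonferroni_threshold",
]

#: conventional two-sided 95% normal quantile
Z95 = 1.96

SCALES = ("raw_rho", "fisher_z", "log_hr")


def bonferroni_threshold(n_tests: int = 20, alpha: float = 0.05) -> float:
    """Family-wise significance threshold; 0.05/20 = 0.0025 for the default
    panel of 20 pathway signatures."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def correlation_se(rho: float, n: int) -> float:
    """Standard error of a Pearson correlation: (1 - rho^2) / sqrt(n - 1)."""
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    if n < 2:
        raise ValueError("n must be >= 2")
    return (1.0 - rho * rho) / math.sqrt(n - 1)


@dataclass
class EffectRecord:
    """One study's effect, ready for pooling.

    ``kind`` is ``correlation`` (estimate = Pearson rho) or ``log_hr``
    (estimate = log hazard ratio).  ``n`` is required for Fisher-z pooling.
    """

    study: str
    kind: str
    estimate: float
    se: float
    n: int | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("correlation", "log_hr"):
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if not self.se > 0:
            raise ValueError("se must be positive")
        if self.kind == "correlation" and not abs(self.estimate) < 1:
            raise ValueError("correlation estimate must lie in (-1, 1)")


@dataclass
class MetaPoolResult:
    """DerSimonian-Laird pooling output.

    ``pooled``/``se_pooled``/``ci95`` are on the pooling scale (z for
    ``fisher_z``, log for ``log_hr``); ``pooled_natural``/``ci95_natural``
    are back-transformed to the natural scale (rho, or hazard ratio).
    ``weights`` are the normalized random-effects weights (sum 1), in input
    order.
    """

    pooled: float
    se_pooled: float
    ci95: tuple[float, float]
    q: float
    df: int
    tau2: float
    weights: np.ndarray
    model: str
    scale: str
    p_value: float
    studies: list[str] = field(default_factory=list)

    def _natural(self, x: float) -> float:
        if self.scale == "fisher_z":
            return math.tanh(x)
        if self.scale == "log_hr":
            return math.exp(x)
        return x

    @property
    def pooled_natural(self) -> float:
        return self._natural(self.pooled)

    @property
    def ci95_natural(self) -> tuple[float, float]:
        return (self._natural(self.ci95[0]), self._natural(self.ci95[1]))


def pearson_correlation(
    x: Sequence[float], y: Sequence[float], study: str = ""
) -> EffectRecord:
    """Pearson product-moment correlation with the study-level SE formula.

    The two-sided p-value comes from t = rho * sqrt((n-2)/(1-rho^2)) on
    n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("Pearson correlation needs at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input: correlation undefined")
    rho = float(np.corrcoef(x, y)[0, 1])
    # keep numerically perfect correlations strictly inside (-1, 1) so the
    # SE stays positive and the record remains poolable
    cap = 1.0 - 1e-12
    rho = max(min(rho, cap), -cap)
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    se = correlation_se(rho, n)
    return EffectRecord(
        study=study, kind="correlation", estimate=rho, se=se, n=n, p_value=float(p)
    )


def _dl_pool(theta: np.ndarray, se: np.ndarray) -> tuple[float, float, float, float, np.ndarray]:
    """DerSimonian-Laird moment estimator on one scale.

    Returns (pooled, se_pooled, Q, tau2, normalized random-effects weights).
    """
    w = 1.0 / se**2
    theta_fixed = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - theta_fixed) ** 2))
    df = len(theta) - 1
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    w_re = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_re * theta) / np.sum(w_re))
    se_pooled = float(1.0 / math.sqrt(np.sum(w_re)))
    return pooled, se_pooled, q, tau2, w_re / np.sum(w_re)


def pool_random_effects(
    effects: Sequence[EffectRecord], scale: str = "raw_rho"
) -> MetaPoolResult:
    """Pool study effects under a DerSimonian-Laird random-effects model.

    ``scale`` is ``raw_rho`` (correlations pooled as-is with their stated
    SEs), ``fisher_z`` (correlations transformed to atanh(rho) with variance
    1/(n-3)), or ``log_hr``.  A single effect passes through with tau2 = 0
    and a CI from its own SE.
    """
    effects = list(effects)
    if not effects:
        raise ValueError("no effects to pool")
    if scale not in SCALES:
        raise ValueError(f"scale must be one of {SCALES}")
    kinds = {e.kind for e in effects}
    if len(kinds) > 1:
        raise ValueError(f"cannot pool mixed effect kinds {sorted(kinds)}")
    kind = kinds.pop()
    if scale == "log_hr" and kind != "log_hr":
        raise ValueError("log_hr scale requires log_hr effects")
    if scale in ("raw_rho", "fisher_z") and kind != "correlation":
        raise ValueError(f"{scale} scale requires correlation effects")

    if scale == "fisher_z":
        for e in effects:
            if e.n is None or e.n < 4:
                raise ValueError("fisher_z pooling needs n >= 4 for every study")
        theta = np.array([math.atanh(e.estimate) for e in effects])
        se = np.array([1.0 / math.sqrt(e.n - 3) for e in effects])
    else:
        theta = np.array([e.estimate for e in effects], dtype=float)
        se = np.array([e.se for e in effects], dtype=float)

    if len(effects) == 1:
        pooled, se_pooled = float(theta[0]), float(se[0])
        q, tau2, weights = 0.0, 0.0, np.array([1.0])
    else:
        pooled, se_pooled, q, tau2, weights = _dl_pool(theta, se)
    ci = (pooled - Z95 * se_pooled, pooled + Z95 * se_pooled)
    z = pooled / se_pooled
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaPoolResult(
        pooled=pooled,
        se_pooled=se_pooled,
        ci95=ci,
        q=q,
        df=len(effects) - 1,
        tau2=tau2,
        weights=weights,
        model="random",
        scale=scale,
        p_value=p,
        studies=[e.study for e in effects],
    )


def pool_hazard_ratios(effects: Sequence) -> MetaPoolResult:
    """Pool Cox effects (log-HR scale); accepts ``HREffect`` or ``EffectRecord``.

    The result's ``pooled_natural``/``ci95_natural`` are the pooled hazard
    ratio and its CI.
    """
    records = []
    for e in effects:
        if isinstance(e, EffectRecord):
            records.append(e)
        else:  # HREffect duck-typing
            records.append(
                EffectRecord(
                    study=getattr(e, "study", ""),
                    kind="log_hr",
                    estimate=e.log_hr,
                    se=e.se,
                    n=getattr(e, "n", None),
                )
            )
    return pool_random_effects(records, scale="log_hr")


def forest_table(result: MetaPoolResult, effects: Sequence[EffectRecord]) -> pd.DataFrame:
    """Numeric forest-plot table: one row per study plus a pooled row.

    Per-study confidence intervals use each study's own SE on the pooling
    scale; the pooled row carries Q, df and tau2.
    """
    rows = []
    for e, w in zip(effects, result.weights):
        lo, hi = e.estimate - Z95 * e.se, e.estimate + Z95 * e.se
        rows.append(
            {
                "study": e.study,
                "estimate": e.estimate,
                "se": e.se,
                "ci_low": lo,
                "ci_high": hi,
                "weight_pct": 100.0 * float(w),
                "q": np.nan,
                "df": np.nan,
                "tau2": np.nan,
            }
        )
    rows.append(
        {
            "study": "pooled",
            "estimate": result.pooled,
            "se": result.se_pooled,
            "ci_low": result.ci95[0],
            "ci_high": result.ci95[1],
            "weight_pct": 100.0,
            "q": result.q,
            "df": result.df,
            "tau2": result.tau2,
        }
    )
    return pd.DataFrame(rows)
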