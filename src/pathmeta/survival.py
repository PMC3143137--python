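"""Univariate Cox proportional-hazards association of a continuous score with survival.

The hazard ratio is reported per 1 unit of the covariate; in the pipeline the
covariate is a standardized activation score (SD 1), so the HR is per SD and
comparable across datasets.  The partial likelihood is maximized by
Newton-Raphson with Breslow handling of tied event times (Efron available);
the standard error comes from the observed information at the maximum, and
confidence intervals and p-values are Wald-based, which is what the pooling
stage needs (a log-HR, SE pair).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["HREffect", "fit_cox_univariate", "cox_partial_loglik"]

Z95 = 1.96

#: |beta| beyond which the likelihood is treated as monotone (no finite MLE)
SEPARATION_BOUND = 20.0


@dataclass
class HREffect:
    """Cox regression effect for one covariate in one study."""

    log_hr: float
    se: float
    hr: float
    ci95: tuple[float, float]
    p_value: float
    n: int
    events: int
    study: str = ""
    signature: str = ""

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("se must be positive")


def _prepare(x, time, event):
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if not (len(x) == len(time) == len(event)):
        raise ValueError("covariate, time and event must have equal length")
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    if not np.isin(event, (0.0, 1.0)).all():
        raise ValueError("event indicator must be 0/1")
    # sort by time descending so risk sets are cumulative prefixes
    order = np.argsort(-time, kind="stable")
    return x[order], time[order], event[order].astype(bool)


def _loglik_grad_hess(beta: float, x, time, event, ties: str):
    """Partial log-likelihood, gradient and negative Hessian at ``beta``.

    Inputs must be sorted by descending time; risk set at an event time is
    the prefix of samples with time >= it.
    """
    eta = beta * x
    eta -= eta.max()  # guards exp overflow; cancels in ratios, shifts loglik by const*d
    r = np.exp(eta)
    cr = np.cumsum(r)
    crx = np.cumsum(r * x)
    crx2 = np.cumsum(r * x * x)

    loglik = grad = info = 0.0
    n = len(x)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and time[j + 1] == time[i]:
            j += 1
        # [i, j] share one time; risk set is the prefix 0..j
        ev = np.arange(i, j + 1)[event[i : j + 1]]
        d = len(ev)
        if d:
            s_x = float(np.sum(x[ev]))
            R, Rx, Rx2 = float(cr[j]), float(crx[j]), float(crx2[j])
            if ties == "breslow":
                loglik += float(np.sum(eta[ev])) - d * math.log(R)
                grad += s_x - d * (Rx / R)
                info += d * (Rx2 / R - (Rx / R) ** 2)
            else:  # efron
                e_r = float(np.sum(r[ev]))
                e_rx = float(np.sum((r * x)[ev]))
                e_rx2 = float(np.sum((r * x * x)[ev]))
                loglik += float(np.sum(eta[ev]))
                for k in range(d):
                    f = k / d
                    Rk = R - f * e_r
                    Rkx = Rx - f * e_rx
                    Rkx2 = Rx2 - f * e_rx2
                    loglik -= math.log(Rk)
                    grad += s_x / d - Rkx / Rk
                    info += Rkx2 / Rk - (Rkx / Rk) ** 2
        i = j + 1
    return loglik, grad, info


def cox_partial_loglik(beta: float, x, time, event, ties: str = "breslow") -> float:
    """Cox partial log-likelihood at ``beta`` (up to an additive constant
    independent of ``beta``)."""
    x, time, event = _prepare(x, time, event)
    ll, _, _ = _loglik_grad_hess(float(beta), x, time, event, ties)
    return ll


def fit_cox_univariate(
    scores,
    time,
    event,
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-8,
    study: str = "",
    signature: str = "",
) -> HREffect:
    """Fit a univariate Cox model by Newton-Raphson.

    Convergence when the Newton step falls below ``tol`` (default 1e-8) or
    after ``max_iter`` iterations.  A constant covariate raises
    "degenerate covariate"; a monotone likelihood (|beta| exceeding 20,
    i.e. HR beyond e^20) raises "separation detected".
    """
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    x, t, ev = _prepare(scores, time, event)
    n_events = int(ev.sum())
    if n_events < 2:
        raise ValueError("need at least 2 events")
    if np.std(x) == 0:
        raise ValueError("degenerate covariate: constant score")

    beta = 0.0
    for _ in range(max_iter):
        _, grad, info = _loglik_grad_hess(beta, x, t, ev, ties)
        if info <= 0:
            raise ValueError("degenerate covariate: no information")
        step = grad / info
        # damp absurd steps; keeps Newton stable far from the optimum
        step = max(min(step, 5.0), -5.0)
        beta += step
        if abs(beta) > SEPARATION_BOUND:
            raise ValueError("separation detected: partial likelihood is monotone")
        if abs(step) < tol:
            break

    _, _, info = _loglik_grad_hess(beta, x, t, ev, ties)
    se = 1.0 / math.sqrt(info)
    ci = (math.exp(beta - Z95 * se), math.exp(beta + Z95 * se))
    p = float(2.0 * stats.norm.sf(abs(beta) / se))
    return HREffect(
        log_hr=float(beta),
        se=float(se),
        hr=math.exp(beta),
        ci95=ci,
        p_value=p,
        n=len(x),
        events=n_events,
        study=study,
        signature=signature,
    )
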