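"""Product-limit ("1-Kaplan-Meier") net-failure estimation.

The probability that a construct has been revised by time ``t`` is estimated
as ``F(t) = 1 - S(t)`` where ``S`` is the Kaplan-Meier survivor function with
first revision as the event and death treated as independent censoring — the
"net failure" of the construct.  Uncertainty comes from the classical
Greenwood variance

    Var[S(t)] = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i)),

which equals the variance of ``F(t)``.  Confidence intervals are symmetric
normal ("plain") intervals on the failure scale, clipped to [0, 1]; this
matches the symmetric intervals registry reports print for small failure
probabilities.  A log(-log) transform is deliberately not used (see
``failure_ci``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .registry import ConstructKey, ProcedureRecord

__all__ = [
    "NetFailureEstimate",
    "km_curve",
    "km_net_failure",
    "greenwood_variance",
    "failure_ci",
    "n_at_risk",
    "ptir",
]


@dataclass(frozen=True)
class NetFailureEstimate:
    """Net failure of one construct at one post-operative time point.

    ``variance`` is the Greenwood variance of S(t) (= variance of F(t)); it
    is ``nan``, with ``degenerate=True``, when the risk set was exhausted by
    events (F = 1 and no comparison is meaningful).  ``n_at_risk`` counts
    procedures still under observation at ``t``.
    """

    construct: Optional[ConstructKey]
    t: float
    failure: float
    variance: float
    n_at_risk: int
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    degenerate: bool = False

    @property
    def se(self) -> float:
        return math.sqrt(self.variance) if self.variance >= 0 else float("nan")


def _event_table(records: Sequence[ProcedureRecord], t: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distinct event times <= t with event counts and risk-set sizes.

    Ties between revisions and censorings/deaths at the same time are
    resolved events-first: the risk set just before t_i includes everyone
    whose follow-up reaches t_i, censorings at t_i included.
    """
    times = np.array([r.time_years for r in records], dtype=float)
    is_event = np.array([r.status == "revision" for r in records], dtype=bool)
    event_times = np.unique(times[is_event & (times <= t)])
    d = np.array([np.sum(is_event & (times == ti)) for ti in event_times], dtype=float)
    n = np.array([np.sum(times >= ti) for ti in event_times], dtype=float)
    return event_times, d, n


def _check_records(records: Sequence[ProcedureRecord], t: float) -> None:
    if len(records) == 0:
        raise ValueError("cannot estimate from an empty record collection")
    if t <= 0:
        raise ValueError(f"evaluation time must be positive, got {t}")
    if all(r.time_years == 0 and r.status != "revision" for r in records):
        raise ValueError("all records censored at time 0: risk set empty")


def km_curve(records: Sequence[ProcedureRecord], t: float) -> tuple[float, float, bool]:
    """Survivor estimate S(t), Greenwood variance, and a degeneracy flag.

    Single pass over the event table shared by :func:`km_net_failure` and
    :func:`greenwood_variance`.  The flag is set when some risk set was
    exhausted (n_i == d_i), where the Greenwood sum diverges.
    """
    _check_records(records, t)
    _, d, n = _event_table(records, t)
    surv = float(np.prod(1.0 - d / n))
    exhausted = bool(np.any(n == d))
    if exhausted:
        return surv, float("nan"), True
    gw = float(np.sum(d / (n * (n - d))))
    return surv, surv * surv * gw, False


def km_net_failure(
    records: Sequence[ProcedureRecord],
    t: float,
    alpha: float = 0.05,
    construct: Optional[ConstructKey] = None,
) -> NetFailureEstimate:
    """Estimate net failure F(t) = 1 - S(t) with Greenwood CI at time ``t``.

    Events at exactly ``t`` count toward F(t).  Deaths and administrative
    censorings leave the risk set without contributing events.
    """
    surv, var, degenerate = km_curve(records, t)
    failure = 1.0 - surv
    if degenerate:
        lo = hi = float("nan")
    else:
        lo, hi = failure_ci(failure, var, alpha)
    if construct is None and records:
        keys = {r.construct for r in records}
        construct = keys.pop() if len(keys) == 1 else None
    return NetFailureEstimate(
        construct=construct,
        t=t,
        failure=failure,
        variance=var,
        n_at_risk=n_at_risk(records, t),
        ci_low=lo,
        ci_high=hi,
        alpha=alpha,
        degenerate=degenerate,
    )


def greenwood_variance(records: Sequence[ProcedureRecord], t: float) -> float:
    """Greenwood variance of S(t) (equal to the variance of F(t)).

    ``nan`` when the risk set was exhausted by events before ``t`` (the sum
    has an infinite term; F = 1 and the estimate is flagged degenerate).
    """
    _, var, _ = km_curve(records, t)
    return var


def failure_ci(failure: float, variance: float, alpha: float = 0.05) -> tuple[float, float]:
    """Symmetric normal CI on the failure scale, clipped to [0, 1].

    The plain interval F +/- z * sqrt(Var) is used rather than a
    log(-log)-transformed one: with failure probabilities of a few percent
    and thousands at risk the normal approximation is adequate, and registry
    reference intervals are printed symmetric.
    """
    if variance < 0:
        raise ValueError("variance must be non-negative")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * math.sqrt(variance)
    return max(0.0, failure - half), min(1.0, failure + half)


def n_at_risk(records: Iterable[ProcedureRecord], t: float) -> int:
    """Procedures still under observation at ``t``.

    A record is at risk when its follow-up reaches ``t`` (``time_years >=
    t``) and it was not revised strictly before ``t``; deaths and censorings
    before ``t`` remove it from the risk set.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    return int(sum(1 for r in records if r.time_years >= t))


def ptir(records: Sequence[ProcedureRecord]) -> float:
    """Prosthesis time incidence rate: revisions per 100 component-years.

    The registry annual-report summary measure — total first revisions over
    total observed component-years, scaled to 100.  Descriptive only; never
    used in noninferiority classification.
    """
    total_years = sum(r.time_years for r in records)
    if total_years <= 0:
        raise ValueError("total observed component-years is zero")
    revisions = sum(1 for r in records if r.status == "revision")
    return 100.0 * revisions / total_years


def estimates_to_frame(estimates: Sequence[NetFailureEstimate]):
    """Tidy export: one row per construct-time estimate."""
    import pandas as pd

    return pd.DataFrame(
        {
            "construct": [e.construct.label if e.construct else "" for e in estimates],
            "t_years": [e.t for e in estimates],
            "n_at_risk": [e.n_at_risk for e in estimates],
            "failure": [e.failure for e in estimates],
            "se": [e.se for e in estimates],
            "ci_low": [e.ci_low for e in estimates],
            "ci_high": [e.ci_high for e in estimates],
        }
    )
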