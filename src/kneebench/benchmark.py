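"""Internal noninferiority benchmarking of construct revision rates.

At each post-operative time point the best-practice reference is chosen
*within* the registry: the construct with the lowest net failure among those
with at least 1000 procedures still at risk (a dynamic benchmark, unlike
fixed external standards).  Every other construct with at least 500 at risk
is compared against it: the difference in failure probabilities, its pooled
Greenwood standard error, a Wald test, and a five-way classification of the
difference CI against two noninferiority margins set at 20% and 100% of the
reference failure (100% = a doubling of the cumulative failure probability).

Classification rules, evaluated in order, first match wins:

1. CI lower limit above the 100% margin        -> inferior at 100%
2. CI lower limit above the 20% margin         -> inferior at 20%
3. CI upper limit below the 20% margin         -> noninferior at 20%
4. CI upper limit below the 100% margin        -> noninferior at 100%
5. otherwise                                   -> inconclusive

Inferiority rules take precedence over noninferiority rules, so a narrow CI
lying wholly between the margins is reported as inferior at 20% (its lower
limit already excludes the acceptable region).  Comparisons are strict;
exact equality with a margin falls through to the weaker category.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

from .registry import ConstructKey, Registry, group_by_construct
from .survival import NetFailureEstimate, km_net_failure

__all__ = [
    "Category",
    "MarginPair",
    "BenchmarkRow",
    "BenchmarkReport",
    "BenchmarkConfig",
    "select_reference",
    "eligible_comparators",
    "margins_from_reference",
    "difference_test",
    "classify",
    "run_benchmark",
    "report_to_frame",
]

logger = logging.getLogger(__name__)

DEFAULT_TIMEPOINTS = (3.0, 5.0, 7.0, 10.0)
REF_MIN_AT_RISK = 1000
COMP_MIN_AT_RISK = 500


class Category(str, Enum):
    """Five-way noninferiority classification band."""

    INFERIOR_100 = "inferior_100"
    INFERIOR_20 = "inferior_20"
    INCONCLUSIVE = "inconclusive"
    NONINFERIOR_100 = "noninferior_100"
    NONINFERIOR_20 = "noninferior_20"


@dataclass(frozen=True)
class MarginPair:
    """Absolute failure-difference margins derived from the reference.

    ``m20 = 0.20 * F_ref`` and ``m100 = 1.00 * F_ref``; a comparator sitting
    exactly at ``m100`` has double the reference failure probability.
    ``degenerate`` flags the uninformative case F_ref = 0 (both margins 0).
    """

    m20: float
    m100: float
    degenerate: bool = False


@dataclass(frozen=True)
class BenchmarkRow:
    """One comparator-vs-reference result at one time point."""

    construct: ConstructKey
    t: float
    n_at_risk: int
    failure: float
    se: float
    diff: float
    se_diff: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    category: Category


@dataclass
class BenchmarkReport:
    """All comparator rows for one time point (and optionally one stratum)."""

    t: float
    reference: ConstructKey
    reference_estimate: NetFailureEstimate
    margins: MarginPair
    rows: list[BenchmarkRow] = field(default_factory=list)
    stratum: str = "all"
    excluded: list[tuple[ConstructKey, int]] = field(default_factory=list)


@dataclass
class BenchmarkConfig:
    """Run-level knobs for :func:`run_benchmark`."""

    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS
    alpha: float = 0.05
    ref_min_at_risk: int = REF_MIN_AT_RISK
    comp_min_at_risk: int = COMP_MIN_AT_RISK
    margins_relative: Sequence[float] = (0.2, 1.0)
    stratify_by: Optional[str] = None

    @classmethod
    def from_mapping(cls, data: dict) -> "BenchmarkConfig":
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**known)


class ReferenceSelectionError(ValueError):
    """No construct satisfies the at-risk threshold for the reference rule."""


def select_reference(
    estimates: Sequence[NetFailureEstimate],
    min_at_risk: int = REF_MIN_AT_RISK,
) -> ConstructKey:
    """Pick the reference: lowest failure among constructs with enough at risk.

    Ties on failure are broken by larger risk set, then lexicographic
    construct label, so the choice is deterministic.
    """
    qualifying = [e for e in estimates if e.n_at_risk >= min_at_risk]
    if not qualifying:
        raise ReferenceSelectionError(
            f"no construct has >= {min_at_risk} procedures at risk; "
            "cannot select a reference"
        )
    best = min(qualifying, key=lambda e: (e.failure, -e.n_at_risk, e.construct.label))
    return best.construct


def eligible_comparators(
    estimates: Sequence[NetFailureEstimate],
    reference: ConstructKey,
    min_at_risk: int = COMP_MIN_AT_RISK,
) -> list[NetFailureEstimate]:
    """Constructs with at least ``min_at_risk`` still at risk, reference excluded."""
    return [
        e for e in estimates if e.n_at_risk >= min_at_risk and e.construct != reference
    ]


def margins_from_reference(
    reference_failure: float,
    relative: Sequence[float] = (0.2, 1.0),
) -> MarginPair:
    """Absolute difference margins at the given relative risks of the reference."""
    if not 0.0 <= reference_failure <= 1.0:
        raise ValueError("reference failure must be a probability")
    lo, hi = sorted(relative)
    return MarginPair(
        m20=lo * reference_failure,
        m100=hi * reference_failure,
        degenerate=reference_failure == 0.0,
    )


def difference_test(
    comp: NetFailureEstimate,
    ref: NetFailureEstimate,
    alpha: float = 0.05,
) -> tuple[float, float, float, float, float, float]:
    """Difference in failure with pooled Greenwood SE, CI, and Wald test.

    Returns ``(diff, se_diff, ci_low, ci_high, z, p)`` where ``diff = F_comp
    - F_ref``, ``se_diff = sqrt(Var_comp + Var_ref)`` (the pooled Greenwood
    estimate), the CI is ``diff +/- z_{1-alpha/2} * se_diff``, and ``p`` is
    the two-sided normal tail of the Wald statistic ``diff / se_diff``.
    """
    if comp.t != ref.t:
        raise ValueError(f"estimates at different time points: {comp.t} vs {ref.t}")
    if not (math.isfinite(comp.variance) and math.isfinite(ref.variance)):
        raise ValueError("degenerate (infinite-variance) estimate in comparison")
    diff = comp.failure - ref.failure
    se_diff = math.sqrt(comp.variance + ref.variance)
    if se_diff == 0.0:
        if diff == 0.0:
            return 0.0, 0.0, 0.0, 0.0, 0.0, 1.0
        raise ValueError("zero pooled SE with nonzero difference: degenerate inputs")
    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    z = diff / se_diff
    p = 2.0 * stats.norm.sf(abs(z))
    return diff, se_diff, diff - zcrit * se_diff, diff + zcrit * se_diff, z, p


def classify(ci_low: float, ci_high: float, margins: MarginPair) -> Category:
    """Map a difference CI to one of the five noninferiority bands.

    See the module docstring for the ordered rules; inferiority before
    noninferiority, strict inequalities throughout.
    """
    if ci_low > ci_high:
        raise ValueError("ci_low must not exceed ci_high")
    if ci_low > margins.m100:
        return Category.INFERIOR_100
    if ci_low > margins.m20:
        return Category.INFERIOR_20
    if ci_high < margins.m20:
        return Category.NONINFERIOR_20
    if ci_high < margins.m100:
        return Category.NONINFERIOR_100
    return Category.INCONCLUSIVE


def _benchmark_one(
    groups,
    t: float,
    config: BenchmarkConfig,
    stratum: str,
) -> Optional[BenchmarkReport]:
    estimates = []
    for key, records in groups.items():
        try:
            estimates.append(km_net_failure(records, t, alpha=config.alpha, construct=key))
        except ValueError as exc:
            logger.warning("t=%g stratum=%s: skipping %s (%s)", t, stratum, key.label, exc)
    try:
        reference = select_reference(estimates, config.ref_min_at_risk)
    except ReferenceSelectionError as exc:
        logger.warning("t=%g stratum=%s: %s; report omitted", t, stratum, exc)
        return None
    ref_est = next(e for e in estimates if e.construct == reference)
    margins = margins_from_reference(ref_est.failure, config.margins_relative)
    if margins.degenerate:
        logger.warning(
            "t=%g stratum=%s: reference failure is 0; margins degenerate", t, stratum
        )
    comparators = eligible_comparators(estimates, reference, config.comp_min_at_risk)
    excluded = [
        (e.construct, e.n_at_risk)
        for e in estimates
        if e.n_at_risk < config.comp_min_at_risk and e.construct != reference
    ]
    for key, n in excluded:
        logger.info(
            "t=%g stratum=%s: %s excluded (%d at risk < %d)",
            t, stratum, key.label, n, config.comp_min_at_risk,
        )
    logger.info(
        "t=%g stratum=%s: reference %s (failure %.4f, %d at risk), %d comparators",
        t, stratum, reference.label, ref_est.failure, ref_est.n_at_risk, len(comparators),
    )
    rows = []
    for comp in comparators:
        if comp.degenerate:
            logger.warning(
                "t=%g stratum=%s: %s degenerate (risk set exhausted); skipped",
                t, stratum, comp.construct.label,
            )
            continue
        diff, se_diff, lo, hi, z, p = difference_test(comp, ref_est, config.alpha)
        rows.append(
            BenchmarkRow(
                construct=comp.construct,
                t=t,
                n_at_risk=comp.n_at_risk,
                failure=comp.failure,
                se=comp.se,
                diff=diff,
                se_diff=se_diff,
                ci_low=lo,
                ci_high=hi,
                z=z,
                p=p,
                category=classify(lo, hi, margins),
            )
        )
    rows.sort(key=lambda r: (r.diff, r.construct.label))
    return BenchmarkReport(
        t=t,
        reference=reference,
        reference_estimate=ref_est,
        margins=margins,
        rows=rows,
        stratum=stratum,
        excluded=excluded,
    )


def run_benchmark(
    registry: Registry,
    config: Optional[BenchmarkConfig] = None,
    **overrides,
) -> list[BenchmarkReport]:
    """Run the full benchmarking procedure over all time points (and strata).

    One report per (time point x stratum); a time point where no construct
    reaches the reference threshold is omitted with a logged reason and the
    run continues.  With ``stratify_by="gender"`` the reference, margins and
    eligibility are all recomputed within each stratum; records with unknown
    gender are excluded from stratified runs with a logged count.
    """
    if len(registry) == 0:
        raise ValueError("registry is empty")
    if config is None:
        config = BenchmarkConfig()
    if overrides:
        config = BenchmarkConfig(
            **{**{f: getattr(config, f) for f in BenchmarkConfig.__dataclass_fields__}, **overrides}
        )
    strata: list[tuple[str, list]] = []
    if config.stratify_by is None:
        strata.append(("all", list(registry)))
    elif config.stratify_by == "gender":
        known = [r for r in registry if r.gender != "unknown"]
        dropped = len(registry) - len(known)
        if dropped:
            logger.info("gender stratification: %d records with unknown gender excluded", dropped)
        for g in ("F", "M"):
            strata.append((g, [r for r in known if r.gender == g]))
    else:
        raise ValueError(f"unsupported stratification: {config.stratify_by!r}")

    reports: list[BenchmarkReport] = []
    for stratum, records in strata:
        if not records:
            logger.warning("stratum %s empty; skipped", stratum)
            continue
        groups = group_by_construct(records)
        for t in config.timepoints:
            report = _benchmark_one(groups, float(t), config, stratum)
            if report is not None:
                reports.append(report)
    return reports


def report_to_frame(report: BenchmarkReport) -> pd.DataFrame:
    """Tidy export of one report: the benchmark CSV schema."""
    ref = report.reference_estimate
    return pd.DataFrame(
        {
            "t_years": [report.t] * len(report.rows),
            "stratum": [report.stratum] * len(report.rows),
            "reference": [report.reference.label] * len(report.rows),
            "ref_failure": [ref.failure] * len(report.rows),
            "ref_ci_low": [ref.ci_low] * len(report.rows),
            "ref_ci_high": [ref.ci_high] * len(report.rows),
            "construct": [r.construct.label for r in report.rows],
            "n_at_risk": [r.n_at_risk for r in report.rows],
            "failure": [r.failure for r in report.rows],
            "diff": [r.diff for r in report.rows],
            "se_diff": [r.se_diff for r in report.rows],
            "ci_low": [r.ci_low for r in report.rows],
            "ci_high": [r.ci_high for r in report.rows],
            "z": [r.z for r in report.rows],
            "p": [r.p for r in report.rows],
            "category": [r.category.value for r in report.rows],
        }
    )
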