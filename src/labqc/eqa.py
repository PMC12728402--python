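"""Multirule screening of EQA data, quality indicators and proportion tests.

Laboratories usually only investigate *unacceptable* external quality
assessment (EQA) results.  The multirule screen here mines the acceptable
results too: a series of EQA events for one analyte/scheme, each carrying
the measured value, the consensus group mean and SD, and the allowable
total error (TEa), is checked against decision rules built on two metrics —
the percentage deviation ``pd = 100 * (measured - group_mean) / group_mean``
and the standard deviation index ``SDI = (measured - group_mean) /
group_sd``.  Fired rules are screening flags for potential systematic or
random error (prompting calibration or preventive action), not inferential
claims, so no multiplicity correction is applied across analytes.

Default rule set (all thresholds strict; events are analysed in date
order):

============  ==========================================  =========  =============
rule          fires when                                  severity   error type
============  ==========================================  =========  =============
1_TEa         |pd| > TEa (unacceptable event)             rejection  indeterminate
1_75pTEa      |pd| > 0.75 * TEa                           warning    indeterminate
same_side     all events (n >= 5) deviate on one side     warning    systematic
2of3_2SDI     >= 2 of 3 consecutive SDI beyond +-2,       warning    systematic
              on the same side
R_range       max SDI - min SDI > 4 over the series       warning    random
============  ==========================================  =========  =============
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sstats

from .datamodel import (
    EQAEvent,
    ErrorType,
    IndicatorName,
    IndicatorValue,
    RuleViolation,
    Severity,
)

__all__ = [
    "EQARuleConfig",
    "DEFAULT_EQA_RULES",
    "EQASeriesAnalysis",
    "percent_deviation",
    "acceptability",
    "multirule_analyze",
    "indicator",
    "ProportionTest",
    "compare_proportions",
]

_EQA_RULE_IDS = ("1_TEa", "1_75pTEa", "same_side", "2of3_2SDI", "R_range")


@dataclass(frozen=True)
class EQARuleConfig:
    """Configuration of the EQA multirule screen."""

    enabled_rules: tuple[str, ...] = _EQA_RULE_IDS
    min_same_side: int = 5
    sdi_limit: float = 2.0
    r_range_span: float = 4.0
    tea_warning_fraction: float = 0.75
    allow_unacceptable: bool = False

    def __post_init__(self) -> None:
        for rule in self.enabled_rules:
            if rule not in _EQA_RULE_IDS:
                raise ValueError(f"unknown EQA rule id: {rule!r}")
        if self.min_same_side < 1:
            raise ValueError("min_same_side must be >= 1")
        if not (0 < self.tea_warning_fraction < 1):
            raise ValueError("tea_warning_fraction must be in (0, 1)")


DEFAULT_EQA_RULES = EQARuleConfig()


def percent_deviation(measured: float, group_mean: float) -> float:
    """Signed percentage deviation of a result from the group mean."""
    if group_mean == 0:
        raise ValueError("group_mean must be nonzero")
    return 100.0 * (measured - group_mean) / group_mean


def acceptability(pd: float, tea: float) -> str:
    """Grade one EQA result: unacceptable iff |pd| strictly exceeds TEa."""
    if tea <= 0:
        raise ValueError("tea must be positive")
    return "unacceptable" if abs(pd) > tea else "acceptable"


@dataclass(frozen=True)
class EQASeriesAnalysis:
    """Multirule screen of one date-ordered EQA series."""

    events: tuple[EQAEvent, ...]
    pd: tuple[float, ...]
    sdi: tuple[float, ...]
    violations: tuple[RuleViolation, ...]
    classification: str  # no_flag | potential_systematic | potential_random | both


def multirule_analyze(
    events: Sequence[EQAEvent], config: EQARuleConfig = DEFAULT_EQA_RULES
) -> EQASeriesAnalysis:
    """Screen a series of EQA events for latent systematic or random error.

    Events are sorted by date (ties broken by sample id) before any rule is
    applied, so violation indices always refer to the chronological series.
    The series is expected to consist of acceptable results; an unacceptable
    event raises unless ``config.allow_unacceptable`` (in which case the
    1_TEa rule flags it).
    """
    if not events:
        raise ValueError("cannot analyze an empty EQA series")
    ordered = tuple(sorted(events, key=lambda e: (e.date, e.sample_id)))
    pds = tuple(percent_deviation(e.measured, e.group_mean) for e in ordered)
    sdis = tuple((e.measured - e.group_mean) / e.group_sd for e in ordered)

    if not config.allow_unacceptable:
        bad = [i for i, (e, p) in enumerate(zip(ordered, pds)) if abs(p) > e.tea]
        if bad:
            raise ValueError(
                f"series contains unacceptable events at positions {bad}; "
                "set allow_unacceptable=True to screen mixed series"
            )

    violations: list[RuleViolation] = []
    n = len(ordered)
    for rule in config.enabled_rules:
        if rule == "1_TEa":
            for i, (e, p) in enumerate(zip(ordered, pds)):
                if abs(p) > e.tea:
                    violations.append(
                        RuleViolation(rule, (i,), Severity.REJECTION, ErrorType.INDETERMINATE)
                    )
        elif rule == "1_75pTEa":
            for i, (e, p) in enumerate(zip(ordered, pds)):
                if abs(p) > config.tea_warning_fraction * e.tea:
                    violations.append(
                        RuleViolation(rule, (i,), Severity.WARNING, ErrorType.INDETERMINATE)
                    )
        elif rule == "same_side":
            if n >= config.min_same_side and (
                all(p > 0 for p in pds) or all(p < 0 for p in pds)
            ):
                violations.append(
                    RuleViolation(rule, tuple(range(n)), Severity.WARNING, ErrorType.SYSTEMATIC)
                )
        elif rule == "2of3_2SDI":
            for start in range(n - 2):
                win = sdis[start : start + 3]
                for sign in (1, -1):
                    hits = tuple(
                        start + j
                        for j, s in enumerate(win)
                        if sign * s > config.sdi_limit
                    )
                    if len(hits) >= 2:
                        violations.append(
                            RuleViolation(
                                "2of3_2SDI", hits, Severity.WARNING, ErrorType.SYSTEMATIC
                            )
                        )
        elif rule == "R_range":
            if n >= 2 and max(sdis) - min(sdis) > config.r_range_span:
                lo = int(np.argmin(sdis))
                hi = int(np.argmax(sdis))
                violations.append(
                    RuleViolation(
                        "R_range",
                        tuple(sorted((lo, hi))),
                        Severity.WARNING,
                        ErrorType.RANDOM,
                    )
                )
    # overlapping 2of3 windows can nominate the same pair twice; keep one
    violations = sorted(
        set(violations), key=lambda v: (v.indices[0], v.indices[-1], v.rule_id)
    )

    has_sys = any(v.error_type is ErrorType.SYSTEMATIC for v in violations)
    has_rand = any(v.error_type is ErrorType.RANDOM for v in violations)
    if has_sys and has_rand:
        classification = "both"
    elif has_sys:
        classification = "potential_systematic"
    elif has_rand:
        classification = "potential_random"
    else:
        classification = "no_flag"
    return EQASeriesAnalysis(
        events=ordered,
        pd=pds,
        sdi=sdis,
        violations=tuple(violations),
        classification=classification,
    )


def indicator(
    name: IndicatorName | str,
    numerator_events,
    denominator_events,
    period: str = "",
) -> IndicatorValue:
    """Build one of the five ratio-type quality indicators.

    ``numerator_events`` / ``denominator_events`` may be counts or sized
    collections.  A zero denominator yields an indeterminate indicator
    (rate ``None``), never 0 %.
    """
    name = IndicatorName(name)
    num = numerator_events if isinstance(numerator_events, int) else len(numerator_events)
    den = (
        denominator_events
        if isinstance(denominator_events, int)
        else len(denominator_events)
    )
    if num < 0 or den < 0 or num > den:
        raise ValueError(f"need 0 <= numerator <= denominator, got {num}/{den}")
    rate = 100.0 * num / den if den > 0 else None
    return IndicatorValue(name=name, numerator=num, denominator=den, rate=rate, period=period)


@dataclass(frozen=True)
class ProportionTest:
    """Two-sided comparison of two binomial proportions."""

    statistic: Optional[float]
    p_value: float
    method: str  # chisq | chisq_yates | fisher
    p1: float
    p2: float


def compare_proportions(
    n1: int, x1: int, n2: int, x2: int, method: str = "auto"
) -> ProportionTest:
    """Compare x1/n1 against x2/n2 with a chi-square or Fisher exact test.

    ``method`` is one of ``chisq`` (Pearson, no correction), ``chisq_yates``
    (continuity-corrected, appropriate for 2x2 tables), ``fisher`` (exact,
    for small or zero cell counts) or ``auto``, which picks Fisher whenever
    any expected cell count is below 5 and the Yates-corrected chi-square
    otherwise.  All p-values are two-sided.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("event counts must satisfy 0 <= x <= n")

    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    if method == "auto":
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        method = "fisher" if (expected < 5).any() else "chisq_yates"

    if method == "fisher":
        res = sstats.fisher_exact(table, alternative="two-sided")
        stat, p = None, float(res.pvalue)
    elif method in ("chisq", "chisq_yates"):
        if (table.sum(axis=0) == 0).any():
            # degenerate margin: chi-square undefined, identical proportions
            stat, p = 0.0, 1.0
        else:
            chi2, p, _, _ = sstats.chi2_contingency(
                table, correction=(method == "chisq_yates")
            )
            stat, p = float(chi2), float(p)
    else:
        raise ValueError(f"unknown method: {method!r}")
    return ProportionTest(
        statistic=stat,
        p_value=min(1.0, p),
        method=method,
        p1=x1 / n1,
        p2=x2 / n2,
    )
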