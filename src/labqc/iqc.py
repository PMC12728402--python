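"""Levey-Jennings statistics and configurable Westgard multirule evaluation.

Control results are standardized against *fixed* target limits taken from a
:class:`~labqc.datamodel.ControlSpec` (the laboratory sets its control
parameters before monitoring starts, so limits never follow the data; a
helper to fit a spec from a baseline period exists but is never implicit).

Rule semantics (classic Westgard set, all thresholds strict — a point
exactly on a limit does not fire, except the R_4s span which uses >= 4 by
its range definition):

========  ==========================================  =========  =============
rule      fires when                                  severity   error type
========  ==========================================  =========  =============
1_2s      |z| > 2                                     warning    indeterminate
1_3s      |z| > 3                                     rejection  indeterminate
2_2s      2 consecutive z on the same side, |z| > 2   rejection  systematic
R_4s      consecutive pair, opposite signs, span >= 4 rejection  random
4_1s      4 consecutive on one side with |z| > 1      rejection  systematic
10_x      10 consecutive on one side of the mean      rejection  systematic
========  ==========================================  =========  =============

Window rules (2_2s, 4_1s, 10_x) fire once per qualifying window, so a run of
5 points beyond 1s yields two overlapping 4_1s violations.  Within a single
series, consecutive points are treated as belonging to the same analytical
run for the pair rules; cross-level within-run evaluation can be done by
interleaving the levels of one run into a single series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    ControlSpec,
    ErrorType,
    LJStatistics,
    RuleViolation,
    Severity,
)

__all__ = [
    "RuleConfig",
    "DEFAULT_RULES",
    "zscores",
    "evaluate_rules",
    "lj_statistics",
    "cv_failure",
    "monthly_summary",
    "MonthlySummaryItem",
    "fit_control_spec",
]

_RULE_TABLE: dict[str, tuple[Severity, ErrorType]] = {
    "1_2s": (Severity.WARNING, ErrorType.INDETERMINATE),
    "1_3s": (Severity.REJECTION, ErrorType.INDETERMINATE),
    "2_2s": (Severity.REJECTION, ErrorType.SYSTEMATIC),
    "R_4s": (Severity.REJECTION, ErrorType.RANDOM),
    "4_1s": (Severity.REJECTION, ErrorType.SYSTEMATIC),
    "10_x": (Severity.REJECTION, ErrorType.SYSTEMATIC),
}


@dataclass(frozen=True)
class RuleConfig:
    """Which rules run and with which window lengths."""

    enabled_rules: tuple[str, ...] = ("1_2s", "1_3s", "2_2s", "R_4s", "4_1s", "10_x")
    windows: Mapping[str, int] = field(
        default_factory=lambda: {"2_2s": 2, "4_1s": 4, "10_x": 10}
    )

    def __post_init__(self) -> None:
        for rule in self.enabled_rules:
            if rule not in _RULE_TABLE:
                raise ValueError(f"unknown rule id: {rule!r}")
        for rule, w in self.windows.items():
            if w < 1:
                raise ValueError(f"window for {rule} must be >= 1, got {w}")

    def window(self, rule: str, default: int) -> int:
        return int(self.windows.get(rule, default))


DEFAULT_RULES = RuleConfig()


def zscores(values: Sequence[float], spec: ControlSpec) -> np.ndarray:
    """Standardize control values against the spec's fixed target limits."""
    if spec.target_sd <= 0:
        raise ValueError("target_sd must be positive")
    return (np.asarray(values, dtype=float) - spec.target_mean) / spec.target_sd


def evaluate_rules(
    z: Sequence[float], config: RuleConfig = DEFAULT_RULES
) -> list[RuleViolation]:
    """Apply the configured Westgard rules to a standardized control series.

    Returns one :class:`RuleViolation` per qualifying point or window,
    sorted by first index then rule id; the result is deterministic.
    """
    z = np.asarray(z, dtype=float)
    if z.size and not np.all(np.isfinite(z)):
        raise ValueError("z-scores must be finite")

    violations: list[RuleViolation] = []
    for rule in config.enabled_rules:
        severity, etype = _RULE_TABLE[rule]
        if rule == "1_2s":
            idx = np.flatnonzero(np.abs(z) > 2)
            violations.extend(
                RuleViolation(rule, (int(i),), severity, etype) for i in idx
            )
        elif rule == "1_3s":
            idx = np.flatnonzero(np.abs(z) > 3)
            violations.extend(
                RuleViolation(rule, (int(i),), severity, etype) for i in idx
            )
        elif rule == "2_2s":
            w = config.window("2_2s", 2)
            violations.extend(
                RuleViolation(rule, win, severity, etype)
                for win in _same_side_windows(z, 2.0, w)
            )
        elif rule == "R_4s":
            if z.size >= 2:
                opposite = z[1:] * z[:-1] < 0
                wide = np.abs(np.diff(z)) >= 4
                for i in np.flatnonzero(opposite & wide):
                    violations.append(
                        RuleViolation(rule, (int(i), int(i) + 1), severity, etype)
                    )
        elif rule == "4_1s":
            w = config.window("4_1s", 4)
            violations.extend(
                RuleViolation(rule, win, severity, etype)
                for win in _same_side_windows(z, 1.0, w)
            )
        elif rule == "10_x":
            w = config.window("10_x", 10)
            violations.extend(
                RuleViolation(rule, win, severity, etype)
                for win in _same_side_windows(z, 0.0, w)
            )
    violations.sort(key=lambda v: (v.indices[0], v.indices[-1], v.rule_id))
    return violations


def _same_side_windows(
    z: np.ndarray, limit: float, width: int
) -> Iterable[tuple[int, ...]]:
    """Windows of ``width`` consecutive points all beyond ``limit`` on one side."""
    if z.size < width:
        return []
    windows: list[tuple[int, ...]] = []
    for mask in (z > limit, z < -limit):
        if width == 1:
            hits = mask.astype(int)
        else:
            hits = np.convolve(mask.astype(int), np.ones(width, dtype=int), "valid")
        for i in np.flatnonzero(hits == width):
            windows.append(tuple(range(int(i), int(i) + width)))
    windows.sort()
    return windows


def lj_statistics(
    observations,
    spec: Optional[ControlSpec] = None,
    period: Optional[tuple[datetime, datetime]] = None,
) -> LJStatistics:
    """Mean, sample SD (n-1) and CV of a control series.

    ``observations`` may be a plain sequence of values or an observation
    DataFrame (its ``value``/``timestamp`` columns are used).  When a period
    is given only observations with ``start <= timestamp < end`` count.
    With fewer than two points the SD and CV are absent, not zero; with a
    spec the percent bias of the mean versus the target is included.
    """
    if isinstance(observations, pd.DataFrame):
        df = observations
        if period is not None:
            start, end = period
            df = df[(df["timestamp"] >= start) & (df["timestamp"] < end)]
        values = df["value"].to_numpy(dtype=float)
    else:
        values = np.asarray(list(observations), dtype=float)

    n = int(values.size)
    if n == 0:
        return LJStatistics(n=0, mean=None, sd=None, cv=None, period=period)
    mean = float(np.mean(values))
    bias = None
    if spec is not None and spec.target_mean != 0:
        bias = 100.0 * (mean - spec.target_mean) / spec.target_mean
    if n < 2:
        return LJStatistics(n=n, mean=mean, sd=None, cv=None, period=period, bias=bias)
    sd = float(np.std(values, ddof=1))
    cv = 100.0 * sd / mean if mean != 0 else None
    return LJStatistics(n=n, mean=mean, sd=sd, cv=cv, period=period, bias=bias)


def cv_failure(stats: LJStatistics, spec: ControlSpec) -> Optional[bool]:
    """True when the observed CV strictly exceeds the allowable CV.

    Returns ``None`` (indeterminate) when the CV is absent; indeterminate
    items are excluded from failure-rate denominators.
    """
    if stats.cv is None:
        return None
    return stats.cv > spec.cv_requirement


@dataclass(frozen=True)
class MonthlySummaryItem:
    """One analyte/level/lot record of a monthly IQC summary."""

    analyte: str
    level: int
    lot_id: str
    stats: LJStatistics
    violations: tuple[RuleViolation, ...]
    cv_failed: Optional[bool]
    out_of_control: bool


def monthly_summary(
    observations: pd.DataFrame,
    specs: Sequence[ControlSpec],
    month: str,
    config: RuleConfig = DEFAULT_RULES,
) -> list[MonthlySummaryItem]:
    """Per analyte/level/lot Levey-Jennings summary for a calendar month.

    ``month`` is ``"YYYY-MM"``.  Each item carries the month's statistics,
    the rule violations of the date-ordered series, the CV verdict, and an
    out-of-control flag (any rejection-severity violation).  Items are
    ordered by (analyte, level, lot).
    """
    start = pd.Timestamp(f"{month}-01")
    end = start + pd.offsets.MonthBegin(1)
    window = observations[
        (observations["timestamp"] >= start) & (observations["timestamp"] < end)
    ]
    spec_map = {s.key(): s for s in specs}

    items: list[MonthlySummaryItem] = []
    for key, grp in window.groupby(["analyte", "level", "lot_id"], sort=True):
        analyte, level, lot_id = key
        spec = spec_map.get((analyte, int(level), lot_id))
        grp = grp.sort_values("timestamp", kind="mergesort")
        stats = lj_statistics(grp, spec, period=(start.to_pydatetime(), end.to_pydatetime()))
        if spec is None:
            items.append(
                MonthlySummaryItem(analyte, int(level), lot_id, stats, (), None, False)
            )
            continue
        z = zscores(grp["value"].to_numpy(), spec)
        violations = tuple(evaluate_rules(z, config))
        failed = cv_failure(stats, spec)
        out = any(v.severity is Severity.REJECTION for v in violations)
        items.append(
            MonthlySummaryItem(analyte, int(level), lot_id, stats, violations, failed, out)
        )
    return items


def fit_control_spec(
    values: Sequence[float],
    *,
    analyte: str,
    level: int,
    lot_id: str,
    cv_requirement: float,
    tea: float,
    unit: str,
) -> ControlSpec:
    """Fit fixed control limits from a baseline period (explicit, never implicit).

    Requires at least 20 baseline points — the conventional minimum for
    establishing control limits.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size < 20:
        raise ValueError("need >= 20 baseline observations to set control limits")
    return ControlSpec(
        analyte=analyte,
        level=level,
        lot_id=lot_id,
        target_mean=float(np.mean(values)),
        target_sd=float(np.std(values, ddof=1)),
        cv_requirement=cv_requirement,
        tea=tea,
        unit=unit,
    )
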