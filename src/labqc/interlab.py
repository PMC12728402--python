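"""Consensus-group construction and SDI/CVR interlaboratory comparison.

A laboratory's IQC data can stand in for external quality assessment when it
is compared against consensus statistics built from other laboratories
running the same control material.  Three group definitions are supported:

* **affiliated** — every laboratory in the configured network (an ad hoc
  consensus group);
* **peer** — laboratories sharing instrument + reagent + method
  (partitioned on the ``peer_key`` column);
* **method** — laboratories sharing a methodology code (``method_code``).

Two consensus metrics are computed: the standard deviation index
``SDI = (lab_mean - group_mean) / group_sd`` (bias) and the CV ratio
``CVR = lab_cv / group_cv`` (imprecision).  Verdicts come from configurable
tier tables; the defaults are the conventional ones (|SDI| <= 1.25
acceptable, <= 2.0 monitor, above that unacceptable; CVR <= 1.0 acceptable,
<= 1.5 monitor).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Optional

import numpy as np
import pandas as pd

from .datamodel import ComparisonReport, GroupStats, GroupType, LJStatistics, Verdict

__all__ = [
    "Thresholds",
    "DEFAULT_THRESHOLDS",
    "build_groups",
    "sdi",
    "cvr",
    "verdict_from_sdi",
    "verdict_from_cvr",
    "compare",
]


@dataclass(frozen=True)
class Thresholds:
    """Tier limits for the bias (|SDI|) and imprecision (CVR) verdicts."""

    sdi_acceptable: float = 1.25
    sdi_monitor: float = 2.0
    cvr_acceptable: float = 1.0
    cvr_monitor: float = 1.5

    def __post_init__(self) -> None:
        if not (0 < self.sdi_acceptable <= self.sdi_monitor):
            raise ValueError("require 0 < sdi_acceptable <= sdi_monitor")
        if not (0 < self.cvr_acceptable <= self.cvr_monitor):
            raise ValueError("require 0 < cvr_acceptable <= cvr_monitor")


DEFAULT_THRESHOLDS = Thresholds()


def sdi(lab_mean: float, group_mean: float, group_sd: float) -> float:
    """Standard deviation index: lab bias in units of the group SD."""
    if group_sd <= 0:
        raise ValueError("group_sd must be positive")
    return (lab_mean - group_mean) / group_sd


def cvr(lab_cv: float, group_cv: float) -> float:
    """Coefficient of variation ratio: lab imprecision relative to the group."""
    if group_cv <= 0:
        raise ValueError("group_cv must be positive")
    return lab_cv / group_cv


def build_groups(
    observations: pd.DataFrame,
    group_type: GroupType | str,
    *,
    window: Optional[tuple[datetime, datetime]] = None,
    exclude_lab: Optional[str] = None,
) -> dict[tuple, GroupStats]:
    """Pool observations into consensus groups and compute their statistics.

    Returns a mapping from ``(analyte, level, lot_id)`` (affiliated) or
    ``(analyte, level, lot_id, group_key)`` (peer/method) to
    :class:`GroupStats`.  Group mean/SD pool the raw member observations,
    not lab means; both the number of points and the number of contributing
    laboratories are reported.  By default the evaluated laboratory's own
    data is part of its group; pass ``exclude_lab`` to leave one lab out.
    Single-laboratory groups are computed but flagged ``low_n``.
    """
    group_type = GroupType(group_type)
    df = observations
    if window is not None:
        start, end = window
        df = df[(df["timestamp"] >= start) & (df["timestamp"] < end)]
    if exclude_lab is not None:
        df = df[df["lab_id"] != exclude_lab]

    if group_type is GroupType.AFFILIATED:
        keys = ["analyte", "level", "lot_id"]
    elif group_type is GroupType.PEER:
        keys = ["analyte", "level", "lot_id", "peer_key"]
    else:
        keys = ["analyte", "level", "lot_id", "method_code"]

    groups: dict[tuple, GroupStats] = {}
    for key, grp in df.groupby(keys, sort=True):
        values = grp["value"].to_numpy(dtype=float)
        n_labs = int(grp["lab_id"].nunique())
        n_points = int(values.size)
        mean = float(np.mean(values)) if n_points else None
        if n_points >= 2:
            sd = float(np.std(values, ddof=1))
            cv = 100.0 * sd / mean if mean else None
        else:
            sd = cv = None
        groups[tuple(key)] = GroupStats(
            group_type=group_type,
            n_labs=n_labs,
            n_points=n_points,
            mean=mean,
            sd=sd,
            cv=cv,
            low_n=n_labs < 2,
        )
    return groups


def verdict_from_sdi(value: float, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> Verdict:
    a = abs(value)
    if a <= thresholds.sdi_acceptable:
        return Verdict.ACCEPTABLE
    if a <= thresholds.sdi_monitor:
        return Verdict.MONITOR
    return Verdict.UNACCEPTABLE


def verdict_from_cvr(value: float, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> Verdict:
    if value <= thresholds.cvr_acceptable:
        return Verdict.ACCEPTABLE
    if value <= thresholds.cvr_monitor:
        return Verdict.MONITOR
    return Verdict.UNACCEPTABLE


def compare(
    lab_stats: LJStatistics,
    group_stats: GroupStats,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    window: str = "monthly",
) -> ComparisonReport:
    """Score one laboratory against its consensus group.

    SDI needs the lab mean and a positive group SD; CVR needs both CVs.
    A metric whose inputs are absent yields no value and no verdict.
    """
    sdi_val = cvr_val = None
    verdict_bias = verdict_imprecision = None
    if (
        lab_stats.mean is not None
        and group_stats.mean is not None
        and group_stats.sd is not None
        and group_stats.sd > 0
    ):
        sdi_val = sdi(lab_stats.mean, group_stats.mean, group_stats.sd)
        verdict_bias = verdict_from_sdi(sdi_val, thresholds)
    if lab_stats.cv is not None and group_stats.cv is not None and group_stats.cv > 0:
        cvr_val = cvr(lab_stats.cv, group_stats.cv)
        verdict_imprecision = verdict_from_cvr(cvr_val, thresholds)
    return ComparisonReport(
        lab_stats=lab_stats,
        group_stats=group_stats,
        sdi=sdi_val,
        cvr=cvr_val,
        window=window,
        verdict_bias=verdict_bias,
        verdict_imprecision=verdict_imprecision,
    )
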