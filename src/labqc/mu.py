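"""Top-down measurement uncertainty from IQC and EQA data.

The model is the standard top-down (Nordtest-style) decomposition used by
clinical laboratories: the within-laboratory reproducibility component
``u_Rw`` is the long-term IQC coefficient of variation, the trueness
component ``u_bias`` combines the root-mean-square of historical EQA
percent deviations with the standard uncertainty of the assigned value
``u_cref``, and

    u_c = sqrt(u_Rw^2 + u_bias^2),        U = k * u_c

with ``k = 2`` giving approximately 95 % coverage.  All components are
*relative* standard uncertainties in percent.

Two clinical applications are provided on top of the estimate:

* a coverage interval around a patient result,
  ``result * (1 -+ U/100)``, used when a value sits near a decision limit;
* the minimum significant difference between two serial results,
  ``z * sqrt(2) * u_c/100 * value`` (a reference-change-value style
  threshold with the biological variation term set to zero), used to
  separate genuine change from analytical noise.  The reference value is
  the earlier of the two results.

Comparisons always use unrounded values; concentrations and percentages are
rounded to two decimals only for display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .datamodel import EQAEvent, MUInput, MULevelReport, MUReport

__all__ = [
    "u_rw_from_iqc",
    "u_bias_from_eqa",
    "default_u_cref",
    "combine_and_expand",
    "result_interval",
    "min_significant_difference",
    "SerialComparison",
    "is_significant",
    "mu_report",
]


def u_rw_from_iqc(
    iqc_cv: float | Sequence[float], n: Optional[Sequence[int]] = None
) -> float:
    """Within-laboratory reproducibility component from long-term IQC.

    For a single control lot this is simply the lot's CV (percent).  When a
    level spans several lots, the lot CVs are pooled as the square root of
    the variance-weighted mean of CV^2 with weights ``n_lot - 1``::

        u_Rw = sqrt( sum (n_i - 1) cv_i^2 / sum (n_i - 1) )

    With ``n`` omitted the lots are weighted equally.
    """
    if np.isscalar(iqc_cv):
        cvs = np.array([float(iqc_cv)])
    else:
        cvs = np.asarray(list(iqc_cv), dtype=float)
    if cvs.size == 0:
        raise ValueError("no IQC data: at least one CV is required")
    if np.any(cvs <= 0):
        raise ValueError("every IQC CV must be positive")
    if n is None:
        weights = np.ones_like(cvs)
    else:
        weights = np.asarray(list(n), dtype=float) - 1.0
        if weights.shape != cvs.shape:
            raise ValueError("n must match the number of CVs")
        if np.any(weights <= 0):
            raise ValueError("each lot needs n >= 2")
    return float(math.sqrt(np.sum(weights * cvs**2) / np.sum(weights)))


def u_bias_from_eqa(biases: Sequence[float], u_cref: float = 0.0) -> float:
    """Trueness component from historical EQA percent deviations.

    ``u_bias = sqrt(RMS_bias^2 + u_cref^2)`` where ``RMS_bias`` is the
    root-mean-square of the EQA percent deviations and ``u_cref`` the
    relative standard uncertainty of the assigned value (0 when the
    consensus value is treated as exact).
    """
    biases = np.asarray(list(biases), dtype=float)
    if biases.size == 0:
        raise ValueError("at least one EQA bias is required")
    if u_cref < 0:
        raise ValueError("u_cref must be >= 0")
    rms = math.sqrt(float(np.mean(biases**2)))
    return math.sqrt(rms**2 + u_cref**2)


def default_u_cref(events: Sequence[EQAEvent]) -> float:
    """Assigned-value uncertainty policy for consensus-graded schemes.

    Per event the relative standard uncertainty of a consensus mean of
    ``n_labs`` participants is ``100 * group_sd / (group_mean * sqrt(n_labs))``;
    events that carry an explicit ``u_cref`` use it directly.  The per-event
    values are averaged in quadrature.  This helper needs the participant
    count, which the EQA record does not carry, so events lacking ``u_cref``
    are treated as exact (contribute 0); forcing 0 overall is a config choice.
    """
    if not events:
        raise ValueError("at least one EQA event is required")
    vals = [e.u_cref if e.u_cref is not None else 0.0 for e in events]
    return float(math.sqrt(np.mean(np.square(vals))))


def combine_and_expand(u_rw: float, u_bias: float, k: float = 2.0) -> tuple[float, float]:
    """Combined and expanded relative uncertainty (percent)."""
    if k <= 0:
        raise ValueError("coverage factor k must be positive")
    u_c = math.hypot(u_rw, u_bias)
    return u_c, k * u_c


@dataclass(frozen=True)
class ResultInterval:
    """Coverage interval around a patient result."""

    result: float
    lower: float
    upper: float
    u_expanded_rel: float

    @property
    def rounded(self) -> tuple[float, float]:
        return (round(self.lower, 2), round(self.upper, 2))


def result_interval(result: float, u_expanded_rel: float) -> ResultInterval:
    """Interval ``result -+ result * U/100`` at the coverage of ``U``.

    The raw bounds are retained; ``.rounded`` gives the 2-decimal display
    form.
    """
    if result <= 0:
        raise ValueError("result must be positive")
    if u_expanded_rel < 0:
        raise ValueError("expanded uncertainty must be >= 0")
    half = result * u_expanded_rel / 100.0
    return ResultInterval(result, result - half, result + half, u_expanded_rel)


def min_significant_difference(value: float, u_c_rel: float, z: float = 1.96) -> float:
    """Smallest serial difference not attributable to analytical variation.

    ``threshold = z * sqrt(2) * (u_c/100) * value`` — the sqrt(2) reflects
    that both results carry the analytical uncertainty ``u_c``.
    """
    if u_c_rel <= 0:
        raise ValueError("u_c must be positive")
    if z <= 0:
        raise ValueError("z must be positive")
    return z * math.sqrt(2.0) * (u_c_rel / 100.0) * value


@dataclass(frozen=True)
class SerialComparison:
    """Verdict on whether two serial results differ significantly."""

    earlier: float
    later: float
    difference: float
    threshold: float
    significant: bool


def is_significant(
    v1: float, v2: float, u_c_rel: float, z: float = 1.96
) -> SerialComparison:
    """Compare two serial results against the minimum significant difference.

    The threshold is anchored on the earlier result ``v1``; the pair is
    significant iff ``|v1 - v2|`` strictly exceeds it.
    """
    threshold = min_significant_difference(v1, u_c_rel, z)
    diff = abs(v1 - v2)
    return SerialComparison(
        earlier=v1,
        later=v2,
        difference=diff,
        threshold=threshold,
        significant=diff > threshold,
    )


def mu_report(inp: MUInput) -> MUReport:
    """One-call per-level uncertainty report with the quality-goal verdict.

    For every control level: ``u_Rw`` is the level's IQC CV, ``u_bias``
    pools the shared EQA deviation history with ``u_cref``, ``u_c`` and the
    expanded ``U = k * u_c`` follow, and the goal is met iff
    ``U <= quality_goal`` (unrounded comparison).
    """
    u_bias = u_bias_from_eqa(inp.eqa_biases, inp.u_cref)
    levels = []
    for lvl in inp.levels:
        try:
            u_rw = u_rw_from_iqc(lvl.iqc_cv)
            u_c, u_exp = combine_and_expand(u_rw, u_bias, inp.k)
        except ValueError as exc:
            raise ValueError(f"level {lvl.level}: {exc}") from exc
        levels.append(
            MULevelReport(
                level=lvl.level,
                iqc_mean=lvl.iqc_mean,
                u_rw=u_rw,
                u_bias=u_bias,
                u_c=u_c,
                u_expanded=u_exp,
                goal_met=u_exp <= inp.quality_goal,
            )
        )
    return MUReport(
        analyte=inp.analyte,
        unit=inp.unit,
        k=inp.k,
        quality_goal=inp.quality_goal,
        eqa_biases=inp.eqa_biases,
        u_cref=inp.u_cref,
        levels=tuple(levels),
    )
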