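"""Domain types, validation and file conventions shared by all engines.

The package works on two representational levels:

* bulk control data is held in :class:`pandas.DataFrame` objects with the
  fixed column schemas declared below (``OBSERVATION_COLUMNS`` etc.), which
  is what the engines consume;
* single records and configuration objects are pydantic models so that
  anything entering the system through a file or the CLI is validated
  field-by-field.

Conventions used throughout:

* all rates and relative uncertainties are percentages on the 0-100 scale
  (an implementation rate of ``97.79`` means 97.79 %);
* periods are half-open intervals ``[start, end)``; "monthly" means a
  calendar month, with no timezone arithmetic;
* a standard deviation or CV requires at least two observations; statistics
  over fewer points are reported as absent (``None``), never as zero.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "OBSERVATION_COLUMNS",
    "SPEC_COLUMNS",
    "EQA_COLUMNS",
    "Severity",
    "ErrorType",
    "GroupType",
    "Verdict",
    "IndicatorName",
    "QCObservation",
    "ControlSpec",
    "LJStatistics",
    "RuleViolation",
    "GroupStats",
    "ComparisonReport",
    "EQAEvent",
    "MULevelInput",
    "MUInput",
    "MULevelReport",
    "MUReport",
    "IndicatorValue",
    "ValidationReport",
    "validate_dataset",
    "read_observations",
    "read_specs",
    "read_eqa",
    "write_observations",
    "write_specs",
    "write_eqa",
]

# Fixed, case-sensitive CSV schemas.
OBSERVATION_COLUMNS = [
    "lab_id", "instrument_id", "analyte", "level", "lot_id",
    "timestamp", "value", "method_code", "peer_key",
]
SPEC_COLUMNS = [
    "analyte", "level", "lot_id", "target_mean", "target_sd",
    "cv_requirement", "tea", "unit",
]
EQA_COLUMNS = [
    "scheme_id", "analyte", "sample_id", "date", "measured",
    "group_mean", "group_sd", "tea", "u_cref",
]

OBSERVATION_KEY = ["lab_id", "instrument_id", "analyte", "level", "lot_id", "timestamp"]


class Severity(str, enum.Enum):
    WARNING = "warning"
    REJECTION = "rejection"


class ErrorType(str, enum.Enum):
    SYSTEMATIC = "systematic"
    RANDOM = "random"
    INDETERMINATE = "indeterminate"


class GroupType(str, enum.Enum):
    AFFILIATED = "affiliated"
    PEER = "peer"
    METHOD = "method"


class Verdict(str, enum.Enum):
    ACCEPTABLE = "acceptable"
    MONITOR = "monitor"
    UNACCEPTABLE = "unacceptable"


class IndicatorName(str, enum.Enum):
    IQC_IMPLEMENTATION_RATE = "iqc_implementation_rate"
    IQC_CV_FAILURE_RATE = "iqc_cv_failure_rate"
    INTERLAB_COMPARISON_RATE_NO_EQA = "interlab_comparison_rate_no_eqa"
    EQA_COVERAGE_RATE = "eqa_coverage_rate"
    EQA_UNACCEPTABLE_RATE = "eqa_unacceptable_rate"


class QCObservation(BaseModel):
    """One control measurement: who ran it, on what, when, and the value."""

    model_config = ConfigDict(frozen=True)

    lab_id: str
    instrument_id: str
    analyte: str
    level: int = Field(ge=1)
    lot_id: str
    timestamp: datetime
    value: float
    method_code: str
    peer_key: str

    @model_validator(mode="after")
    def _finite_value(self) -> "QCObservation":
        if not math.isfinite(self.value):
            raise ValueError("observation value must be finite")
        return self


class ControlSpec(BaseModel):
    """Per analyte/level/lot control targets and quality requirements.

    ``target_mean``/``target_sd`` define the fixed Levey-Jennings limits;
    ``cv_requirement`` is the allowable CV and ``tea`` the allowable total
    error, both in percent.
    """

    model_config = ConfigDict(frozen=True)

    analyte: str
    level: int = Field(ge=1)
    lot_id: str
    target_mean: float
    target_sd: float = Field(gt=0)
    cv_requirement: float = Field(gt=0)
    tea: float = Field(gt=0)
    unit: str

    @property
    def target_cv(self) -> float:
        """Target CV in percent, ``100 * target_sd / target_mean``."""
        return 100.0 * self.target_sd / self.target_mean

    @model_validator(mode="after")
    def _finite_cv(self) -> "ControlSpec":
        if self.target_mean == 0 or not math.isfinite(self.target_cv):
            raise ValueError("target CV must be finite (target_mean must be nonzero)")
        return self

    def key(self) -> tuple[str, int, str]:
        return (self.analyte, self.level, self.lot_id)


@dataclass(frozen=True)
class LJStatistics:
    """Levey-Jennings summary of a control series over a period.

    ``sd`` and ``cv`` are ``None`` when fewer than two points are available.
    ``bias`` (percent vs the target mean) is populated when the statistics
    were computed against a :class:`ControlSpec`.
    """

    n: int
    mean: Optional[float]
    sd: Optional[float]
    cv: Optional[float]
    period: Optional[tuple[datetime, datetime]] = None
    bias: Optional[float] = None


@dataclass(frozen=True)
class RuleViolation:
    """A fired QC rule.

    ``indices`` are 0-based positions into the evaluated series, strictly
    increasing and identifying exactly the points that made the rule fire.
    """

    rule_id: str
    indices: tuple[int, ...]
    severity: Severity
    error_type: ErrorType

    def __post_init__(self) -> None:
        if not self.indices:
            raise ValueError("violation must reference at least one point")
        if any(b <= a for a, b in zip(self.indices, self.indices[1:])):
            raise ValueError("violation indices must be strictly increasing")


@dataclass(frozen=True)
class GroupStats:
    """Consensus-group statistics pooled over member-laboratory observations."""

    group_type: GroupType
    n_labs: int
    n_points: int
    mean: Optional[float]
    sd: Optional[float]
    cv: Optional[float]
    low_n: bool = False


@dataclass(frozen=True)
class ComparisonReport:
    """Interlaboratory comparison of one laboratory against a consensus group."""

    lab_stats: LJStatistics
    group_stats: GroupStats
    sdi: Optional[float]
    cvr: Optional[float]
    window: str  # "monthly" | "cumulative"
    verdict_bias: Optional[Verdict]
    verdict_imprecision: Optional[Verdict]


class EQAEvent(BaseModel):
    """One external quality assessment result with its group consensus."""

    model_config = ConfigDict(frozen=True)

    scheme_id: str
    analyte: str
    sample_id: str
    date: date
    measured: float
    group_mean: float
    group_sd: float = Field(gt=0)
    tea: float = Field(gt=0)
    u_cref: Optional[float] = Field(default=None, ge=0)


class MULevelInput(BaseModel):
    """IQC summary for one control level feeding the uncertainty estimate."""

    model_config = ConfigDict(frozen=True)

    level: int = Field(ge=1)
    iqc_mean: float = Field(gt=0)
    iqc_cv: float = Field(gt=0)
    n_iqc: int = Field(ge=2)
    period: Optional[str] = None


class MUInput(BaseModel):
    """Inputs for top-down measurement-uncertainty estimation.

    ``eqa_biases`` are the percent deviations of historical EQA results from
    their assigned values; they feed the trueness component shared by all
    levels.  ``u_cref`` is the relative standard uncertainty of the assigned
    value (0 when the consensus value is treated as exact). ``k`` is the
    coverage factor for the expanded uncertainty and ``quality_goal`` the
    allowable relative expanded uncertainty, both driving the verdict.
    """

    model_config = ConfigDict(frozen=True)

    analyte: str
    levels: tuple[MULevelInput, ...] = Field(min_length=1)
    eqa_biases: tuple[float, ...] = Field(min_length=1)
    u_cref: float = Field(default=0.0, ge=0)
    k: float = Field(default=2.0, gt=0)
    quality_goal: float = Field(gt=0)
    z_serial: float = Field(default=1.96, gt=0)
    unit: str = ""


@dataclass(frozen=True)
class MULevelReport:
    """Uncertainty components for one control level, all in percent."""

    level: int
    iqc_mean: float
    u_rw: float
    u_bias: float
    u_c: float
    u_expanded: float
    goal_met: bool


@dataclass(frozen=True)
class MUReport:
    """Per-level combined and expanded uncertainty with the goal verdict."""

    analyte: str
    unit: str
    k: float
    quality_goal: float
    eqa_biases: tuple[float, ...]
    u_cref: float
    levels: tuple[MULevelReport, ...]

    @property
    def all_goals_met(self) -> bool:
        return all(lvl.goal_met for lvl in self.levels)


@dataclass(frozen=True)
class IndicatorValue:
    """A ratio-type quality indicator over a period, on the 0-100 scale.

    ``rate`` is ``None`` (indeterminate) when the denominator is zero.
    """

    name: IndicatorName
    numerator: int
    denominator: int
    rate: Optional[float]
    period: str = ""


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_dataset`; entries are sorted for determinism."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    orphans: list[tuple[str, int, str]] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.errors


def validate_dataset(
    observations: pd.DataFrame,
    specs: Sequence[ControlSpec],
    *,
    require_positive: bool = True,
) -> ValidationReport:
    """Check a QC observation table against its control specifications.

    Flags duplicate observation keys and non-finite values as errors,
    non-positive values as errors when ``require_positive`` (the default for
    concentration-like units), and observations whose (analyte, level, lot)
    has no matching :class:`ControlSpec` as orphan warnings.  The report is
    deterministic and independent of row order.
    """
    report = ValidationReport()
    if observations.empty:
        return report

    missing = [c for c in OBSERVATION_COLUMNS if c not in observations.columns]
    if missing:
        report.errors.append(f"missing columns: {', '.join(sorted(missing))}")
        return report

    values = pd.to_numeric(observations["value"], errors="coerce")
    bad = observations.index[~values.apply(lambda v: pd.notna(v) and math.isfinite(v))]
    for idx in bad:
        report.errors.append(f"non-finite value at row {idx}")
    if require_positive:
        nonpos = observations.index[values.notna() & (values <= 0)]
        for idx in nonpos:
            report.errors.append(f"non-positive value at row {idx}")

    dup = observations.duplicated(subset=OBSERVATION_KEY, keep=False)
    if dup.any():
        for key, grp in observations[dup].groupby(OBSERVATION_KEY, sort=True):
            report.errors.append(
                f"duplicate observation key {tuple(key)} ({len(grp)} rows)"
            )

    spec_keys = {s.key() for s in specs}
    obs_keys = set(
        observations[["analyte", "level", "lot_id"]]
        .itertuples(index=False, name=None)
    )
    for key in sorted(obs_keys - spec_keys, key=lambda k: (k[0], k[1], k[2])):
        report.orphans.append(key)
        report.warnings.append(f"no control spec for {key}")

    report.errors.sort()
    report.warnings.sort()
    report.orphans.sort()
    return report


# ---------------------------------------------------------------------------
# CSV readers / writers


def read_observations(path) -> pd.DataFrame:
    """Read an observation table, parsing timestamps and checking the schema."""
    df = pd.read_csv(path, dtype={"lab_id": str, "instrument_id": str,
                                  "analyte": str, "lot_id": str,
                                  "method_code": str, "peer_key": str})
    _require_columns(df, OBSERVATION_COLUMNS, "observations")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["level"] = df["level"].astype(int)
    df["value"] = df["value"].astype(float)
    return df[OBSERVATION_COLUMNS]


def read_specs(path) -> list[ControlSpec]:
    df = pd.read_csv(path, dtype={"analyte": str, "lot_id": str, "unit": str})
    _require_columns(df, SPEC_COLUMNS, "specs")
    return [ControlSpec(**row) for row in df[SPEC_COLUMNS].to_dict("records")]


def read_eqa(path) -> list[EQAEvent]:
    df = pd.read_csv(path, dtype={"scheme_id": str, "analyte": str, "sample_id": str})
    _require_columns(df, EQA_COLUMNS, "eqa")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    records = df[EQA_COLUMNS].to_dict("records")
    for rec in records:
        if pd.isna(rec["u_cref"]):
            rec["u_cref"] = None
    return [EQAEvent(**rec) for rec in records]


# Writers emit full float precision so that write -> read reproduces values
# exactly (and identical inputs yield identical bytes).


def write_observations(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%d %H:%M:%S")
    out[OBSERVATION_COLUMNS].to_csv(path, index=False)


def write_specs(specs: Sequence[ControlSpec], path) -> None:
    df = pd.DataFrame([s.model_dump() for s in specs], columns=SPEC_COLUMNS)
    df.to_csv(path, index=False)


def write_eqa(events: Sequence[EQAEvent], path) -> None:
    df = pd.DataFrame([e.model_dump() for e in events], columns=EQA_COLUMNS)
    df.to_csv(path, index=False)


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file is missing columns: {', '.join(missing)}")
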