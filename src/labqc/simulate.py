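"""Synthetic multi-laboratory QC data with known ground truth.

The generator emulates the data streams of a regional laboratory network:
every laboratory runs the same control materials daily, so each observation
is drawn as

    value = mu_lab + sd_lab * eps,    eps ~ N(0, 1)

with ``mu_lab = true_mean * (1 + lab_bias/100)`` (a multiplicative per-lab
bias) and ``sd_lab = (true_cv/100) * true_mean * imprecision_multiplier``.
Injections superimpose out-of-control conditions on a single lab/analyte/
level stream: a *shift* adds ``magnitude * sd`` from ``start_day`` on, a
*drift* adds ``magnitude * sd * (day - start_day)/days`` (linear ramp), and
an *imprecision* injection scales the SD by ``(1 + magnitude)``.  With
magnitude 0 every mode reproduces the uninjected stream bit for bit, since
the underlying standard-normal draws do not depend on the injection.

EQA events scatter through the simulated period; each sample is measured
once by every laboratory from its current error model.  The assigned value
is either the consensus mean/SD of the simulated participants (mirroring
peer-graded schemes) or the configured truth (for oracle tests).

Everything is driven by one mandatory seed: the same (config, seed) pair
regenerates identical CSV bytes.  The returned truth record carries every
generating parameter so recovery tests can compare estimates against it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .datamodel import (
    ControlSpec,
    EQA_COLUMNS,
    MUInput,
    MULevelInput,
    OBSERVATION_COLUMNS,
)

__all__ = [
    "AnalyteSim",
    "Injection",
    "EQASimConfig",
    "SimConfig",
    "SimResult",
    "simulate_network",
    "RBPExample",
    "rbp_example",
]

_START = pd.Timestamp("2024-01-01")


class AnalyteSim(BaseModel):
    """True concentration model for one analyte's control material."""

    model_config = ConfigDict(frozen=True)

    name: str
    true_means: tuple[float, ...] = Field(min_length=1)  # one per control level
    true_cv: float = Field(gt=0)  # percent
    cv_requirement: float = Field(default=5.0, gt=0)
    tea: float = Field(default=10.0, gt=0)
    unit: str = "mmol/L"


class Injection(BaseModel):
    """An out-of-control condition applied to one lab/analyte/level stream."""

    model_config = ConfigDict(frozen=True)

    lab: int = Field(ge=0)  # lab index
    analyte: str
    level: int = Field(ge=1)
    mode: Literal["shift", "drift", "imprecision"]
    magnitude: float
    start_day: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _finite(self) -> "Injection":
        if not np.isfinite(self.magnitude):
            raise ValueError("injection magnitude must be finite")
        return self


class EQASimConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_events: int = Field(default=6, ge=1)
    samples_per_event: int = Field(default=5, ge=1)
    assigned_from: Literal["consensus", "truth"] = "consensus"
    imprecision_scale: float = Field(default=1.0, ge=0)


class SimConfig(BaseModel):
    """Full description of a simulated laboratory network.

    Defaults model a small district network: 5 laboratories reporting two
    control levels twice a day for 90 days, with 2 % analytical CV and a
    10 % allowable total error — typical clinical-chemistry conditions.
    """

    model_config = ConfigDict(frozen=True)

    n_labs: int = Field(default=5, ge=1)
    analytes: tuple[AnalyteSim, ...] = (
        AnalyteSim(name="potassium", true_means=(4.0, 6.5), true_cv=2.0,
                   cv_requirement=3.0, tea=10.0, unit="mmol/L"),
    )
    lab_biases: Optional[tuple[float, ...]] = None  # percent, default zeros
    lab_imprecision: Optional[tuple[float, ...]] = None  # multipliers, default ones
    injections: tuple[Injection, ...] = ()
    days: int = Field(default=90, ge=1)
    points_per_day: int = Field(default=2, ge=1)
    n_peer_groups: int = Field(default=1, ge=1)
    n_method_groups: int = Field(default=1, ge=1)
    eqa: EQASimConfig = EQASimConfig()
    seed: int  # mandatory: no silent nondeterminism

    @model_validator(mode="after")
    def _check_lab_vectors(self) -> "SimConfig":
        for name in ("lab_biases", "lab_imprecision"):
            vec = getattr(self, name)
            if vec is not None and len(vec) != self.n_labs:
                raise ValueError(f"{name} must have one entry per lab")
        return self

    def biases(self) -> np.ndarray:
        return np.asarray(self.lab_biases or (0.0,) * self.n_labs, dtype=float)

    def imprecision(self) -> np.ndarray:
        return np.asarray(self.lab_imprecision or (1.0,) * self.n_labs, dtype=float)


@dataclass
class SimResult:
    """Generated network data plus the generating parameters."""

    observations: pd.DataFrame
    specs: list[ControlSpec]
    eqa: pd.DataFrame  # EQA_COLUMNS plus a lab_id column
    truth: dict


def simulate_network(config: SimConfig) -> SimResult:
    """Generate observations, control specs and EQA events for a network."""
    rng = np.random.default_rng(config.seed)
    biases = config.biases()
    imprec = config.imprecision()
    lab_ids = [f"LAB{i + 1:02d}" for i in range(config.n_labs)]

    specs = [
        ControlSpec(
            analyte=a.name,
            level=lvl + 1,
            lot_id=f"LOT-{a.name}",
            target_mean=mean,
            target_sd=a.true_cv / 100.0 * mean,
            cv_requirement=a.cv_requirement,
            tea=a.tea,
            unit=a.unit,
        )
        for a in config.analytes
        for lvl, mean in enumerate(a.true_means)
    ]

    injections = {
        (inj.lab, inj.analyte, inj.level): inj for inj in config.injections
    }

    rows: list[tuple] = []
    hours = np.linspace(8, 20, config.points_per_day, endpoint=False)
    for li, lab in enumerate(lab_ids):
        for a in config.analytes:
            for lvl, true_mean in enumerate(a.true_means, start=1):
                mu0 = true_mean * (1.0 + biases[li] / 100.0)
                sd0 = a.true_cv / 100.0 * true_mean * imprec[li]
                inj = injections.get((li, a.name, lvl))
                eps = rng.standard_normal(config.days * config.points_per_day)
                k = 0
                for day in range(config.days):
                    mu, sd = mu0, sd0
                    if inj is not None and day >= inj.start_day:
                        if inj.mode == "shift":
                            mu = mu0 + inj.magnitude * sd0
                        elif inj.mode == "drift":
                            frac = (day - inj.start_day) / config.days
                            mu = mu0 + inj.magnitude * sd0 * frac
                        else:  # imprecision
                            sd = sd0 * (1.0 + inj.magnitude)
                    for h in hours:
                        ts = _START + pd.Timedelta(days=day, hours=float(h))
                        rows.append(
                            (
                                lab,
                                f"INS{li + 1:02d}",
                                a.name,
                                lvl,
                                f"LOT-{a.name}",
                                ts,
                                mu + sd * eps[k],
                                f"M{li % config.n_method_groups + 1}",
                                f"PK{li % config.n_peer_groups + 1}",
                            )
                        )
                        k += 1
    observations = pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)

    eqa_rows: list[tuple] = []
    ecfg = config.eqa
    event_days = [
        (e + 1) * config.days // (ecfg.n_events + 1) for e in range(ecfg.n_events)
    ]
    for a in config.analytes:
        for e, day in enumerate(event_days):
            date = (_START + pd.Timedelta(days=day)).date()
            for s in range(ecfg.samples_per_event):
                lvl = s % len(a.true_means)
                true_val = a.true_means[lvl]
                sd_nominal = a.true_cv / 100.0 * true_val
                measured = true_val * (1.0 + biases / 100.0) + (
                    sd_nominal * imprec * ecfg.imprecision_scale
                ) * rng.standard_normal(config.n_labs)
                if ecfg.assigned_from == "consensus" and config.n_labs >= 2:
                    g_mean = float(np.mean(measured))
                    g_sd = float(np.std(measured, ddof=1))
                    if g_sd <= 0:
                        g_sd = sd_nominal
                else:
                    g_mean, g_sd = true_val, sd_nominal
                sample_id = f"E{e + 1}S{s + 1}"
                for li, lab in enumerate(lab_ids):
                    eqa_rows.append(
                        (
                            f"SCH-{a.name}",
                            a.name,
                            sample_id,
                            date,
                            float(measured[li]),
                            g_mean,
                            g_sd,
                            a.tea,
                            None,
                            lab,
                        )
                    )
    eqa = pd.DataFrame(eqa_rows, columns=EQA_COLUMNS + ["lab_id"])

    truth = {
        "seed": config.seed,
        "lab_ids": lab_ids,
        "lab_biases_pct": biases.tolist(),
        "lab_imprecision": imprec.tolist(),
        "analytes": {
            a.name: {
                "true_means": list(a.true_means),
                "true_cv_pct": a.true_cv,
                "tea_pct": a.tea,
            }
            for a in config.analytes
        },
        "injections": [inj.model_dump() for inj in config.injections],
    }
    return SimResult(observations=observations, specs=specs, eqa=eqa, truth=truth)


@dataclass(frozen=True)
class RBPExample:
    """Worked retinol-binding-protein example with published summary values.

    The level means (25 and 46 mg/L), the level-1 relative expanded
    uncertainty (15.18 %), the level-2 relative combined uncertainty
    (4.44 %), the patient results (28, then the serial pair 71 and 68 mg/L)
    and the reference range (25-70 mg/L) are published summary quantities.
    The per-component breakdown in ``mu_input`` (IQC CVs and the EQA bias
    history) is a synthetic reconstruction: the underlying raw data are not
    public, so components were chosen to be exactly consistent with the
    published combined values under k = 2.
    """

    mu_input: MUInput
    u_expanded_level1: float  # percent, published
    u_c_level2: float  # percent, published
    result_near_limit: float  # mg/L
    serial_results: tuple[float, float]  # mg/L, chronological
    reference_range: tuple[float, float]  # mg/L


def rbp_example() -> RBPExample:
    """Retinol-binding-protein fixture for the uncertainty workflow."""
    u_c1 = 15.18 / 2.0  # k = 2
    u_c2 = 4.44
    rms_bias = 3.0  # synthetic reconstruction, RMS of the 6 EQA deviations
    cv1 = float(np.sqrt(u_c1**2 - rms_bias**2))
    cv2 = float(np.sqrt(u_c2**2 - rms_bias**2))
    mu_input = MUInput(
        analyte="RBP",
        levels=(
            MULevelInput(level=1, iqc_mean=25.0, iqc_cv=cv1, n_iqc=180,
                         period="2023-01-01/2023-07-01"),
            MULevelInput(level=2, iqc_mean=46.0, iqc_cv=cv2, n_iqc=180,
                         period="2023-01-01/2023-07-01"),
        ),
        eqa_biases=(3.0, -3.0, 3.0, -3.0, 3.0, -3.0),
        u_cref=0.0,
        k=2.0,
        quality_goal=16.0,
        unit="mg/L",
    )
    return RBPExample(
        mu_input=mu_input,
        u_expanded_level1=15.18,
        u_c_level2=4.44,
        result_near_limit=28.0,
        serial_results=(71.0, 68.0),
        reference_range=(25.0, 70.0),
    )
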