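from datetime import date

import pytest
from hypothesis import HealthCheck, settings

from labqc import ControlSpec, EQAEvent

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def potassium_spec() -> ControlSpec:
    return ControlSpec(
        analyte="potassium",
        level=1,
        lot_id="LOT-1",
        target_mean=5.0,
        target_sd=0.1,
        cv_requirement=3.0,
        tea=10.0,
        unit="mmol/L",
    )


def make_eqa_series(pds, tea=8.0, group_mean=5.0, group_sd=0.1, analyte="urea"):
    """Build a date-ordered EQA series with the given percent deviations."""
    events = []
    for i, pd_val in enumerate(pds):
        events.append(
            EQAEvent(
                scheme_id="SCH-1",
                analyte=analyte,
                sample_id=f"S{i + 1}",
                date=date(2024, 1 + i % 12, 1 + i // 12),
                measured=group_mean * (1 + pd_val / 100.0),
                group_mean=group_mean,
                group_sd=group_sd,
                tea=tea,
            )
        )
    return events


@pytest.fixture
def eqa_series_builder():
    return make_eqa_series
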