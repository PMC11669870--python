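import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from inhalerhr.store import (
    HEART_RATE,
    STEPS,
    CohortBundle,
    EventLog,
    MedStatusTimeline,
    MinuteSeries,
    PatientData,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def make_patient(
    patient_id="p1",
    start="2016-01-01",
    n_days=5,
    hr_fn=lambda abs_minute, minute_of_day: 70.0,
    worn=None,
    steps=None,
    events=(),
    laba=None,
):
    """Build a small deterministic patient from closed-form ingredients.

    ``hr_fn(abs_minute, minute_of_day)`` gives the heart rate; ``worn`` is an
    optional boolean mask over absolute minutes; ``steps`` an optional array;
    ``events`` a list of (abs_minute, inhaler_type).
    """
    start = pd.Timestamp(start)
    n_min = n_days * 1440
    abs_min = np.arange(n_min)
    mod = abs_min % 1440
    hr = np.array([hr_fn(a, m) for a, m in zip(abs_min, mod)], dtype=float)
    mask = np.ones(n_min, dtype=bool) if worn is None else np.asarray(worn, bool)
    idx = start + pd.to_timedelta(abs_min[mask], unit="m")
    hr_series = MinuteSeries(patient_id, HEART_RATE, pd.Series(hr[mask], index=idx))
    step_vals = np.zeros(n_min) if steps is None else np.asarray(steps, float)
    steps_series = MinuteSeries(
        patient_id, STEPS, pd.Series(step_vals[mask], index=idx)
    )
    ev = pd.DataFrame(
        [
            {"timestamp": start + pd.Timedelta(minutes=int(a)), "inhaler_type": t}
            for a, t in events
        ],
        columns=["timestamp", "inhaler_type"],
    )
    if laba is None:
        iv = pd.DataFrame(
            {
                "start_date": [start],
                "end_date": [start + pd.Timedelta(days=n_days - 1)],
                "laba": [False],
            }
        )
    else:
        iv = pd.DataFrame(laba)
    return PatientData(
        patient_id,
        hr_series,
        steps_series,
        EventLog(patient_id, ev),
        MedStatusTimeline(patient_id, iv),
    )


def make_bundle(*patients) -> CohortBundle:
    b = CohortBundle()
    for p in patients:
        b.patients[p.patient_id] = p
    return b


@pytest.fixture
def constant_patient():
    return make_patient(n_days=7)


@pytest.fixture
def tiny_bundle():
    """Two-patient bundle with distinct constant heart rates."""
    p1 = make_patient("p1", hr_fn=lambda a, m: 60.0)
    p2 = make_patient(
        "p2",
        hr_fn=lambda a, m: 70.0,
        laba=[
            {
                "start_date": pd.Timestamp("2016-01-01"),
                "end_date": pd.Timestamp("2016-01-05"),
                "laba": True,
            }
        ],
    )
    return make_bundle(p1, p2)
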