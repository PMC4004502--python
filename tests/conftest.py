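import datetime as dt

import numpy as np
import pytest

from qicompare.indicator_engine import load_definitions
from qicompare.records import DataItemValue, PatientRecord, Status, present

OP = dt.date(2011, 6, 15)


def make_record(pid="p1", source="registry", gender="female", op=OP, **overrides):
    """A fully-present, indicator-2-eligible patient; overrides replace items.

    Pass ``item=value`` for a present value, ``item=DataItemValue(...)`` for
    an explicit status, or ``item=None`` for absent.
    """
    items = {
        "operation_date": op,
        "year_of_birth": 1950,
        "procedure": {"colectomy"},
        "operation_urgency": "elective",
        "diagnosis": {"location": "colon", "primary": True, "date": op - dt.timedelta(days=30)},
        "ct_stage": "T2",
        "pn_stage": "N0",
        "pm_stage": "M0",
        "examined_lymph_nodes": 12,
        "circumferential_margin_mm": 5.0,
        "colonoscopy": {"performed": True, "complete": True, "date": op - dt.timedelta(days=40)},
        "chemotherapy": {"received": False},
        "meeting_date": op - dt.timedelta(days=7),
        "radiotherapy_start_date": op - dt.timedelta(days=35),
    }
    items.update(overrides)
    wrapped = {}
    for name, value in items.items():
        if isinstance(value, DataItemValue):
            wrapped[name] = value
        elif value is None:
            wrapped[name] = DataItemValue()
        else:
            wrapped[name] = present(value)
    return PatientRecord(patient_id=pid, source=source, gender=gender, items=wrapped)


@pytest.fixture(scope="session")
def indicator_set():
    return load_definitions()


def random_record(rng: np.random.Generator, pid: str, source: str = "registry",
                  p_present: float = 0.75) -> PatientRecord:
    """A record with randomised values and statuses for oracle comparisons."""
    op = dt.date(2011, 1, 1) + dt.timedelta(days=int(rng.integers(0, 365)))
    values = {
        "operation_date": op,
        "year_of_birth": 1920 + int(rng.integers(0, 80)),
        "procedure": set(
            rng.choice(["colectomy", "rectum_resection", "appendectomy"],
                       size=int(rng.integers(1, 3)), replace=False)
        ),
        "operation_urgency": str(rng.choice(["elective", "urgent", "acute"])),
        "diagnosis": {
            "location": str(rng.choice(["colon", "rectum", "rectosigmoid"])),
            "primary": bool(rng.integers(0, 2)),
            "date": op + dt.timedelta(days=int(rng.integers(-60, 20))),
        },
        "ct_stage": str(rng.choice(["T1", "T2", "T3", "T4"])),
        "pn_stage": str(rng.choice(["N0", "N1", "N2"])),
        "pm_stage": str(rng.choice(["M0", "M1"])),
        "examined_lymph_nodes": int(rng.integers(0, 25)),
        "circumferential_margin_mm": float(rng.integers(0, 80)) / 10.0,
        "colonoscopy": {
            "performed": bool(rng.integers(0, 2)),
            "complete": bool(rng.integers(0, 2)),
            "date": op + dt.timedelta(days=int(rng.integers(-60, 10))),
        },
        "chemotherapy": {"received": bool(rng.integers(0, 2))},
        "meeting_date": op + dt.timedelta(days=int(rng.integers(-30, 30))),
        "radiotherapy_start_date": op + dt.timedelta(days=int(rng.integers(-60, 30))),
    }
    items = {}
    for name, value in values.items():
        u = rng.random()
        if u < p_present:
            items[name] = present(value)
        elif u < p_present + 0.15:
            items[name] = DataItemValue()
        elif u < p_present + 0.20:
            items[name] = DataItemValue(status=Status.UNKNOWN)
        else:
            items[name] = DataItemValue(status=Status.UNSTRUCTURED)
    for flag in ("recurrent_carcinoma", "tem_resection",
                 "colonoscopic_resection", "previous_radiotherapy"):
        if rng.random() < 0.15:
            items[flag] = present(bool(rng.integers(0, 2)))
    gender = str(rng.choice(["male", "female"]))
    return PatientRecord(patient_id=pid, source=source, gender=gender, items=items)


def random_dataset(rng, n, source="registry", with_anchor=True):
    """Random records plus one fully-present anchor so every item is available."""
    data = [random_record(rng, f"{source[0]}{i:03d}", source) for i in range(n)]
    if with_anchor:
        data.append(make_record(pid=f"{source[0]}anchor", source=source))
    return data
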