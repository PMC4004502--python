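"""Item-specific effect-inconsistent value replacement.

Correctness is defined by effect on the indicators, so an injected error
must flip the value across whatever boundary the indicator definitions
read: a date moves to the other side of the operation date, a count crosses
the 10-node threshold, a margin crosses 1 mm, a procedure swaps resection
class, and so on.
"""

from __future__ import annotations

import datetime as dt
from typing import Any

import numpy as np


def corrupt_value(item: str, value: Any, operation_date: dt.date, rng: np.random.Generator) -> Any:
    """Return an effect-inconsistent replacement for ``value``."""
    if item in ("meeting_date", "radiotherapy_start_date"):
        offset = int(rng.integers(1, 30))
        if value < operation_date:
            return operation_date + dt.timedelta(days=offset)
        return operation_date - dt.timedelta(days=offset)
    if item == "operation_date":
        return value + dt.timedelta(days=int(rng.integers(1, 15)))
    if item == "year_of_birth":
        return value + (1 if rng.random() < 0.5 else -1)
    if item == "procedure":
        swapped = set(value)
        if "colectomy" in swapped:
            swapped.discard("colectomy")
            swapped.add("rectum_resection")
        else:
            swapped.discard("rectum_resection")
            swapped.add("colectomy")
        return swapped
    if item == "operation_urgency":
        return "acute" if value == "elective" else "elective"
    if item == "diagnosis":
        flipped = dict(value)
        flipped["location"] = "rectum" if value.get("location") != "rectum" else "colon"
        return flipped
    if item == "ct_stage":
        return "T1" if value in ("T3", "T4") else "T3"
    if item == "pn_stage":
        return "N1" if value == "N0" else "N0"
    if item == "pm_stage":
        return "M1" if value == "M0" else "M0"
    if item == "examined_lymph_nodes":
        return int(rng.integers(0, 10)) if value >= 10 else int(rng.integers(10, 25))
    if item == "circumferential_margin_mm":
        return float(rng.integers(2, 10)) if value <= 1 else float(rng.integers(0, 2)) / 2.0
    if item == "colonoscopy":
        flipped = dict(value)
        flipped["complete"] = not value.get("complete")
        flipped["performed"] = True
        return flipped
    if item == "chemotherapy":
        return {"received": not value.get("received")}
    raise ValueError(f"no corruption rule for item {item!r}")
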