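"""Patient-level record model.

A :class:`PatientRecord` is one patient as seen by one source (registry or
EMR).  Every clinical data item is wrapped in a :class:`DataItemValue` that
carries an explicit presence status, so that "not recorded", "recorded as
unknown" and "only available as free text" are distinguishable from a real
value.  Downstream evaluation never encounters a silently missing key.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Mapping

from .errors import DefinitionError


class Status(str, Enum):
    """Presence status of a data item in a given source."""

    PRESENT = "present"
    ABSENT = "absent"
    UNKNOWN = "unknown"          # explicitly recorded as 'unknown'
    UNSTRUCTURED = "unstructured"  # exists only as free text


#: The fourteen data items needed to evaluate the full indicator set.
ITEM_NAMES: tuple[str, ...] = (
    "operation_date",
    "year_of_birth",
    "procedure",
    "operation_urgency",
    "diagnosis",
    "ct_stage",
    "pn_stage",
    "pm_stage",
    "examined_lymph_nodes",
    "circumferential_margin_mm",
    "colonoscopy",
    "chemotherapy",
    "meeting_date",
    "radiotherapy_start_date",
)

#: Optional boolean flags backing exclusion criteria that have no structured
#: representation in either source; they default to status=absent.
OPTIONAL_FLAG_ITEMS: tuple[str, ...] = (
    "recurrent_carcinoma",
    "tem_resection",
    "colonoscopic_resection",
    "previous_radiotherapy",
)

ALL_ITEM_NAMES: tuple[str, ...] = ITEM_NAMES + OPTIONAL_FLAG_ITEMS

#: Sub-fields of compound items (used by I/O flattening and field access).
COMPOUND_FIELDS: dict[str, tuple[str, ...]] = {
    "diagnosis": ("location", "primary", "date"),
    "colonoscopy": ("performed", "complete", "date"),
    "chemotherapy": ("received",),
}

LOCATION_CLASSES = ("colon", "rectosigmoid", "rectum")
CT_VALUES = ("T1", "T2", "T3", "T4")
PN_VALUES = ("N0", "N1", "N2")
PM_VALUES = ("M0", "M1")


@dataclass(frozen=True)
class DataItemValue:
    """A value together with its presence status.

    Invariant: ``status == PRESENT`` iff ``value`` is non-empty; any
    non-present status carries an empty value.
    """

    value: Any = None
    status: Status = Status.ABSENT

    def __post_init__(self) -> None:
        if self.status is Status.PRESENT and self.value is None:
            raise ValueError("status=present requires a non-empty value")
        if self.status is not Status.PRESENT and self.value is not None:
            raise ValueError(f"status={self.status.value} requires an empty value")

    @property
    def present(self) -> bool:
        return self.status is Status.PRESENT


def present(value: Any) -> DataItemValue:
    return DataItemValue(value=value, status=Status.PRESENT)


def absent() -> DataItemValue:
    return DataItemValue()


def unknown() -> DataItemValue:
    return DataItemValue(status=Status.UNKNOWN)


def unstructured() -> DataItemValue:
    return DataItemValue(status=Status.UNSTRUCTURED)


@dataclass
class PatientRecord:
    """One patient in one source.

    ``items`` always carries every core item name (missing entries are filled
    with status=absent on construction); optional exclusion-flag items are
    filled with status=absent as well.
    """

    patient_id: str
    source: str  # "registry" | "emr"
    gender: str = "absent"  # "male" | "female" | "absent"
    items: dict[str, DataItemValue] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.source not in ("registry", "emr"):
            raise ValueError(f"unknown source {self.source!r}")
        for name in ALL_ITEM_NAMES:
            self.items.setdefault(name, absent())
        unknown_keys = set(self.items) - set(ALL_ITEM_NAMES)
        if unknown_keys:
            raise DefinitionError(f"unknown item names: {sorted(unknown_keys)}")
        self._validate_values()

    def _validate_values(self) -> None:
        for name, div in self.items.items():
            if not div.present:
                continue
            v = div.value
            if name in ("operation_date", "meeting_date", "radiotherapy_start_date"):
                if not isinstance(v, dt.date):
                    raise ValueError(f"{name} must be a date, got {type(v).__name__}")
            elif name == "year_of_birth":
                if not isinstance(v, int) or not (1850 <= v <= 2100):
                    raise ValueError(f"year_of_birth out of range: {v!r}")
            elif name == "examined_lymph_nodes":
                if not isinstance(v, int) or v < 0:
                    raise ValueError(f"examined_lymph_nodes must be a count: {v!r}")
            elif name == "circumferential_margin_mm":
                if not isinstance(v, (int, float)) or v < 0:
                    raise ValueError(f"circumferential_margin_mm must be >= 0: {v!r}")
            elif name == "procedure":
                if not isinstance(v, (set, frozenset)):
                    raise ValueError("procedure must be a set of codes")
            elif name in COMPOUND_FIELDS:
                if not isinstance(v, Mapping):
                    raise ValueError(f"{name} must be a mapping")

    # -- convenience accessors -------------------------------------------------

    @property
    def year_of_birth(self) -> int | None:
        div = self.items["year_of_birth"]
        return div.value if div.present else None

    @property
    def operation_date(self) -> dt.date | None:
        div = self.items["operation_date"]
        return div.value if div.present else None

    def get(self, item: str, fld: str | None = None) -> tuple[Any, Status]:
        """Resolve ``item`` (optionally a compound sub-field).

        Returns ``(value, status)``; a present compound whose sub-field is
        empty resolves to ``(None, ABSENT)``.
        """
        if item not in self.items:
            raise DefinitionError(f"unknown item {item!r}")
        div = self.items[item]
        if fld is None:
            return div.value, div.status
        if item not in COMPOUND_FIELDS or fld not in COMPOUND_FIELDS[item]:
            raise DefinitionError(f"item {item!r} has no field {fld!r}")
        if not div.present:
            return None, div.status
        sub = div.value.get(fld)
        if sub is None:
            return None, Status.ABSENT
        return sub, Status.PRESENT
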