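"""Paired registry/EMR cohort generation with controlled quality defects.

The EMR is treated as the source system: every true patient yields an EMR
record, and a registry record with probability ``registry_coverage``.  All
degradation (missingness, explicit 'unknown', free-text-only items,
effect-inconsistent replacements, extraction anomalies) is applied on top of
a shared ground truth that the returned :class:`TruthLedger` preserves.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ..errors import ConfigurationError
from ..indicator_engine import IndicatorSet, load_definitions, select_patients
from ..records import (
    ITEM_NAMES,
    DataItemValue,
    PatientRecord,
    Status,
    present,
    unknown,
    unstructured,
)
from .config import GeneratorConfig
from .corruption import corrupt_value

_EMR8_URGENCY = {
    # registry category -> pool of raw source-system categories
    "elective": ("elective", "planned", "scheduled"),
    "urgent": ("urgent", "semi_urgent", "transfer"),
    "acute": ("acute", "emergency"),
}


@dataclass
class TruthLedger:
    """Ground truth behind a generated cohort.

    ``true_items`` holds the pre-degradation value of every item (``None``
    when the event truly did not happen); ``memberships`` holds, per truth
    patient, the indicator elements it truly belongs to; ``identity`` maps
    the truth id to the per-source record ids (registry id is ``None`` for
    patients never abstracted).
    """

    true_items: dict[str, dict[str, Any]] = field(default_factory=dict)
    gender: dict[str, str] = field(default_factory=dict)
    memberships: dict[str, dict[str, bool]] = field(default_factory=dict)
    identity: dict[str, tuple[str | None, str]] = field(default_factory=dict)

    @property
    def registry_to_emr(self) -> dict[str, str]:
        return {r: e for r, e in self.identity.values() if r is not None}


def _sample_truth(i: int, config: GeneratorConfig, rng: np.random.Generator) -> tuple[str, dict]:
    """Draw one patient's true clinical values from simple distributions."""
    year = config.reporting_year
    gender = "male" if rng.random() < 0.5 else "female"
    yob = 1925 + int(rng.integers(0, 70))
    op_date = dt.date(year, 1, 1) + dt.timedelta(days=int(rng.integers(0, 365)))
    location = ["colon", "rectum", "rectosigmoid"][
        int(rng.choice(3, p=[0.6, 0.3, 0.1]))
    ]
    diag_date = op_date - dt.timedelta(days=int(rng.integers(7, 120)))
    procedure = {"rectum_resection"} if location == "rectum" else {"colectomy"}
    if rng.random() < 0.15:
        procedure.add("appendectomy")
    urgency = "elective" if rng.random() < 0.85 else "acute"
    ct = ["T1", "T2", "T3", "T4"][int(rng.choice(4, p=[0.1, 0.2, 0.4, 0.3]))]
    pn = ["N0", "N1", "N2"][int(rng.choice(3, p=[0.5, 0.3, 0.2]))]
    pm = "M0" if rng.random() < 0.85 else "M1"
    nodes = int(rng.poisson(12.0))
    crm = round(float(rng.gamma(2.0, 2.0)), 1)
    scope_performed = rng.random() < 0.95
    scope_complete = scope_performed and rng.random() < 0.85
    scope_date = diag_date - dt.timedelta(days=int(rng.integers(0, 5)))
    stage_iii = pn in ("N1", "N2") and pm == "M0"
    chemo = rng.random() < (0.55 if stage_iii else 0.15)
    meeting_before = rng.random() < 0.9
    meeting_offset = int(rng.integers(1, 28))
    meeting = (
        op_date - dt.timedelta(days=meeting_offset)
        if meeting_before
        else op_date + dt.timedelta(days=meeting_offset)
    )
    gets_radiotherapy = location == "rectum" and ct in ("T3", "T4") and rng.random() < 0.8
    radio = op_date - dt.timedelta(days=int(rng.integers(28, 60))) if gets_radiotherapy else None

    items: dict[str, Any] = {
        "operation_date": op_date,
        "year_of_birth": yob,
        "procedure": procedure,
        "operation_urgency": urgency,
        "diagnosis": {"location": location, "primary": True, "date": diag_date},
        "ct_stage": ct,
        "pn_stage": pn,
        "pm_stage": pm,
        "examined_lymph_nodes": nodes,
        "circumferential_margin_mm": crm,
        "colonoscopy": {
            "performed": scope_performed,
            "complete": scope_complete,
            "date": scope_date if scope_performed else None,
        },
        "chemotherapy": {"received": chemo},
        "meeting_date": meeting,
        "radiotherapy_start_date": radio,
    }
    return gender, items


def _degrade_record(
    pid: str,
    source: str,
    gender: str,
    true_items: dict[str, Any],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> PatientRecord:
    items: dict[str, DataItemValue] = {}
    for name in ITEM_NAMES:
        true_value = true_items[name]
        if source == "emr" and name in config.unstructured_items:
            items[name] = unstructured()
            continue
        if true_value is None:  # event never happened; nothing to record
            items[name] = DataItemValue()
            continue
        rates = config.per_item_completeness.get(name)
        p_complete = getattr(rates, source) if rates is not None else 1.0
        if rng.random() >= p_complete:
            items[name] = unknown() if rng.random() < config.unknown_fraction else DataItemValue()
            continue
        error_rates = config.per_item_error if source == "emr" else config.registry_item_error
        value = true_value
        if rng.random() < error_rates.get(name, 0.0):
            value = corrupt_value(name, value, true_items["operation_date"], rng)
        items[name] = present(_copy(value))
    record = PatientRecord(patient_id=pid, source=source, gender=gender, items=items)
    return record


def _copy(value: Any) -> Any:
    if isinstance(value, dict):
        return dict(value)
    if isinstance(value, set):
        return set(value)
    return value


def _apply_anomalies(
    record: PatientRecord, config: GeneratorConfig, rng: np.random.Generator
) -> None:
    """Inject EMR extraction anomalies in place (EMR records only)."""
    noise = config.emr_extract_noise
    diag = record.items["diagnosis"]
    op = record.operation_date
    if rng.random() < noise.missing_diagnosis:
        record.items["diagnosis"] = DataItemValue()
    elif diag.present and op is not None and rng.random() < noise.diagnosis_after_operation:
        shifted = dict(diag.value)
        shifted["date"] = op + dt.timedelta(days=int(rng.integers(1, 45)))
        record.items["diagnosis"] = present(shifted)
    elif diag.present and rng.random() < noise.imprecise_code:
        blurred = dict(diag.value)
        blurred["location"] = "unspecified"
        blurred["primary"] = None
        record.items["diagnosis"] = present(blurred)
    proc = record.items["procedure"]
    if proc.present and op is not None and rng.random() < noise.wrong_procedure_class:
        record.items["procedure"] = present(
            corrupt_value("procedure", proc.value, op, rng)
        )


def _emr8_urgency(record: PatientRecord, rng: np.random.Generator) -> None:
    div = record.items["operation_urgency"]
    if div.present and div.value in _EMR8_URGENCY:
        pool = _EMR8_URGENCY[div.value]
        record.items["operation_urgency"] = present(pool[int(rng.integers(0, len(pool)))])


def _truth_record(pid: str, gender: str, true_items: dict[str, Any]) -> PatientRecord:
    items = {
        name: present(_copy(v)) if v is not None else DataItemValue()
        for name, v in true_items.items()
    }
    return PatientRecord(patient_id=pid, source="registry", gender=gender, items=items)


def true_memberships(
    ledger: TruthLedger, indicator_set: IndicatorSet | None = None
) -> dict[str, dict[str, bool]]:
    """Indicator-element membership of each truth patient, by re-evaluation."""
    if indicator_set is None:
        indicator_set = load_definitions()
    pristine = [
        _truth_record(pid, ledger.gender[pid], items)
        for pid, items in ledger.true_items.items()
    ]
    memberships: dict[str, dict[str, bool]] = {pid: {} for pid in ledger.true_items}
    for definition in indicator_set:
        for element in ("numerator", "denominator"):
            if element == "numerator" and not definition.has_numerator:
                continue
            selected = select_patients(pristine, definition, element)
            key = f"{definition.id}.{element}"
            for pid in memberships:
                memberships[pid][key] = pid in selected
    return memberships


def generate_paired_cohort(
    config: GeneratorConfig,
) -> tuple[list[PatientRecord], list[PatientRecord], TruthLedger]:
    """Generate the registry dataset, the EMR dataset and the truth ledger."""
    if config.n_patients < 1:
        raise ConfigurationError("n_patients must be at least 1")
    rng = np.random.default_rng(config.seed)
    registry: list[PatientRecord] = []
    emr: list[PatientRecord] = []
    ledger = TruthLedger()
    for i in range(config.n_patients):
        pid = f"p{i:05d}"
        gender, true_items = _sample_truth(i, config, rng)
        ledger.true_items[pid] = true_items
        ledger.gender[pid] = gender

        emr_id = f"e{i:05d}"
        emr_record = _degrade_record(emr_id, "emr", gender, true_items, config, rng)
        _apply_anomalies(emr_record, config, rng)
        if config.emr_urgency_vocabulary == "emr8":
            _emr8_urgency(emr_record, rng)
        emr.append(emr_record)

        reg_id: str | None = None
        if rng.random() < config.registry_coverage:
            reg_id = f"r{i:05d}"
            registry.append(
                _degrade_record(reg_id, "registry", gender, true_items, config, rng)
            )
        ledger.identity[pid] = (reg_id, emr_id)
    ledger.memberships = true_memberships(ledger)
    return registry, emr, ledger
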