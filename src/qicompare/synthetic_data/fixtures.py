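"""Deterministic paired fixtures.

``build_fixture_from_crosstab`` constructs a minimal pair of datasets whose
cross-classification for a named indicator element reproduces requested
TP / reference-only / test-only / TN counts exactly, with no randomness.
``build_quality_fixture`` constructs matched pairs with prescribed per-item
presence and consistency counts for data-quality measurements.

Both exist so that published summary tables (which are counts, not patient
data) can be turned back into datasets on which the full pipeline runs.
"""

from __future__ import annotations

import datetime as dt
from typing import Any, Mapping

import numpy as np

from ..errors import DefinitionError
from ..indicator_engine import IndicatorSet, load_definitions, select_patients
from ..patient_matching import MatchResult, match_patients
from ..records import ITEM_NAMES, DataItemValue, PatientRecord, present, unstructured
from .corruption import corrupt_value


def _base_items(op: dt.date, yob: int) -> dict[str, Any]:
    return {
        "operation_date": op,
        "year_of_birth": yob,
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
        "radiotherapy_start_date": None,
    }


def _overrides(indicator_id: str, role: str, op: dt.date) -> dict[str, Any]:
    """Item overrides putting a record in a given role for an indicator.

    Roles: ``in`` (denominator member), ``num`` / ``not_num`` (denominator
    member with the numerator condition met / failed), ``out`` (outside the
    denominator).
    """
    rectal = {"diagnosis.location": "rectum", "procedure": {"rectum_resection"}}
    colonic = {"diagnosis.location": "colon", "procedure": {"colectomy"}}
    non_resection = {"procedure": {"appendectomy"}}
    table: dict[str, dict[str, dict[str, Any]]] = {
        "1": {"in": colonic, "out": non_resection},
        "2": {
            "in": colonic,
            "num": {"examined_lymph_nodes": 15},
            "not_num": {"examined_lymph_nodes": 4},
            "out": rectal,
        },
        "3": {
            "in": rectal,
            "num": {"meeting_date": op - dt.timedelta(days=7)},
            "not_num": {"meeting_date": op + dt.timedelta(days=7)},
            "out": colonic,
        },
        "4": {
            "in": dict(colonic, **{"operation_urgency": "elective"}),
            "num": {"colonoscopy": {"performed": True, "complete": True,
                                    "date": op - dt.timedelta(days=40)}},
            "not_num": {"colonoscopy": {"performed": True, "complete": False,
                                        "date": op - dt.timedelta(days=40)}},
            "out": {"operation_urgency": "acute"},
        },
        "5a": {
            "in": dict(colonic, **{"pn_stage": "N1", "pm_stage": "M0"}),
            "num": {"chemotherapy": {"received": True}},
            "not_num": {"chemotherapy": {"received": False}},
            "out": {"pn_stage": "N0"},
        },
        "5b": {
            "in": dict(colonic, **{"pn_stage": "N1", "pm_stage": "M0"}),
            "num": {"chemotherapy": {"received": True}},
            "not_num": {"chemotherapy": {"received": False}},
            "out": {"pn_stage": "N0"},
        },
        "6a": {"in": rectal, "out": colonic},
        "6b": {
            "in": rectal,
            "num": {"circumferential_margin_mm": 0.5},
            "not_num": {"circumferential_margin_mm": 5.0},
            "out": colonic,
        },
        "7": {
            "in": dict(rectal, **{"ct_stage": "T3"}),
            "num": {"radiotherapy_start_date": op - dt.timedelta(days=30)},
            "not_num": {"radiotherapy_start_date": op + dt.timedelta(days=10)},
            "out": {"ct_stage": "T1"},
        },
        "8b": {"in": colonic, "out": non_resection},
    }
    try:
        roles = table[indicator_id]
    except KeyError:
        raise DefinitionError(f"no fixture templates for indicator {indicator_id!r}") from None
    if role not in roles:
        raise DefinitionError(f"indicator {indicator_id!r} has no fixture role {role!r}")
    return roles[role]


def _make_record(
    pid: str, source: str, idx: int, indicator_id: str, roles: tuple[str, ...], year: int
) -> PatientRecord:
    yob = (1900 + idx % 30) if indicator_id == "5b" else (1940 + idx % 60)
    span = 30 if indicator_id == "5b" else 60
    op = dt.date(year, 1, 1) + dt.timedelta(days=idx // span)
    items = _base_items(op, yob)
    for role in roles:
        for key, value in _overrides(indicator_id, role, op).items():
            if "." in key:
                item, fld = key.split(".")
                items[item] = dict(items[item], **{fld: value})
            else:
                items[key] = value
    wrapped = {
        name: present(v) if v is not None else DataItemValue() for name, v in items.items()
    }
    return PatientRecord(patient_id=pid, source=source, gender="female", items=wrapped)


def build_fixture_from_crosstab(
    element_id: str,
    tp: int,
    ref_only: int,
    test_only: int,
    tn: int,
    extra_unmatched_ref: int = 0,
    extra_unmatched_test: int = 0,
    indicator_set: IndicatorSet | None = None,
    reporting_year: int = 2011,
) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Minimal paired datasets reproducing a requested cross-classification.

    For a numerator element, ``extra_unmatched_ref`` / ``extra_unmatched_test``
    add denominator members on one side whose counterpart falls outside the
    other side's denominator, which sets the two universe sizes; for a
    denominator element they add one-sided non-members.
    """
    for name, value in (("tp", tp), ("ref_only", ref_only), ("test_only", test_only),
                        ("tn", tn), ("extra_unmatched_ref", extra_unmatched_ref),
                        ("extra_unmatched_test", extra_unmatched_test)):
        if value < 0:
            raise DefinitionError(f"{name} must be non-negative, got {value}")
    if indicator_set is None:
        indicator_set = load_definitions()
    definition, element = indicator_set.element(element_id)
    if element == "numerator" and not definition.has_numerator:
        raise DefinitionError(
            f"indicator {definition.id!r} has no evaluable numerator"
        )
    iid = definition.id

    if element == "numerator":
        role_plan = [
            (tp, ("in", "num"), ("in", "num")),
            (ref_only, ("in", "num"), ("out",)),
            (test_only, ("out",), ("in", "num")),
            (tn, ("in", "not_num"), ("in", "not_num")),
            (extra_unmatched_ref, ("in", "not_num"), ("out",)),
            (extra_unmatched_test, ("out",), ("in", "not_num")),
        ]
    else:
        role_plan = [
            (tp, ("in",), ("in",)),
            (ref_only, ("in",), ("out",)),
            (test_only, ("out",), ("in",)),
            (tn, ("out",), ("out",)),
            (extra_unmatched_ref, ("out",), None),
            (extra_unmatched_test, None, ("out",)),
        ]

    registry: list[PatientRecord] = []
    emr: list[PatientRecord] = []
    idx = 0
    for count, reg_roles, emr_roles in role_plan:
        for _ in range(count):
            if reg_roles is not None:
                registry.append(
                    _make_record(f"r{idx:04d}", "registry", idx, iid, reg_roles, reporting_year)
                )
            if emr_roles is not None:
                emr.append(
                    _make_record(f"e{idx:04d}", "emr", idx, iid, emr_roles, reporting_year)
                )
            idx += 1
    return registry, emr


def evaluate_fixture(
    element_id: str,
    registry: list[PatientRecord],
    emr: list[PatientRecord],
    indicator_set: IndicatorSet | None = None,
):
    """Run the full path on a fixture: match, select, cross-classify.

    Returns ``(crosstab, matches)``.  The universe of a numerator element is
    the source's denominator selection; of a denominator element, the whole
    dataset.
    """
    from ..concordance_stats import cross_classify  # local import to avoid cycle

    if indicator_set is None:
        indicator_set = load_definitions()
    definition, element = indicator_set.element(element_id)
    matches = match_patients(registry, emr)
    ref_sel = select_patients(registry, definition, element)
    test_sel = select_patients(emr, definition, element)
    if element == "numerator":
        ref_uni = select_patients(registry, definition, "denominator")
        test_uni = select_patients(emr, definition, "denominator")
    else:
        ref_uni = frozenset(r.patient_id for r in registry)
        test_uni = frozenset(e.patient_id for e in emr)
    crosstab = cross_classify(ref_sel, test_sel, ref_uni, test_uni, matches, element_id)
    return crosstab, matches


def build_quality_fixture(
    n: int,
    presence: Mapping[str, Mapping[str, Any]],
    reporting_year: int = 2011,
) -> tuple[list[PatientRecord], list[PatientRecord], list[tuple[PatientRecord, PatientRecord]]]:
    """``n`` matched pairs with prescribed per-item presence/consistency counts.

    ``presence`` maps an item name to either ``{"emr": "unstructured", ...}``
    or counts ``registry_present`` (default ``n``), ``emr_present`` (default
    ``n``), ``evaluable`` (pairs with the item present on both sides; default
    ``min`` of the two) and ``consistent`` (default all evaluable pairs).
    Registry presence occupies patients ``0..a-1``; EMR presence is placed so
    the both-present overlap is exactly ``evaluable``.
    """
    registry: list[PatientRecord] = []
    emr: list[PatientRecord] = []
    rng = np.random.default_rng(0)  # only feeds value corruption; layout is fixed

    plans = {}
    for item, spec in presence.items():
        if item not in ITEM_NAMES:
            raise DefinitionError(f"unknown data item {item!r}")
        if spec.get("emr") == "unstructured":
            a = int(spec.get("registry_present", n))
            plans[item] = {"a": a, "unstructured": True}
            continue
        a = int(spec.get("registry_present", n))
        b = int(spec.get("emr_present", n))
        e = int(spec.get("evaluable", min(a, b)))
        c = int(spec.get("consistent", e))
        if not (0 <= c <= e <= min(a, b) and a <= n and b <= n and a - e + b <= n):
            raise DefinitionError(f"infeasible presence plan for {item!r}: {spec}")
        plans[item] = {"a": a, "b": b, "e": e, "c": c, "unstructured": False}

    for idx in range(n):
        base = _make_record(f"r{idx:04d}", "registry", idx, "1", ("in",), reporting_year)
        reg_items = dict(base.items)
        emr_items = dict(base.items)
        # radiotherapy is absent in the generic base; give it a value so that
        # presence plans for it are expressible
        op = base.operation_date
        reg_items["radiotherapy_start_date"] = present(op - dt.timedelta(days=30))
        emr_items["radiotherapy_start_date"] = present(op - dt.timedelta(days=30))
        for item, plan in plans.items():
            if plan["unstructured"]:
                if idx >= plan["a"]:
                    reg_items[item] = DataItemValue()
                emr_items[item] = unstructured()
                continue
            a, b, e, c = plan["a"], plan["b"], plan["e"], plan["c"]
            if idx >= a:
                reg_items[item] = DataItemValue()
            if not (a - e <= idx < a - e + b):
                emr_items[item] = DataItemValue()
            elif a - (e - c) <= idx < a and emr_items[item].present:
                # an evaluable pair marked inconsistent: corrupt the EMR value
                emr_items[item] = present(
                    corrupt_value(item, emr_items[item].value, op, rng)
                )
        registry.append(
            PatientRecord(f"r{idx:04d}", "registry", base.gender, reg_items)
        )
        emr.append(PatientRecord(f"e{idx:04d}", "emr", base.gender, emr_items))
    pairs = list(zip(registry, emr))
    return registry, emr, pairs
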