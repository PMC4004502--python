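"""Evaluation of indicator definitions over a dataset.

An element (numerator or denominator) is *computable* on a dataset iff every
data item its predicates read is available in a structured format there,
i.e. at least one record carries the item with a status other than
``unstructured``.  Non-computable elements get no selection and no counts.

Selection semantics: a record is in the denominator iff the denominator
predicate is satisfied and the exclusion predicate is not satisfied; the
numerator additionally requires the numerator predicate to be satisfied.
Undetermined outcomes never select.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .._util import pct
from ..errors import DefinitionError
from ..records import PatientRecord, Status, present
from .definitions import ELEMENTS, IndicatorDefinition
from .predicates import Tri, evaluate_predicate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ElementResult:
    """Selection outcome for one indicator element on one dataset."""

    computable: bool
    reason: str | None = None
    selected: frozenset[str] = frozenset()
    undetermined: frozenset[str] = frozenset()

    @property
    def count(self) -> int | None:
        return len(self.selected) if self.computable else None


@dataclass(frozen=True)
class IndicatorResult:
    """Result of one indicator on one dataset."""

    indicator_id: str
    kind: str
    numerator: ElementResult
    denominator: ElementResult

    @property
    def percentage(self) -> float | None:
        """``100 * |numerator| / |denominator|`` when defined, else ``None``."""
        if self.kind == "count":
            return None
        if not (self.numerator.computable and self.denominator.computable):
            return None
        if not self.denominator.selected:
            return None
        return pct(len(self.numerator.selected), len(self.denominator.selected))


def item_available(dataset: Sequence[PatientRecord], item: str) -> bool:
    """Dataset-level structured availability of ``item``."""
    return any(rec.items[item].status is not Status.UNSTRUCTURED for rec in dataset)


def _element_computable(
    dataset: Sequence[PatientRecord], definition: IndicatorDefinition, element: str
) -> tuple[bool, str | None]:
    if element == "numerator":
        if definition.numerator_excluded:
            return False, "excluded_by_design"
        if definition.numerator_predicate is None:
            return False, "no_numerator"
    if not dataset:
        return True, None  # vacuously computable; counts are zero
    unavailable = sorted(
        it for it in definition.required_items(element) if not item_available(dataset, it)
    )
    if unavailable:
        return False, f"items_unstructured: {', '.join(unavailable)}"
    return True, None


def _evaluate_membership(
    record: PatientRecord, definition: IndicatorDefinition, element: str, strict: bool
) -> Tri:
    den = evaluate_predicate(record, definition.denominator_predicate, strict)
    if definition.exclusion_predicate is not None:
        excl = evaluate_predicate(record, definition.exclusion_predicate, strict)
    else:
        excl = Tri.NOT_SATISFIED
    # in-denominator = den AND NOT excl, under Kleene logic
    if den is Tri.NOT_SATISFIED or excl is Tri.SATISFIED:
        member = Tri.NOT_SATISFIED
    elif den is Tri.UNDETERMINED or excl is Tri.UNDETERMINED:
        member = Tri.UNDETERMINED
    else:
        member = Tri.SATISFIED
    if element == "denominator":
        return member
    if member is Tri.NOT_SATISFIED:
        return Tri.NOT_SATISFIED
    num = evaluate_predicate(record, definition.numerator_predicate, strict)
    if member is Tri.UNDETERMINED:
        return Tri.NOT_SATISFIED if num is Tri.NOT_SATISFIED else Tri.UNDETERMINED
    return num


def _compute_element(
    dataset: Sequence[PatientRecord],
    definition: IndicatorDefinition,
    element: str,
    strict: bool,
) -> ElementResult:
    computable, reason = _element_computable(dataset, definition, element)
    if not computable:
        return ElementResult(computable=False, reason=reason)
    selected, undet = set(), set()
    for record in dataset:
        outcome = _evaluate_membership(record, definition, element, strict)
        if outcome is Tri.SATISFIED:
            selected.add(record.patient_id)
        elif outcome is Tri.UNDETERMINED:
            undet.add(record.patient_id)
    return ElementResult(
        computable=True, selected=frozenset(selected), undetermined=frozenset(undet)
    )


def compute_indicator(
    dataset: Sequence[PatientRecord],
    definition: IndicatorDefinition,
    strict_exclusions: bool = False,
) -> IndicatorResult:
    """Evaluate one indicator on a dataset.

    ``strict_exclusions`` treats absent optional exclusion flags as
    undetermined rather than not-excluded.
    """
    denominator = _compute_element(dataset, definition, "denominator", strict_exclusions)
    if definition.has_numerator and denominator.computable:
        numerator = _compute_element(dataset, definition, "numerator", strict_exclusions)
        if numerator.computable:
            # numerator membership requires denominator membership per record,
            # so containment holds by construction; assert the invariant.
            assert numerator.selected <= denominator.selected
    else:
        computable, reason = _element_computable(dataset, definition, "numerator")
        numerator = ElementResult(computable=False, reason=reason or denominator.reason)
    return IndicatorResult(
        indicator_id=definition.id,
        kind=definition.kind,
        numerator=numerator,
        denominator=denominator,
    )


def select_patients(
    dataset: Sequence[PatientRecord],
    definition: IndicatorDefinition,
    element: str,
    strict_exclusions: bool = False,
) -> frozenset[str]:
    """Ids selected by ``element`` of ``definition``; empty if non-computable."""
    if element not in ELEMENTS:
        raise DefinitionError(f"unknown element {element!r}")
    return _compute_element(dataset, definition, element, strict_exclusions).selected


def harmonise_urgency(
    dataset: Iterable[PatientRecord], mapping: Mapping[str, str]
) -> tuple[list[PatientRecord], list[str]]:
    """Map source-system urgency categories onto the registry's categories.

    Returns the harmonised dataset and the list of patient ids whose category
    had no mapping (a standardisation problem); those records keep their raw
    category so downstream evaluation can still report them.
    """
    out, unmapped = [], []
    for record in dataset:
        div = record.items["operation_urgency"]
        if div.present and div.value in mapping:
            items = dict(record.items)
            items["operation_urgency"] = present(mapping[div.value])
            record = PatientRecord(
                patient_id=record.patient_id,
                source=record.source,
                gender=record.gender,
                items=items,
            )
        elif div.present:
            unmapped.append(record.patient_id)
            logger.warning(
                "unmapped operation-urgency category %r for patient %s",
                div.value,
                record.patient_id,
            )
        out.append(record)
    return out, unmapped
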