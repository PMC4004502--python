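"""Per-item data-quality measurement: availability, completeness, correctness.

Completeness is the share of applicable records in which an item is actually
recorded; values explicitly recorded as 'unknown' and values existing only
as free text count as absent.  Correctness is measured over matched pairs
in which both sources carry the item, and asks for *effect equivalence*: the
two values must drive the indicator computation the same way (a meeting date
is correct when both dates fall on the same side of the operation date, not
when they are byte-equal).

Four items apply only to patients for whom the respective event occurred
(colonoscopy, chemotherapy/medication, meeting date, radiotherapy start
date); they are excluded from the completeness average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from ._util import pct
from .errors import DefinitionError
from .records import ITEM_NAMES, PatientRecord, Status

#: Items applicable to every operated patient; the rest are event-conditional.
UNIVERSAL_ITEMS: tuple[str, ...] = (
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
)
CONDITIONAL_ITEMS: tuple[str, ...] = (
    "colonoscopy",
    "chemotherapy",
    "meeting_date",
    "radiotherapy_start_date",
)

ApplicabilityRule = Callable[[PatientRecord], bool]
ConsistencyRule = Callable[[PatientRecord, PatientRecord], "bool | None"]


@dataclass(frozen=True)
class QualityValue:
    """A percentage with the counts it came from; undefined when denominator 0."""

    numerator: int
    denominator: int

    @property
    def percentage(self) -> float | None:
        return pct(self.numerator, self.denominator)

    @property
    def defined(self) -> bool:
        return self.denominator > 0


def structured_available(dataset: Sequence[PatientRecord], item: str) -> bool:
    """True iff at least one record carries the item in a structured status."""
    _check_item(item)
    return any(rec.items[item].status is not Status.UNSTRUCTURED for rec in dataset)


def completeness(
    dataset: Sequence[PatientRecord],
    item: str,
    applicability_rule: ApplicabilityRule | None = None,
) -> QualityValue:
    """Share of applicable records with the item present.

    With no ``applicability_rule`` every record is applicable.  Undefined
    (denominator 0) when the rule rules out every record.
    """
    _check_item(item)
    applicable = [
        rec for rec in dataset if applicability_rule is None or applicability_rule(rec)
    ]
    n_present = sum(rec.items[item].status is Status.PRESENT for rec in applicable)
    return QualityValue(numerator=n_present, denominator=len(applicable))


def correctness(
    matched_pairs: Iterable[tuple[PatientRecord, PatientRecord]],
    item: str,
    consistency_rule: ConsistencyRule | None = None,
) -> QualityValue:
    """Share of evaluable matched pairs whose values are effect-consistent.

    A pair is evaluable when both sources carry the item present and the rule
    can reach a verdict (rules return ``None`` when e.g. a needed reference
    date is itself missing).  Undefined when no pair is evaluable.
    """
    _check_item(item)
    rule = consistency_rule if consistency_rule is not None else CONSISTENCY_RULES[item]
    n_eval = n_ok = 0
    for ref, test in matched_pairs:
        if not (ref.items[item].present and test.items[item].present):
            continue
        verdict = rule(ref, test)
        if verdict is None:
            continue
        n_eval += 1
        n_ok += bool(verdict)
    return QualityValue(numerator=n_ok, denominator=n_eval)


def _check_item(item: str) -> None:
    if item not in ITEM_NAMES:
        raise DefinitionError(f"unknown data item {item!r}")


# -- effect-consistency rules -------------------------------------------------

def _value(rec: PatientRecord, item: str, fld: str | None = None):
    v, status = rec.get(item, fld)
    return v if status is Status.PRESENT else None


def _same_side_of_operation(item: str) -> ConsistencyRule:
    def rule(a: PatientRecord, b: PatientRecord) -> bool | None:
        sides = []
        for rec in (a, b):
            d = _value(rec, item)
            op = rec.operation_date
            if d is None or op is None:
                return None
            sides.append(d < op)
        return sides[0] == sides[1]

    return rule


def _equal(item: str, fld: str | None = None) -> ConsistencyRule:
    def rule(a: PatientRecord, b: PatientRecord) -> bool | None:
        va, vb = _value(a, item, fld), _value(b, item, fld)
        if va is None or vb is None:
            return None
        return va == vb

    return rule


def _same_class(item: str, fld: str, classifier: Callable) -> ConsistencyRule:
    def rule(a: PatientRecord, b: PatientRecord) -> bool | None:
        va, vb = _value(a, item, fld), _value(b, item, fld)
        if va is None or vb is None:
            return None
        return classifier(va) == classifier(vb)

    return rule


def _resection_classes(codes) -> frozenset[str]:
    return frozenset(c for c in codes if c in ("colectomy", "rectum_resection"))


def _procedure_rule(a: PatientRecord, b: PatientRecord) -> bool | None:
    va, vb = _value(a, "procedure"), _value(b, "procedure")
    if va is None or vb is None:
        return None
    return _resection_classes(va) == _resection_classes(vb)


def _threshold_rule(item: str, test: Callable) -> ConsistencyRule:
    def rule(a: PatientRecord, b: PatientRecord) -> bool | None:
        va, vb = _value(a, item), _value(b, item)
        if va is None or vb is None:
            return None
        return test(va) == test(vb)

    return rule


def _colonoscopy_rule(a: PatientRecord, b: PatientRecord) -> bool | None:
    # effect on the imaging indicator: complete colonoscopy before operation
    verdicts = []
    for rec in (a, b):
        complete = _value(rec, "colonoscopy", "complete")
        date = _value(rec, "colonoscopy", "date")
        op = rec.operation_date
        if complete is None or op is None:
            return None
        if not complete:
            verdicts.append(False)
            continue
        if date is None:
            return None
        verdicts.append(date < op)
    return verdicts[0] == verdicts[1]


#: Default effect-consistency rule per item (all symmetric in the two sources).
CONSISTENCY_RULES: dict[str, ConsistencyRule] = {
    "operation_date": _equal("operation_date"),
    "year_of_birth": _equal("year_of_birth"),
    "procedure": _procedure_rule,
    "operation_urgency": _threshold_rule("operation_urgency", lambda v: v == "elective"),
    "diagnosis": _same_class(
        "diagnosis", "location", lambda loc: "rectal" if loc == "rectum" else "colonic"
    ),
    "ct_stage": _threshold_rule("ct_stage", lambda v: v in ("T3", "T4")),
    "pn_stage": _threshold_rule("pn_stage", lambda v: v in ("N1", "N2")),
    "pm_stage": _threshold_rule("pm_stage", lambda v: v == "M0"),
    "examined_lymph_nodes": _threshold_rule("examined_lymph_nodes", lambda v: v >= 10),
    "circumferential_margin_mm": _threshold_rule(
        "circumferential_margin_mm", lambda v: v <= 1
    ),
    "colonoscopy": _colonoscopy_rule,
    "chemotherapy": _equal("chemotherapy", "received"),
    "meeting_date": _same_side_of_operation("meeting_date"),
    "radiotherapy_start_date": _same_side_of_operation("radiotherapy_start_date"),
}


# -- report assembly ----------------------------------------------------------

@dataclass(frozen=True)
class ItemQuality:
    item: str
    universal: bool
    available_registry: bool
    available_emr: bool
    completeness_registry: QualityValue
    completeness_emr: QualityValue
    correctness: QualityValue


@dataclass
class QualityReport:
    items: dict[str, ItemQuality] = field(default_factory=dict)

    @property
    def averages(self) -> dict[str, float | None]:
        return aggregate_quality(self)


def quality_report(
    registry_dataset: Sequence[PatientRecord],
    emr_dataset: Sequence[PatientRecord],
    matched_pairs: Iterable[tuple[PatientRecord, PatientRecord]],
    applicability_rules: dict[str, ApplicabilityRule] | None = None,
) -> QualityReport:
    """Full per-item report over the two datasets and their matched pairs."""
    pairs = list(matched_pairs)
    rules = applicability_rules or {}
    report = QualityReport()
    for item in ITEM_NAMES:
        rule = rules.get(item)
        report.items[item] = ItemQuality(
            item=item,
            universal=item in UNIVERSAL_ITEMS,
            available_registry=structured_available(registry_dataset, item),
            available_emr=structured_available(emr_dataset, item),
            completeness_registry=completeness(registry_dataset, item, rule),
            completeness_emr=completeness(emr_dataset, item, rule),
            correctness=correctness(pairs, item),
        )
    return report


def aggregate_quality(report: QualityReport) -> dict[str, float | None]:
    """Applicability-aware unweighted averages.

    Completeness averages run over the universally-applicable items only
    (event-conditional items are excluded); the correctness average runs over
    every item with at least one evaluable pair.
    """
    def mean(values: list[float]) -> float | None:
        return sum(values) / len(values) if values else None

    reg = [
        iq.completeness_registry.percentage
        for iq in report.items.values()
        if iq.universal and iq.completeness_registry.defined
    ]
    emr = [
        iq.completeness_emr.percentage
        for iq in report.items.values()
        if iq.universal and iq.completeness_emr.defined
    ]
    corr = [
        iq.correctness.percentage for iq in report.items.values() if iq.correctness.defined
    ]
    return {
        "completeness_registry": mean(reg),
        "completeness_emr": mean(emr),
        "correctness": mean(corr),
    }
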