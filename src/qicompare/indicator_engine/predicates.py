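"""Three-valued evaluation of declarative predicate trees.

Predicates are plain JSON-compatible dicts so that indicator definitions can
be shipped, inspected and overridden as data.  The grammar:

``{"all": [p, ...]}``
    Kleene conjunction: not_satisfied if any child is, else undetermined if
    any child is, else satisfied.
``{"any": [p, ...]}``
    Kleene disjunction (dual).
``{"not": p}``
    Negation; undetermined stays undetermined.
``{"item": name, "op": op, ...}``
    Leaf test on a data item.  ``"field"`` selects a compound sub-field.
    ``"absent_as": "false"`` makes an absent item evaluate to not_satisfied
    instead of undetermined (used for optional exclusion flags; disabled in
    strict mode).
``{"op": "age_lt"/"age_ge", "value": y}``
    Age at operation, computed as operation-date year minus year of birth.

Leaf operators: ``eq ne ge gt le lt in is_true is_false intersects`` plus the
date comparators ``before_item on_or_before_item after_item`` which compare a
date-valued item against another item named in ``"other"``.
"""

from __future__ import annotations

from enum import Enum
from typing import Any, Iterator, Mapping

from ..errors import DefinitionError
from ..records import ALL_ITEM_NAMES, COMPOUND_FIELDS, PatientRecord, Status


class Tri(Enum):
    """Outcome of a three-valued predicate evaluation."""

    SATISFIED = "satisfied"
    NOT_SATISFIED = "not_satisfied"
    UNDETERMINED = "undetermined"


_SAT, _NOT, _UND = Tri.SATISFIED, Tri.NOT_SATISFIED, Tri.UNDETERMINED

_SCALAR_OPS = frozenset(
    {"eq", "ne", "ge", "gt", "le", "lt", "in", "is_true", "is_false", "intersects"}
)
_DATE_OPS = frozenset({"before_item", "on_or_before_item", "after_item"})
_AGE_OPS = frozenset({"age_lt", "age_ge"})


def evaluate_predicate(
    record: PatientRecord, predicate: Mapping[str, Any], strict: bool = False
) -> Tri:
    """Evaluate ``predicate`` against ``record`` under Kleene three-valued logic.

    ``strict`` disables the ``absent_as: false`` escape hatch, so absent
    optional flags yield undetermined instead of not_satisfied.
    """
    if "all" in predicate:
        results = [evaluate_predicate(record, p, strict) for p in predicate["all"]]
        if _NOT in results:
            return _NOT
        if _UND in results:
            return _UND
        return _SAT
    if "any" in predicate:
        results = [evaluate_predicate(record, p, strict) for p in predicate["any"]]
        if _SAT in results:
            return _SAT
        if _UND in results:
            return _UND
        return _NOT
    if "not" in predicate:
        inner = evaluate_predicate(record, predicate["not"], strict)
        return {_SAT: _NOT, _NOT: _SAT, _UND: _UND}[inner]
    return _evaluate_leaf(record, predicate, strict)


def _evaluate_leaf(record: PatientRecord, leaf: Mapping[str, Any], strict: bool) -> Tri:
    op = leaf.get("op")
    if op is None:
        raise DefinitionError(f"predicate node without op: {leaf!r}")

    if op in _AGE_OPS:
        opdate, st1 = record.get("operation_date")
        yob, st2 = record.get("year_of_birth")
        if st1 is not Status.PRESENT or st2 is not Status.PRESENT:
            return _UND
        age = opdate.year - yob
        ok = age < leaf["value"] if op == "age_lt" else age >= leaf["value"]
        return _SAT if ok else _NOT

    item = leaf.get("item")
    if item is None:
        raise DefinitionError(f"leaf predicate lacks an item: {leaf!r}")
    value, status = record.get(item, leaf.get("field"))
    if status is not Status.PRESENT:
        if not strict and leaf.get("absent_as") == "false" and status is Status.ABSENT:
            return _NOT
        return _UND

    if op in _DATE_OPS:
        other = leaf["other"]
        other_value, other_status = record.get(other["item"], other.get("field"))
        if other_status is not Status.PRESENT:
            return _UND
        if op == "before_item":
            ok = value < other_value
        elif op == "on_or_before_item":
            ok = value <= other_value
        else:
            ok = value > other_value
        return _SAT if ok else _NOT

    if op not in _SCALAR_OPS:
        raise DefinitionError(f"unknown predicate operator {op!r}")
    target = leaf.get("value")
    if op == "eq":
        ok = value == target
    elif op == "ne":
        ok = value != target
    elif op == "ge":
        ok = value >= target
    elif op == "gt":
        ok = value > target
    elif op == "le":
        ok = value <= target
    elif op == "lt":
        ok = value < target
    elif op == "in":
        ok = value in target
    elif op == "is_true":
        ok = bool(value)
    elif op == "is_false":
        ok = not bool(value)
    else:  # intersects: set-valued item vs code list
        ok = bool(set(value) & set(target))
    return _SAT if ok else _NOT


def referenced_items(
    predicate: Mapping[str, Any], include_optional_flags: bool = True
) -> frozenset[str]:
    """All item names a predicate tree reads.

    Optional-flag leaves (those carrying ``absent_as``) can be excluded, which
    is what computability assessment needs: an absent optional flag still has
    a decidable outcome.
    """

    def walk(node: Mapping[str, Any]) -> Iterator[str]:
        for key in ("all", "any"):
            if key in node:
                for child in node[key]:
                    yield from walk(child)
                return
        if "not" in node:
            yield from walk(node["not"])
            return
        op = node.get("op")
        if op in _AGE_OPS:
            yield "operation_date"
            yield "year_of_birth"
            return
        if not include_optional_flags and node.get("absent_as") == "false":
            return
        if "item" not in node:
            raise DefinitionError(f"leaf predicate lacks an item: {node!r}")
        yield node["item"]
        if op in _DATE_OPS:
            if "other" not in node:
                raise DefinitionError(f"{op} requires an 'other' item: {node!r}")
            yield node["other"]["item"]

    items = frozenset(walk(predicate))
    bad = items - set(ALL_ITEM_NAMES)
    if bad:
        raise DefinitionError(f"predicate references unknown items: {sorted(bad)}")
    return items


def validate_predicate(predicate: Mapping[str, Any]) -> None:
    """Structural validation; raises :class:`DefinitionError` on malformed trees."""
    referenced_items(predicate)  # walks the whole tree, checking item names

    def walk(node: Mapping[str, Any]) -> None:
        for key in ("all", "any"):
            if key in node:
                if not node[key]:
                    raise DefinitionError(f"empty {key!r} clause")
                for child in node[key]:
                    walk(child)
                return
        if "not" in node:
            walk(node["not"])
            return
        op = node.get("op")
        if op in _AGE_OPS:
            return
        if op in _DATE_OPS:
            if "other" not in node:
                raise DefinitionError(f"{op} requires an 'other' item: {node!r}")
            return
        if op not in _SCALAR_OPS:
            raise DefinitionError(f"unknown predicate operator {op!r}")
        item, fld = node.get("item"), node.get("field")
        if fld is not None and fld not in COMPOUND_FIELDS.get(item, ()):
            raise DefinitionError(f"item {item!r} has no field {fld!r}")

    walk(predicate)
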