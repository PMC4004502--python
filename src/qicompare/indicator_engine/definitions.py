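"""Loading and validation of declarative indicator definitions.

Definitions ship as a JSON document (one object per indicator, predicate
trees as data) with code-list placeholders (``"$colonic_locations"`` etc.)
resolved against a YAML code-list document at load time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from ..errors import DefinitionError
from .predicates import referenced_items, validate_predicate

_CODE_LIST_KEYS = (
    "colonic_locations",
    "rectal_locations",
    "colectomy_codes",
    "rectum_resection_codes",
    "elective_categories",
)

ELEMENTS = ("numerator", "denominator")


@dataclass(frozen=True)
class IndicatorDefinition:
    """One indicator: numerator/denominator/exclusion predicate trees.

    ``numerator_excluded`` marks numerators that cannot meaningfully be
    evaluated on either dataset (registry-submission items); their
    denominators are still computed.
    """

    id: str
    kind: str  # process | outcome | count
    title: str
    denominator_predicate: Mapping[str, Any]
    numerator_predicate: Mapping[str, Any] | None = None
    exclusion_predicate: Mapping[str, Any] | None = None
    numerator_excluded: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("process", "outcome", "count"):
            raise DefinitionError(f"indicator {self.id}: unknown kind {self.kind!r}")
        validate_predicate(self.denominator_predicate)
        if self.numerator_predicate is not None:
            validate_predicate(self.numerator_predicate)
        if self.exclusion_predicate is not None:
            validate_predicate(self.exclusion_predicate)

    def required_items(self, element: str) -> frozenset[str]:
        """Items that must be structurally available to compute ``element``.

        Optional exclusion flags do not gate computability: when absent they
        still yield a decidable (not-excluded) outcome in lenient mode.
        """
        if element not in ELEMENTS:
            raise DefinitionError(f"unknown element {element!r}")
        items = referenced_items(self.denominator_predicate, include_optional_flags=False)
        if self.exclusion_predicate is not None:
            items |= referenced_items(self.exclusion_predicate, include_optional_flags=False)
        if element == "numerator":
            if self.numerator_predicate is None:
                return frozenset()
            items |= referenced_items(self.numerator_predicate, include_optional_flags=False)
        return items

    @property
    def has_numerator(self) -> bool:
        return self.numerator_predicate is not None


@dataclass
class IndicatorSet:
    """An ordered collection of indicator definitions keyed by id."""

    definitions: dict[str, IndicatorDefinition] = field(default_factory=dict)

    def __getitem__(self, indicator_id: str) -> IndicatorDefinition:
        try:
            return self.definitions[indicator_id]
        except KeyError:
            raise DefinitionError(f"unknown indicator id {indicator_id!r}") from None

    def __iter__(self):
        return iter(self.definitions.values())

    def __len__(self) -> int:
        return len(self.definitions)

    def element(self, element_id: str) -> tuple[IndicatorDefinition, str]:
        """Resolve an ``"<indicator>.<numerator|denominator>"`` element id."""
        try:
            indicator_id, elem = element_id.rsplit(".", 1)
        except ValueError:
            raise DefinitionError(f"malformed element id {element_id!r}") from None
        if elem not in ELEMENTS:
            raise DefinitionError(f"unknown element {elem!r} in {element_id!r}")
        return self[indicator_id], elem


def load_code_lists(path: str | Path | None = None) -> dict[str, Any]:
    if path is None:
        text = resources.files("qicompare.indicator_engine").joinpath("code_lists.yaml").read_text()
    else:
        text = Path(path).read_text()
    lists = yaml.safe_load(text)
    missing = [k for k in _CODE_LIST_KEYS if k not in lists]
    if missing:
        raise DefinitionError(f"code-list document lacks keys: {missing}")
    return lists


def _substitute(node: Any, code_lists: Mapping[str, Any]) -> Any:
    if isinstance(node, str) and node.startswith("$"):
        key = node[1:]
        if key not in code_lists:
            raise DefinitionError(f"unknown code-list placeholder {node!r}")
        return code_lists[key]
    if isinstance(node, dict):
        return {k: _substitute(v, code_lists) for k, v in node.items()}
    if isinstance(node, list):
        return [_substitute(v, code_lists) for v in node]
    return node


def load_definitions(
    path: str | Path | None = None,
    code_lists: Mapping[str, Any] | None = None,
    indicator7_require_resection: bool = False,
) -> IndicatorSet:
    """Load the indicator set from ``path`` (default: the packaged document).

    ``indicator7_require_resection`` switches the radiotherapy indicator to
    the variant whose denominator additionally requires a rectal resection.
    """
    if path is None:
        text = resources.files("qicompare.indicator_engine").joinpath("indicators.json").read_text()
    else:
        text = Path(path).read_text()
    doc = json.loads(text)
    if code_lists is None:
        code_lists = load_code_lists()

    indicator_set = IndicatorSet()
    for raw in doc["indicators"]:
        raw = _substitute(raw, code_lists)
        denominator = raw["denominator"]
        if raw["id"] == "7" and indicator7_require_resection:
            denominator = raw.get("denominator_with_resection", denominator)
        definition = IndicatorDefinition(
            id=raw["id"],
            kind=raw["kind"],
            title=raw.get("title", raw["id"]),
            denominator_predicate=denominator,
            numerator_predicate=raw.get("numerator"),
            exclusion_predicate=raw.get("exclusion"),
            numerator_excluded=bool(raw.get("numerator_excluded", False)),
        )
        if definition.id in indicator_set.definitions:
            raise DefinitionError(f"duplicate indicator id {definition.id!r}")
        indicator_set.definitions[definition.id] = definition
    return indicator_set
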