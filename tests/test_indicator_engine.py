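import numpy as np
import pytest

from qicompare._util import round_half_up
from qicompare.errors import DefinitionError
from qicompare.indicator_engine import (
    Tri,
    compute_indicator,
    evaluate_predicate,
    harmonise_urgency,
    item_available,
    load_definitions,
    select_patients,
)
from qicompare.records import DataItemValue, Status, present, unstructured
from qicompare.synthetic_data import build_fixture_from_crosstab

import oracles
from conftest import make_record, random_dataset, random_record


def test_indicator2_percentage_39_of_46(indicator_set):
    # 46 denominator-qualifying colonic resections, 39 with >= 10 nodes
    registry, _ = build_fixture_from_crosstab("2.numerator", tp=39, ref_only=0,
                                              test_only=0, tn=7)
    result = compute_indicator(registry, indicator_set["2"])
    assert result.denominator.count == 46
    assert result.numerator.count == 39
    assert result.percentage == pytest.approx(100 * 39 / 46)
    assert round_half_up(result.percentage) == 85


def test_unstructured_stage_items_make_indicators_non_computable(indicator_set):
    dataset = [
        make_record(pid=f"p{i}", ct_stage=unstructured(), pn_stage=unstructured(),
                    pm_stage=unstructured())
        for i in range(5)
    ]
    for indicator_id in ("5a", "5b", "7"):
        result = compute_indicator(dataset, indicator_set[indicator_id])
        assert not result.denominator.computable
        assert "items_unstructured" in result.denominator.reason
        assert result.percentage is None
    # but indicator 2 (nodes present) still computes
    assert compute_indicator(dataset, indicator_set["2"]).denominator.computable


def test_empty_dataset_yields_zero_counts_and_undefined_percentage(indicator_set):
    for definition in indicator_set:
        result = compute_indicator([], definition)
        assert result.denominator.count == 0
        assert result.percentage is None


def test_numerators_excluded_by_design(indicator_set):
    rectal = make_record(
        diagnosis={"location": "rectum", "primary": True,
                   "date": make_record().operation_date},
        procedure={"rectum_resection"},
    )
    for indicator_id, dataset in (("1", [make_record()]), ("6a", [rectal])):
        result = compute_indicator(dataset, indicator_set[indicator_id])
        assert not result.numerator.computable
        assert result.numerator.reason == "excluded_by_design"
        assert result.denominator.computable and result.denominator.count == 1


def test_exclusion_flags_lenient_vs_strict(indicator_set):
    excluded = make_record(pid="x", recurrent_carcinoma=True)
    clean = make_record(pid="c")
    dataset = [excluded, clean]
    selected = select_patients(dataset, indicator_set["2"], "denominator")
    assert selected == {"c"}
    # strict mode: absent flags become undetermined, so even the clean record drops
    strict_sel = select_patients(dataset, indicator_set["2"], "denominator",
                                 strict_exclusions=True)
    assert strict_sel == set()


def test_select_patients_unknown_element(indicator_set):
    with pytest.raises(DefinitionError):
        select_patients([], indicator_set["2"], "nominator")


def test_required_items_cover_predicate_references(indicator_set):
    from qicompare.indicator_engine import referenced_items

    for definition in indicator_set:
        for element in ("numerator", "denominator"):
            if element == "numerator" and not definition.has_numerator:
                continue
            required = definition.required_items(element)
            refs = referenced_items(definition.denominator_predicate,
                                    include_optional_flags=False)
            if element == "numerator":
                refs |= referenced_items(definition.numerator_predicate,
                                         include_optional_flags=False)
            assert refs <= required


def test_item_available_semantics():
    dataset = [make_record(ct_stage=unstructured())]
    assert not item_available(dataset, "ct_stage")
    dataset.append(make_record(pid="p2", ct_stage=None))  # absent still counts
    assert item_available(dataset, "ct_stage")


def test_selection_equals_naive_oracle_on_random_datasets(indicator_set):
    rng = np.random.default_rng(42)
    for _ in range(120):
        dataset = random_dataset(rng, int(rng.integers(1, 8)))
        for definition in indicator_set:
            for element in ("numerator", "denominator"):
                if element == "numerator" and not definition.has_numerator:
                    continue
                got = select_patients(dataset, definition, element)
                want = oracles.naive_select(dataset, definition, element)
                assert got == want, (definition.id, element)


def test_numerator_subset_of_denominator_on_random_datasets(indicator_set):
    rng = np.random.default_rng(7)
    for _ in range(60):
        dataset = random_dataset(rng, 6)
        for definition in indicator_set:
            if not definition.has_numerator:
                continue
            num = select_patients(dataset, definition, "numerator")
            den = select_patients(dataset, definition, "denominator")
            assert num <= den


def test_monotonicity_adding_a_record_never_unselects(indicator_set):
    rng = np.random.default_rng(11)
    for _ in range(40):
        dataset = random_dataset(rng, 5)
        extra = [random_record(rng, "rextra")]
        for definition in indicator_set:
            before = select_patients(dataset, definition, "denominator")
            after = select_patients(dataset + extra, definition, "denominator")
            assert before <= after


def test_three_valued_soundness_removing_information_never_flips(indicator_set):
    # contrapositive: blanking one item can only move a determinate outcome
    # to undetermined, never SAT <-> NOT
    rng = np.random.default_rng(13)
    determinate = {Tri.SATISFIED, Tri.NOT_SATISFIED}
    for _ in range(40):
        record = random_dataset(rng, 1, with_anchor=False)[0]
        for definition in indicator_set:
            before = evaluate_predicate(record, definition.denominator_predicate)
            for item in definition.required_items("denominator"):
                blanked = make_blanked(record, item)
                after = evaluate_predicate(blanked, definition.denominator_predicate)
                if before in determinate and after in determinate:
                    assert after is before


def make_blanked(record, item):
    items = dict(record.items)
    items[item] = DataItemValue()
    from qicompare.records import PatientRecord

    return PatientRecord(record.patient_id, record.source, record.gender, items)


def test_harmonise_urgency_maps_and_reports_unmapped():
    dataset = [
        make_record(pid="a", operation_urgency="planned"),
        make_record(pid="b", operation_urgency="extra"),
        make_record(pid="c", operation_urgency=None),
    ]
    mapping = {"planned": "elective"}
    out, unmapped = harmonise_urgency(dataset, mapping)
    by_id = {r.patient_id: r for r in out}
    assert by_id["a"].items["operation_urgency"].value == "elective"
    assert by_id["b"].items["operation_urgency"].value == "extra"
    assert unmapped == ["b"]


def test_indicator7_variant_flag():
    default = load_definitions()
    strict7 = load_definitions(indicator7_require_resection=True)
    # without a resection procedure the default still selects, the variant not
    record = make_record(
        diagnosis={"location": "rectum", "primary": True, "date": None},
        ct_stage="T3",
        procedure={"appendectomy"},
    )
    assert select_patients([record], default["7"], "denominator") == {"p1"}
    assert select_patients([record], strict7["7"], "denominator") == set()


def test_load_definitions_rejects_bad_code_lists():
    with pytest.raises(DefinitionError):
        load_definitions(code_lists={"colonic_locations": ["colon"]})
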