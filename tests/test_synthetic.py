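import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pydantic import ValidationError

from qicompare.data_quality import completeness, correctness
from qicompare.errors import ConfigurationError, DefinitionError, EmptyCohortError
from qicompare.io import dataset_to_dataframe
from qicompare.records import Status
from qicompare.synthetic_data import (
    GeneratorConfig,
    build_fixture_from_crosstab,
    evaluate_fixture,
    generate_paired_cohort,
)
from qicompare.synthetic_data.config import SourceRates, validate_config

import oracles
from qicompare.indicator_engine import load_definitions
from qicompare.synthetic_data.generator import _truth_record


def _pairs(registry, emr, ledger):
    reg_by = {r.patient_id: r for r in registry}
    emr_by = {e.patient_id: e for e in emr}
    return [
        (reg_by[rid], emr_by[eid])
        for rid, eid in ledger.registry_to_emr.items()
        if rid in reg_by
    ]


def test_no_degradation_sources_agree_on_every_item():
    registry, emr, ledger = generate_paired_cohort(GeneratorConfig(n_patients=40, seed=1))
    assert len(registry) == len(emr) == 40
    for reg, e in _pairs(registry, emr, ledger):
        assert reg.gender == e.gender
        for item, div in reg.items.items():
            assert div.status == e.items[item].status, item
            assert div.value == e.items[item].value, item


def test_identical_seed_and_config_byte_identical():
    config = GeneratorConfig(
        n_patients=50, seed=9, registry_coverage=0.8,
        per_item_completeness={"meeting_date": SourceRates(emr=0.5, registry=0.7)},
        per_item_error={"chemotherapy": 0.4},
        unstructured_items={"ct_stage"},
        emr_extract_noise={"missing_diagnosis": 0.1, "diagnosis_after_operation": 0.1},
    )
    a = generate_paired_cohort(config)
    b = generate_paired_cohort(config)
    for da, db in zip(a[:2], b[:2]):
        assert dataset_to_dataframe(da).to_csv(index=False) == \
               dataset_to_dataframe(db).to_csv(index=False)
    assert generate_paired_cohort(
        config.model_copy(update={"seed": 10})
    )[0] != a[0]


def test_registry_coverage_controls_abstraction():
    config = GeneratorConfig(n_patients=600, seed=2, registry_coverage=0.5)
    registry, emr, ledger = generate_paired_cohort(config)
    assert len(emr) == 600  # the EMR is the source system
    assert 240 <= len(registry) <= 360
    assert len(ledger.registry_to_emr) == len(registry)


def test_unstructured_items_flag_emr_only():
    config = GeneratorConfig(n_patients=20, seed=3, unstructured_items={"pn_stage"})
    registry, emr, _ = generate_paired_cohort(config)
    assert all(e.items["pn_stage"].status is Status.UNSTRUCTURED for e in emr)
    assert all(r.items["pn_stage"].status is Status.PRESENT for r in registry)


def test_unknown_fraction_splits_missingness():
    config = GeneratorConfig(
        n_patients=1200, seed=4,
        per_item_completeness={"meeting_date": SourceRates(emr=0.5)},
        unknown_fraction=0.5,
    )
    _, emr, _ = generate_paired_cohort(config)
    statuses = [e.items["meeting_date"].status for e in emr]
    n_missing = sum(s is not Status.PRESENT for s in statuses)
    n_unknown = sum(s is Status.UNKNOWN for s in statuses)
    assert 0.35 < n_unknown / n_missing < 0.65


def test_anomaly_diagnosis_after_operation():
    config = GeneratorConfig(
        n_patients=30, seed=5,
        emr_extract_noise={"diagnosis_after_operation": 1.0},
    )
    _, emr, _ = generate_paired_cohort(config)
    for e in emr:
        diag = e.items["diagnosis"]
        assert diag.present and diag.value["date"] > e.operation_date


def test_anomaly_missing_diagnosis():
    config = GeneratorConfig(n_patients=30, seed=6,
                             emr_extract_noise={"missing_diagnosis": 1.0})
    _, emr, _ = generate_paired_cohort(config)
    assert all(not e.items["diagnosis"].present for e in emr)


def test_rate_recovery_medium_cohort():
    config = GeneratorConfig(
        n_patients=1500, seed=7,
        per_item_completeness={"circumferential_margin_mm": SourceRates(registry=0.24)},
        per_item_error={"meeting_date": 0.3},
    )
    registry, emr, ledger = generate_paired_cohort(config)
    qv = completeness(registry, "circumferential_margin_mm")
    assert qv.percentage == pytest.approx(24, abs=3)
    corr = correctness(_pairs(registry, emr, ledger), "meeting_date")
    assert corr.percentage == pytest.approx(70, abs=4)


def test_ledger_memberships_match_naive_reevaluation():
    config = GeneratorConfig(n_patients=40, seed=8)
    _, _, ledger = generate_paired_cohort(config)
    indicator_set = load_definitions()
    pristine = {
        pid: _truth_record(pid, ledger.gender[pid], items)
        for pid, items in ledger.true_items.items()
    }
    for pid, memberships in ledger.memberships.items():
        for element_id, member in memberships.items():
            definition, element = indicator_set.element(element_id)
            assert member == oracles.naive_member(pristine[pid], definition, element), (
                pid, element_id)


def test_config_validation():
    with pytest.raises((ConfigurationError, ValidationError)):
        GeneratorConfig(n_patients=10, registry_coverage=1.5)
    with pytest.raises((ConfigurationError, ValidationError)):
        GeneratorConfig(n_patients=10, per_item_error={"meeting_date": -0.1})
    with pytest.raises((ConfigurationError, ValidationError)):
        GeneratorConfig(n_patients=10, per_item_completeness={"no_such_item": {}})
    with pytest.raises(EmptyCohortError):
        validate_config({"n_patients": 0})
    with pytest.raises(ConfigurationError):
        validate_config({"n_patients": 5, "unknown_key": 1})


# --- fixture builders --------------------------------------------------------

ELEMENT_IDS = ["2.numerator", "3.numerator", "4.numerator", "6b.numerator",
               "7.numerator", "3.denominator", "8b.denominator"]


@given(
    element_id=st.sampled_from(ELEMENT_IDS),
    counts=st.tuples(*[st.integers(0, 7)] * 6),
)
@settings(max_examples=60, deadline=None)
def test_fixture_round_trip_exact_counts(element_id, counts):
    tp, ref_only, test_only, tn, extra_ref, extra_test = counts
    registry, emr = build_fixture_from_crosstab(
        element_id, tp, ref_only, test_only, tn, extra_ref, extra_test
    )
    ct, _ = evaluate_fixture(element_id, registry, emr)
    assert (ct.tp, ct.ref_only, ct.test_only, ct.tn) == (tp, ref_only, test_only, tn)


def test_fixture_table3_meeting_denominator_sizes(indicator_set):
    registry, emr = build_fixture_from_crosstab("3.denominator", 25, 4, 8, 0)
    from qicompare.indicator_engine import select_patients

    assert len(select_patients(registry, indicator_set["3"], "denominator")) == 29
    assert len(select_patients(emr, indicator_set["3"], "denominator")) == 33


def test_fixture_empty_counts_yield_empty_datasets():
    registry, emr = build_fixture_from_crosstab("3.numerator", 0, 0, 0, 0)
    assert registry == [] and emr == []
    ct, _ = evaluate_fixture("3.numerator", registry, emr)
    from qicompare.concordance_stats import accuracy_stats

    stats = accuracy_stats(ct)
    assert all(v is None for v in (stats.sensitivity, stats.specificity,
                                   stats.ppv, stats.npv, stats.plr, stats.nlr))


def test_fixture_unknown_element_raises():
    with pytest.raises(DefinitionError):
        build_fixture_from_crosstab("9.numerator", 1, 0, 0, 0)
    with pytest.raises(DefinitionError):
        build_fixture_from_crosstab("1.numerator", 1, 0, 0, 0)  # excluded by design
    with pytest.raises(DefinitionError):
        build_fixture_from_crosstab("3.numerator", -1, 0, 0, 0)
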