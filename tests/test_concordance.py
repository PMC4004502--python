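import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qicompare.concordance_stats import (
    CrossTab,
    accuracy_stats,
    cross_classify,
    likelihood_ratios_from_rounded,
    overlapping_proportions_test,
)
from qicompare.errors import ConsistencyError, DegenerateVarianceError
from qicompare.patient_matching import MatchResult

import oracles


def _matches(pairs):
    return MatchResult(
        matched_pairs=frozenset(pairs),
        unmatched_registry=frozenset(),
        unmatched_emr=frozenset(),
    )


# --- cross_classify ----------------------------------------------------------

def test_cross_classify_counts_matched_pairs():
    matches = _matches({(f"r{i}", f"e{i}") for i in range(10)})
    ref_uni = {f"r{i}" for i in range(10)}
    test_uni = {f"e{i}" for i in range(10)}
    ref_sel = {"r0", "r1", "r2", "r3"}
    test_sel = {"e2", "e3", "e4"}
    ct = cross_classify(ref_sel, test_sel, ref_uni, test_uni, matches, "x")
    assert (ct.tp, ct.ref_only, ct.test_only) == (2, 2, 1)
    assert ct.tn == 5  # r5..r9 pairs selected by neither
    assert (ct.n_ref, ct.n_test) == (10, 10)


def test_cross_classify_disjoint_universes_no_overlap():
    matches = _matches(set())
    ct = cross_classify({"r1"}, {"e1"}, {"r1", "r2"}, {"e1", "e2"}, matches)
    assert ct.tp == 0 and ct.tn == 0
    assert ct.ref_only == 1 and ct.test_only == 1


def test_cross_classify_rejects_selection_outside_universe():
    with pytest.raises(ConsistencyError):
        cross_classify({"r1"}, set(), {"r2"}, set(), _matches(set()))


def test_cross_classify_agrees_with_bruteforce_scan():
    rng = np.random.default_rng(31)
    for _ in range(40):
        n = 200
        pairs = {(f"r{i}", f"e{i}") for i in range(n) if rng.random() < 0.8}
        ref_uni = {f"r{i}" for i in range(n) if rng.random() < 0.9}
        test_uni = {f"e{i}" for i in range(n) if rng.random() < 0.9}
        ref_sel = {r for r in ref_uni if rng.random() < 0.4}
        test_sel = {e for e in test_uni if rng.random() < 0.4}
        ct = cross_classify(ref_sel, test_sel, ref_uni, test_uni, _matches(pairs))
        tp = sum(1 for r, e in pairs if r in ref_sel and e in test_sel)
        tn = sum(
            1 for r, e in pairs
            if r in ref_uni and e in test_uni and r not in ref_sel and e not in test_sel
        )
        assert ct.tp == tp and ct.tn == tn
        assert ct.ref_only == len(ref_sel) - tp
        assert ct.test_only == len(test_sel) - tp


def test_crosstab_validates_counts():
    with pytest.raises(ConsistencyError):
        CrossTab("x", tp=-1, ref_only=0, test_only=0, tn=0, n_ref=0, n_test=0)
    with pytest.raises(ConsistencyError):
        CrossTab("x", tp=5, ref_only=0, test_only=0, tn=0, n_ref=4, n_test=5)


# --- accuracy statistics -----------------------------------------------------

def test_accuracy_stats_meeting_indicator_row():
    ct = CrossTab("3.numerator", tp=23, ref_only=6, test_only=0, tn=0, n_ref=29, n_test=33)
    stats = accuracy_stats(ct)
    assert stats.sensitivity == pytest.approx(23 / 29)
    assert stats.ppv == 1.0
    assert stats.npv == 0.0
    assert stats.specificity is None  # 0/0
    assert stats.fractions["specificity"] == (0, 0)
    assert stats.fractions["npv"] == (0, 10)


def test_accuracy_stats_undefined_on_empty():
    stats = accuracy_stats(CrossTab("x", 0, 0, 0, 0, 0, 0))
    assert stats.sensitivity is None and stats.ppv is None
    assert stats.plr is None and stats.nlr is None


def test_accuracy_stats_imaging_indicator_row():
    ct = CrossTab("4.numerator", tp=21, ref_only=15, test_only=10, tn=3, n_ref=41, n_test=53)
    stats = accuracy_stats(ct)
    assert stats.sensitivity == pytest.approx(21 / 36)
    assert stats.specificity == pytest.approx(3 / 5)
    assert stats.plr == pytest.approx(1.4583333333)
    assert stats.nlr == pytest.approx(0.6944444444)
    plr, nlr = likelihood_ratios_from_rounded(stats)
    assert plr == pytest.approx(1.45)
    assert nlr == pytest.approx(0.70)


@given(tp=st.integers(0, 50), ref_only=st.integers(0, 50), test_only=st.integers(0, 50),
       tn=st.integers(0, 50), extra_ref=st.integers(0, 50), extra_test=st.integers(0, 50))
@settings(max_examples=200, deadline=None)
def test_accuracy_invariants_and_lr_identities(tp, ref_only, test_only, tn, extra_ref, extra_test):
    ct = CrossTab("x", tp, ref_only, test_only, tn,
                  n_ref=tp + ref_only + tn + extra_ref,
                  n_test=tp + test_only + tn + extra_test)
    stats = accuracy_stats(ct)
    for value in (stats.sensitivity, stats.specificity, stats.ppv, stats.npv):
        assert value is None or 0.0 <= value <= 1.0
    if stats.plr is not None:
        assert stats.plr >= 0
        assert abs(stats.plr - stats.sensitivity / (1 - stats.specificity)) < 1e-12
    if stats.nlr is not None:
        assert stats.nlr >= 0
        assert abs(stats.nlr - (1 - stats.sensitivity) / stats.specificity) < 1e-12


# --- overlapping-samples proportion test -------------------------------------

def test_zero_overlap_reduces_to_unpooled_z_test():
    for (x1, n1, x2, n2) in [(29, 29, 23, 33), (36, 41, 31, 53), (10, 40, 20, 50)]:
        result = overlapping_proportions_test(x1, n1, x2, n2, overlap=[])
        z, p = oracles.unpooled_two_proportion_z(x1, n1, x2, n2)
        assert result.z == pytest.approx(z)
        assert result.p_value == pytest.approx(p)
        assert result.covariance == 0.0


def test_fully_shared_identical_outcomes_gives_p_one():
    overlap = [(True, True)] * 12 + [(False, False)] * 8
    result = overlapping_proportions_test(12, 20, 12, 20, overlap)
    assert result.p_value == 1.0 and result.z == 0.0


def test_monotone_in_difference_with_fixed_structure():
    n1 = n2 = 60
    overlap = [(True, True)] * 10 + [(False, False)] * 20
    p_values = []
    for x2 in (30, 25, 20):
        result = overlapping_proportions_test(30, n1, x2, n2, overlap)
        p_values.append(result.p_value)
    assert p_values[0] > p_values[1] > p_values[2]


def test_overlap_preconditions():
    with pytest.raises(ConsistencyError):
        overlapping_proportions_test(5, 4, 1, 10)
    with pytest.raises(ConsistencyError):
        overlapping_proportions_test(1, 2, 1, 10, overlap=[(True, True)] * 3)
    with pytest.raises(ConsistencyError):
        overlapping_proportions_test(1, 10, 1, 10, overlap=[(True, True), (True, False)])


def test_degenerate_variance_raises():
    overlap = [(True, False)] * 4
    with pytest.raises(DegenerateVarianceError):
        overlapping_proportions_test(4, 4, 0, 4, overlap)


def test_small_sample_warning_flag():
    assert overlapping_proportions_test(2, 30, 15, 30).small_sample_warning
    assert not overlapping_proportions_test(15, 40, 20, 40).small_sample_warning


def test_matches_paired_bootstrap_oracle_quickly():
    # smaller-scale version of the acceptance check
    rng = np.random.default_rng(2)
    m, k1, k2 = 31, 10, 22
    shared = np.column_stack([rng.random(m) < 0.7, rng.random(m) < 0.55])
    extra1 = (rng.random(k1) < 0.7).astype(int)
    extra2 = (rng.random(k2) < 0.55).astype(int)
    x1 = int(shared[:, 0].sum() + extra1.sum())
    x2 = int(shared[:, 1].sum() + extra2.sum())
    result = overlapping_proportions_test(
        x1, m + k1, x2, m + k2, [(bool(a), bool(b)) for a, b in shared]
    )
    p_boot = oracles.bootstrap_overlap_p(shared, extra1, extra2, n_boot=30_000, seed=9)
    assert result.p_value == pytest.approx(p_boot, abs=0.02)
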