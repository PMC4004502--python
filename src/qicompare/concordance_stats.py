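"""Cross-source agreement statistics for indicator selections.

``cross_classify`` tabulates a selection made on the reference (registry)
side against the same selection made on the test (EMR) side, over matched
pairs.  ``accuracy_stats`` derives sensitivity, specificity, predictive
values and likelihood ratios, with explicit undefined states for zero
denominators.  ``overlapping_proportions_test`` compares two proportions
whose samples share subjects, correcting the variance of the difference by
the covariance induced by the shared subjects.

Universe conventions (the sources never define them explicitly, so they are
fixed here and used consistently):

* positives on each side are that side's selection; reference positives
  drive sensitivity, test positives drive PPV;
* negatives on each side are the universe minus the selection; true
  negatives are matched pairs, inside both universes, selected by neither;
* specificity = TN / reference negatives; NPV = TN / test negatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import norm

from ._util import round_half_up
from .errors import ConsistencyError, DegenerateVarianceError
from .patient_matching import MatchResult


@dataclass(frozen=True)
class CrossTab:
    """Cross-classification of one indicator element across the two sources."""

    element_id: str
    tp: int          # selected in both sources (matched pairs)
    ref_only: int    # selected in the registry only
    test_only: int   # selected in the EMR only
    tn: int          # matched pairs in both universes, selected in neither
    n_ref: int       # registry universe size
    n_test: int      # EMR universe size

    def __post_init__(self) -> None:
        counts = (self.tp, self.ref_only, self.test_only, self.tn, self.n_ref, self.n_test)
        if any(c < 0 for c in counts):
            raise ConsistencyError(f"negative count in cross-tab: {self}")
        if self.tp + self.ref_only > self.n_ref or self.tp + self.test_only > self.n_test:
            raise ConsistencyError(f"selection exceeds universe: {self}")

    @property
    def ref_selected(self) -> int:
        return self.tp + self.ref_only

    @property
    def test_selected(self) -> int:
        return self.tp + self.test_only

    @property
    def ref_negatives(self) -> int:
        return self.n_ref - self.ref_selected

    @property
    def test_negatives(self) -> int:
        return self.n_test - self.test_selected


def cross_classify(
    reference_selected: Iterable[str],
    test_selected: Iterable[str],
    reference_universe: Iterable[str],
    test_universe: Iterable[str],
    matches: MatchResult,
    element_id: str = "",
) -> CrossTab:
    """Tabulate a paired selection over matched patients."""
    ref_sel, test_sel = set(reference_selected), set(test_selected)
    ref_uni, test_uni = set(reference_universe), set(test_universe)
    if not ref_sel <= ref_uni:
        raise ConsistencyError("reference selection is not a subset of its universe")
    if not test_sel <= test_uni:
        raise ConsistencyError("test selection is not a subset of its universe")
    tp = tn = 0
    for r, e in matches.matched_pairs:
        if r in ref_sel and e in test_sel:
            tp += 1
        elif r in ref_uni and e in test_uni and r not in ref_sel and e not in test_sel:
            tn += 1
    return CrossTab(
        element_id=element_id,
        tp=tp,
        ref_only=len(ref_sel) - tp,
        test_only=len(test_sel) - tp,
        tn=tn,
        n_ref=len(ref_uni),
        n_test=len(test_uni),
    )


@dataclass(frozen=True)
class AccuracyStats:
    """Diagnostic-accuracy statistics with explicit undefined states.

    Each proportion is ``None`` when its denominator is zero; ``fractions``
    retains the numerator/denominator pair behind every defined statistic.
    """

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    plr: float | None
    nlr: float | None
    fractions: dict[str, tuple[int, int]]


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def accuracy_stats(crosstab: CrossTab) -> AccuracyStats:
    """Sensitivity/specificity/PPV/NPV/PLR/NLR from a cross-tab."""
    ct = crosstab
    sens = _ratio(ct.tp, ct.ref_selected)
    spec = _ratio(ct.tn, ct.ref_negatives)
    ppv = _ratio(ct.tp, ct.test_selected)
    npv = _ratio(ct.tn, ct.test_negatives)
    plr = sens / (1.0 - spec) if sens is not None and spec is not None and spec < 1 else None
    nlr = (1.0 - sens) / spec if sens is not None and spec is not None and spec > 0 else None
    return AccuracyStats(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        plr=plr,
        nlr=nlr,
        fractions={
            "sensitivity": (ct.tp, ct.ref_selected),
            "specificity": (ct.tn, ct.ref_negatives),
            "ppv": (ct.tp, ct.test_selected),
            "npv": (ct.tn, ct.test_negatives),
        },
    )


def likelihood_ratios_from_rounded(stats: AccuracyStats) -> tuple[float | None, float | None]:
    """PLR/NLR recomputed from the integer-percent rounded sensitivity and
    specificity, i.e. from the numbers a report table prints rather than the
    exact ratios.  Published tables are commonly derived this way, so this
    variant is what reproduces them."""
    if stats.sensitivity is None or stats.specificity is None:
        return None, None
    sens = round_half_up(100 * stats.sensitivity) / 100.0
    spec = round_half_up(100 * stats.specificity) / 100.0
    plr = sens / (1.0 - spec) if spec < 1 else None
    nlr = (1.0 - sens) / spec if spec > 0 else None
    return plr, nlr


@dataclass(frozen=True)
class OverlapTestResult:
    """Outcome of the overlapping-samples two-proportion z-test."""

    p1: float
    p2: float
    n1: int
    n2: int
    m: int
    q1: float
    q2: float
    q11: float
    covariance: float
    standard_error: float
    z: float
    p_value: float
    small_sample_warning: bool = False


def overlapping_proportions_test(
    x1: int,
    n1: int,
    x2: int,
    n2: int,
    overlap: Sequence[tuple[bool, bool]] = (),
) -> OverlapTestResult:
    """Compare ``x1/n1`` with ``x2/n2`` when the samples share subjects.

    ``overlap`` lists, for each of the ``m`` shared subjects, the pair of
    outcomes (positive on measure 1, positive on measure 2).  The covariance
    of the two estimated proportions is ``m * (q11 - q1*q2) / (n1*n2)`` with
    ``q1``, ``q2``, ``q11`` the within-overlap proportions positive on
    measure 1, on measure 2, and on both.  At ``m == 0`` this reduces to the
    ordinary unpooled two-proportion z-test.
    """
    m = len(overlap)
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ConsistencyError("successes must lie in [0, n]")
    if n1 == 0 or n2 == 0:
        raise ConsistencyError("sample sizes must be positive")
    if m > min(n1, n2):
        raise ConsistencyError("overlap larger than a sample")
    if sum(a for a, _ in overlap) > x1 or sum(b for _, b in overlap) > x2:
        raise ConsistencyError("overlap outcomes exceed the reported successes")

    p1, p2 = x1 / n1, x2 / n2
    if m:
        q1 = sum(a for a, _ in overlap) / m
        q2 = sum(b for _, b in overlap) / m
        q11 = sum(a and b for a, b in overlap) / m
    else:
        q1 = q2 = q11 = 0.0
    covariance = m * (q11 - q1 * q2) / (n1 * n2)
    variance = p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2 - 2 * covariance
    variance = max(variance, 0.0)

    small = min(
        x1, n1 - x1, x2, n2 - x2
    ) < 5  # normal approximation unreliable for sparse cells

    if variance == 0.0:
        if p1 != p2:
            raise DegenerateVarianceError(
                f"zero variance with differing proportions ({p1} vs {p2})"
            )
        z, p_value = 0.0, 1.0
    else:
        se = math.sqrt(variance)
        z = (p1 - p2) / se
        p_value = 2.0 * norm.sf(abs(z))
        return OverlapTestResult(
            p1=p1, p2=p2, n1=n1, n2=n2, m=m, q1=q1, q2=q2, q11=q11,
            covariance=covariance, standard_error=se, z=z, p_value=p_value,
            small_sample_warning=small,
        )
    return OverlapTestResult(
        p1=p1, p2=p2, n1=n1, n2=n2, m=m, q1=q1, q2=q2, q11=q11,
        covariance=covariance, standard_error=0.0, z=z, p_value=p_value,
        small_sample_warning=small,
    )
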