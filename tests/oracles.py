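"""Independent reference implementations used as test oracles.

These deliberately re-derive results through a different route than the
package (naive per-record loops, exhaustive enumeration, bootstrap
simulation) so that agreement is evidence, not tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import norm

from qicompare.records import Status

# --- three-valued predicate evaluation (True / False / None) -----------------


def kleene_eval(record, node, strict=False):
    if "all" in node:
        vals = [kleene_eval(record, c, strict) for c in node["all"]]
        if False in vals:
            return False
        if None in vals:
            return None
        return True
    if "any" in node:
        vals = [kleene_eval(record, c, strict) for c in node["any"]]
        if True in vals:
            return True
        if None in vals:
            return None
        return False
    if "not" in node:
        v = kleene_eval(record, node["not"], strict)
        return None if v is None else (not v)
    op = node["op"]
    if op in ("age_lt", "age_ge"):
        opdate, s1 = record.get("operation_date")
        yob, s2 = record.get("year_of_birth")
        if s1 is not Status.PRESENT or s2 is not Status.PRESENT:
            return None
        age = opdate.year - yob
        return age < node["value"] if op == "age_lt" else age >= node["value"]
    value, status = record.get(node["item"], node.get("field"))
    if status is not Status.PRESENT:
        if not strict and node.get("absent_as") == "false" and status is Status.ABSENT:
            return False
        return None
    if op in ("before_item", "on_or_before_item", "after_item"):
        other, os = record.get(node["other"]["item"], node["other"].get("field"))
        if os is not Status.PRESENT:
            return None
        return {"before_item": value < other,
                "on_or_before_item": value <= other,
                "after_item": value > other}[op]
    t = node.get("value")
    return {
        "eq": lambda: value == t,
        "ne": lambda: value != t,
        "ge": lambda: value >= t,
        "gt": lambda: value > t,
        "le": lambda: value <= t,
        "lt": lambda: value < t,
        "in": lambda: value in t,
        "is_true": lambda: bool(value),
        "is_false": lambda: not bool(value),
        "intersects": lambda: bool(set(value) & set(t)),
    }[op]()


def and3(a, b):
    if a is False or b is False:
        return False
    if a is None or b is None:
        return None
    return True


def not3(a):
    return None if a is None else (not a)


def naive_member(record, definition, element, strict=False):
    """True iff the record belongs to the element, by direct evaluation."""
    den = kleene_eval(record, definition.denominator_predicate, strict)
    excl = (
        kleene_eval(record, definition.exclusion_predicate, strict)
        if definition.exclusion_predicate is not None
        else False
    )
    member = and3(den, not3(excl))
    if element == "denominator":
        return member is True
    num = kleene_eval(record, definition.numerator_predicate, strict)
    return and3(member, num) is True


def naive_select(dataset, definition, element, strict=False):
    return {
        r.patient_id for r in dataset if naive_member(r, definition, element, strict)
    }


# --- matching ----------------------------------------------------------------


def jaccard(a, b):
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def block_optimum(reg_procs, emr_procs):
    """(max cardinality, max total Jaccard, list of optimal pair-sets).

    ``reg_procs`` / ``emr_procs``: dict id -> frozenset of procedure codes.
    Exhaustive over permutations.
    """
    reg_ids, emr_ids = sorted(reg_procs), sorted(emr_procs)
    k = min(len(reg_ids), len(emr_ids))
    best, optima = -1.0, []
    for subset in itertools.combinations(emr_ids, k):
        for perm in itertools.permutations(subset):
            pairs = frozenset(zip(reg_ids[:k], perm)) if len(reg_ids) <= len(emr_ids) else None
            if pairs is None:
                break
            w = sum(jaccard(reg_procs[r], emr_procs[e]) for r, e in pairs)
            if w > best + 1e-12:
                best, optima = w, [pairs]
            elif abs(w - best) <= 1e-12:
                optima.append(pairs)
    if len(reg_ids) > len(emr_ids):
        for subset in itertools.combinations(reg_ids, k):
            for perm in itertools.permutations(subset):
                pairs = frozenset(zip(perm, emr_ids))
                w = sum(jaccard(reg_procs[r], emr_procs[e]) for r, e in pairs)
                if w > best + 1e-12:
                    best, optima = w, [pairs]
                elif abs(w - best) <= 1e-12:
                    optima.append(pairs)
    return k, best, optima


# --- proportions -------------------------------------------------------------


def unpooled_two_proportion_z(x1, n1, x2, n2):
    p1, p2 = x1 / n1, x2 / n2
    var = p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2
    if var == 0:
        return 0.0, 1.0
    z = (p1 - p2) / math.sqrt(var)
    return z, 2 * norm.sf(abs(z))


def bootstrap_overlap_p(shared, extra1, extra2, n_boot=100_000, seed=0):
    """Paired-bootstrap p-value for the difference of overlapping proportions.

    ``shared``: (m, 2) array of paired 0/1 outcomes; ``extra1``/``extra2``:
    1-d arrays of the non-shared outcomes of each sample.  The bootstrap
    standard error of p1 - p2 feeds a normal two-sided p-value.
    """
    rng = np.random.default_rng(seed)
    shared = np.asarray(shared)
    extra1, extra2 = np.asarray(extra1), np.asarray(extra2)
    m, k1, k2 = len(shared), len(extra1), len(extra2)
    n1, n2 = m + k1, m + k2
    p1 = (shared[:, 0].sum() + extra1.sum()) / n1
    p2 = (shared[:, 1].sum() + extra2.sum()) / n2
    idx_s = rng.integers(0, m, size=(n_boot, m))
    s1 = shared[:, 0][idx_s].sum(axis=1)
    s2 = shared[:, 1][idx_s].sum(axis=1)
    if k1:
        s1 = s1 + extra1[rng.integers(0, k1, size=(n_boot, k1))].sum(axis=1)
    if k2:
        s2 = s2 + extra2[rng.integers(0, k2, size=(n_boot, k2))].sum(axis=1)
    diffs = s1 / n1 - s2 / n2
    se = diffs.std(ddof=1)
    if se == 0:
        return 1.0
    z = (p1 - p2) / se
    return 2 * norm.sf(abs(z))
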