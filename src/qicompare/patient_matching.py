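"""Deterministic cross-source record linkage without shared identifiers.

Patients are blocked on the primary key (gender, year of birth, operation
date); within a block the assignment maximising first the number of pairs
and then the total Jaccard similarity of procedure-code sets is chosen.
When several optimal assignments exist, records whose alternative partners
carry identical procedure sets are genuinely indistinguishable and are
reported as an ambiguous candidate group (and counted unmatched); remaining
ties are broken lexicographically so output is independent of input order.
"""

from __future__ import annotations

import datetime as dt
import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

from .records import PatientRecord, Status

logger = logging.getLogger(__name__)

_MAX_EXHAUSTIVE = 9  # block side size above which enumeration is abandoned


@dataclass
class MatchResult:
    matched_pairs: frozenset[tuple[str, str]]
    unmatched_registry: frozenset[str]
    unmatched_emr: frozenset[str]
    ambiguous: tuple[dict, ...] = ()
    #: patient id -> reason it could not be matched
    reasons: dict[str, str] = field(default_factory=dict)

    @property
    def registry_to_emr(self) -> dict[str, str]:
        return {r: e for r, e in self.matched_pairs}

    @property
    def emr_to_registry(self) -> dict[str, str]:
        return {e: r for r, e in self.matched_pairs}

    def to_dict(self) -> dict:
        return {
            "matched_pairs": sorted(self.matched_pairs),
            "unmatched_registry": sorted(self.unmatched_registry),
            "unmatched_emr": sorted(self.unmatched_emr),
            "ambiguous": list(self.ambiguous),
            "reasons": dict(sorted(self.reasons.items())),
        }


def _match_key(record: PatientRecord) -> tuple[str, int, dt.date] | None:
    yob = record.year_of_birth
    opdate = record.operation_date
    if record.gender in ("male", "female") and yob is not None and opdate is not None:
        return record.gender, yob, opdate
    return None


def _procedures(record: PatientRecord) -> frozenset[str]:
    div = record.items["procedure"]
    if div.status is Status.PRESENT:
        return frozenset(div.value)
    return frozenset()


def jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def _enumerate_optimal(
    reg_ids: Sequence[str], emr_ids: Sequence[str], weights: dict[tuple[str, str], float]
) -> list[frozenset[tuple[str, str]]]:
    """All maximum-cardinality assignments with maximal total Jaccard weight."""
    k = min(len(reg_ids), len(emr_ids))
    best_weight = -1.0
    optima: list[frozenset[tuple[str, str]]] = []
    smaller, larger, flip = (
        (reg_ids, emr_ids, False) if len(reg_ids) <= len(emr_ids) else (emr_ids, reg_ids, True)
    )
    for subset in itertools.combinations(larger, k):
        for perm in itertools.permutations(subset):
            if flip:
                pairs = frozenset(zip(perm, smaller))
            else:
                pairs = frozenset(zip(smaller, perm))
            w = sum(weights[p] for p in pairs)
            if w > best_weight + 1e-12:
                best_weight = w
                optima = [pairs]
            elif abs(w - best_weight) <= 1e-12:
                optima.append(pairs)
    return optima


def _canonical_key(pairs: frozenset[tuple[str, str]]) -> tuple:
    # symmetric under swapping the two sides
    return tuple(sorted(tuple(sorted(p)) for p in pairs))


def _resolve_block(
    reg_records: list[PatientRecord], emr_records: list[PatientRecord]
) -> tuple[set[tuple[str, str]], list[dict]]:
    reg_ids = sorted(r.patient_id for r in reg_records)
    emr_ids = sorted(e.patient_id for e in emr_records)
    if len(reg_ids) == 1 and len(emr_ids) == 1:
        return {(reg_ids[0], emr_ids[0])}, []

    procs = {r.patient_id: _procedures(r) for r in reg_records + emr_records}
    weights = {(r, e): jaccard(procs[r], procs[e]) for r in reg_ids for e in emr_ids}

    if max(len(reg_ids), len(emr_ids)) > _MAX_EXHAUSTIVE:
        # degenerate cohort: greedy best-first fallback, logged
        logger.warning(
            "key block with %d x %d candidates; falling back to greedy matching",
            len(reg_ids),
            len(emr_ids),
        )
        pairs: set[tuple[str, str]] = set()
        free_r, free_e = set(reg_ids), set(emr_ids)
        for (r, e), _w in sorted(weights.items(), key=lambda kv: (-kv[1], kv[0])):
            if r in free_r and e in free_e:
                pairs.add((r, e))
                free_r.discard(r)
                free_e.discard(e)
        return pairs, []

    optima = _enumerate_optimal(reg_ids, emr_ids, weights)
    if len(optima) == 1:
        return set(optima[0]), []

    reg_partners: dict[str, set[str]] = {r: set() for r in reg_ids}
    emr_partners: dict[str, set[str]] = {e: set() for e in emr_ids}
    for assignment in optima:
        for r, e in assignment:
            reg_partners[r].add(e)
            emr_partners[e].add(r)

    def indistinguishable(alternatives: set[str]) -> bool:
        return len(alternatives) > 1 and len({procs[a] for a in alternatives}) == 1

    chosen = min(optima, key=_canonical_key)
    pairs, ambiguous_reg, ambiguous_emr = set(), set(), set()
    for r, e in chosen:
        if indistinguishable(reg_partners[r]) or indistinguishable(emr_partners[e]):
            # indistinguishable candidates: never silently assigned
            ambiguous_reg.update(emr_partners[e])
            ambiguous_emr.update(reg_partners[r])
        else:
            pairs.add((r, e))
    groups = []
    if ambiguous_reg:
        groups.append({"registry": sorted(ambiguous_reg), "emr": sorted(ambiguous_emr)})
    return pairs, groups


def match_patients(
    registry_dataset: Sequence[PatientRecord],
    emr_dataset: Sequence[PatientRecord],
    date_window: int = 0,
) -> MatchResult:
    """Match registry against EMR records.

    ``date_window`` relaxes the operation-date component of the key to a
    ±``date_window``-day tolerance (0 = exact, the default).
    """
    reasons: dict[str, str] = {}
    reg_keyed: dict[tuple, list[PatientRecord]] = {}
    emr_keyed: dict[tuple, list[PatientRecord]] = {}
    for dataset, keyed in ((registry_dataset, reg_keyed), (emr_dataset, emr_keyed)):
        for record in dataset:
            key = _match_key(record)
            if key is None:
                reasons[record.patient_id] = "missing_key_fields"
                logger.info("patient %s lacks key fields; unmatched", record.patient_id)
            else:
                keyed.setdefault(key, []).append(record)

    # blocks: exact keys, or (gender, yob) keys whose dates fall within the
    # window, merged transitively
    pairs: set[tuple[str, str]] = set()
    ambiguous: list[dict] = []
    if date_window == 0:
        for key in sorted(set(reg_keyed) & set(emr_keyed), key=str):
            block_pairs, block_amb = _resolve_block(reg_keyed[key], emr_keyed[key])
            pairs |= block_pairs
            ambiguous.extend(block_amb)
    else:
        merged: dict[tuple, tuple[list, list]] = {}
        for (g, y, d), recs in reg_keyed.items():
            merged.setdefault((g, y), ([], []))[0].extend(recs)
        for (g, y, d), recs in emr_keyed.items():
            merged.setdefault((g, y), ([], []))[1].extend(recs)
        for gy in sorted(merged, key=str):
            reg_recs, emr_recs = merged[gy]
            # drop cross-pairs whose dates disagree beyond the window by
            # clustering on registry dates
            eligible_emr = [
                e
                for e in emr_recs
                if any(
                    abs((e.operation_date - r.operation_date).days) <= date_window
                    for r in reg_recs
                )
            ]
            if reg_recs and eligible_emr:
                block_pairs, block_amb = _resolve_block(reg_recs, eligible_emr)
                block_pairs = {
                    (r, e)
                    for r, e in block_pairs
                    if abs(
                        (
                            next(x.operation_date for x in emr_recs if x.patient_id == e)
                            - next(x.operation_date for x in reg_recs if x.patient_id == r)
                        ).days
                    )
                    <= date_window
                }
                pairs |= block_pairs
                ambiguous.extend(block_amb)

    matched_reg = {r for r, _ in pairs}
    matched_emr = {e for _, e in pairs}
    unmatched_reg = {r.patient_id for r in registry_dataset} - matched_reg
    unmatched_emr = {e.patient_id for e in emr_dataset} - matched_emr
    for group in ambiguous:
        for rid in group["registry"]:
            reasons.setdefault(rid, "ambiguous_candidates")
        for eid in group["emr"]:
            if eid in unmatched_emr:
                reasons.setdefault(eid, "ambiguous_candidates")
    for pid in sorted(unmatched_reg | unmatched_emr):
        reasons.setdefault(pid, "no_key_counterpart")
    return MatchResult(
        matched_pairs=frozenset(pairs),
        unmatched_registry=frozenset(unmatched_reg),
        unmatched_emr=frozenset(unmatched_emr),
        ambiguous=tuple(ambiguous),
        reasons=reasons,
    )
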