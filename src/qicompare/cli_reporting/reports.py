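"""CSV report writers shaped like the published summary tables."""

from __future__ import annotations

import csv
from pathlib import Path
from typing import TYPE_CHECKING

from .._util import round_half_up

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import ReportBundle

UNDEFINED = "-"


def _fmt_number(value: float | None, locale: str, ndigits: int = 2) -> str:
    if value is None:
        return UNDEFINED
    text = f"{round_half_up(value, ndigits):.{ndigits}f}"
    return text.replace(".", ",") if locale == "comma" else text


def _fmt_pct(value: float | None, num: int | None = None, den: int | None = None) -> str:
    if value is None:
        return UNDEFINED if num is None or den is None else f"{UNDEFINED} ({num}/{den})"
    text = f"{round_half_up(value):.0f}%"
    if num is not None and den is not None:
        text += f" ({num}/{den})"
    return text


def write_indicator_table(bundle: "ReportBundle", path: Path, locale: str = "point") -> None:
    rows = []
    for definition in bundle.indicator_set:
        rr = bundle.registry_results[definition.id]
        er = bundle.emr_results[definition.id]
        element_id = f"{definition.id}.numerator"
        stats = bundle.accuracy.get(element_id)
        test = bundle.overlap_tests.get(definition.id)

        def source_cell(result):
            if result.kind == "count":
                return str(result.denominator.count) if result.denominator.computable else UNDEFINED
            num = result.numerator.count if result.numerator.computable else UNDEFINED
            den = result.denominator.count if result.denominator.computable else UNDEFINED
            if result.percentage is None:
                return f"({num}/{den})"
            return f"{round_half_up(result.percentage):.0f}% ({num}/{den})"

        row = {
            "indicator": definition.id,
            "kind": definition.kind,
            "title": definition.title,
            "registry": source_cell(rr),
            "emr": source_cell(er),
            "registry_computable": f"{rr.numerator.computable}/{rr.denominator.computable}",
            "emr_computable": f"{er.numerator.computable}/{er.denominator.computable}",
        }
        if stats is not None:
            f = stats.fractions

            def scale(v):
                return None if v is None else 100 * v

            row.update(
                sensitivity=_fmt_pct(scale(stats.sensitivity), *f["sensitivity"]),
                specificity=_fmt_pct(scale(stats.specificity), *f["specificity"]),
                ppv=_fmt_pct(scale(stats.ppv), *f["ppv"]),
                npv=_fmt_pct(scale(stats.npv), *f["npv"]),
                plr=_fmt_number(stats.plr, locale),
                nlr=_fmt_number(stats.nlr, locale),
            )
        else:
            row.update(sensitivity=UNDEFINED, specificity=UNDEFINED, ppv=UNDEFINED,
                       npv=UNDEFINED, plr=UNDEFINED, nlr=UNDEFINED)
        row["p_value"] = _fmt_number(test.p_value, locale, 4) if test else UNDEFINED
        rows.append(row)
    _write_csv(path, rows)


def write_crosstab_table(bundle: "ReportBundle", path: Path) -> None:
    rows = [
        {
            "element": element_id,
            "registry_selected": ct.ref_selected,
            "emr_selected": ct.test_selected,
            "tp_both": ct.tp,
            "registry_only": ct.ref_only,
            "emr_only": ct.test_only,
            "tn_neither": ct.tn,
            "registry_universe": ct.n_ref,
            "emr_universe": ct.n_test,
        }
        for element_id, ct in sorted(bundle.crosstabs.items())
    ]
    _write_csv(path, rows)


def write_quality_table(bundle: "ReportBundle", path: Path) -> None:
    rows = []
    for item, iq in bundle.quality.items.items():
        creg, cemr, corr = iq.completeness_registry, iq.completeness_emr, iq.correctness
        rows.append(
            {
                "item": item,
                "universally_applicable": iq.universal,
                "available_registry": iq.available_registry,
                "available_emr": iq.available_emr,
                "completeness_registry": _fmt_pct(creg.percentage, creg.numerator, creg.denominator),
                "completeness_emr": _fmt_pct(cemr.percentage, cemr.numerator, cemr.denominator),
                "correctness": _fmt_pct(corr.percentage, corr.numerator, corr.denominator)
                if corr.defined
                else UNDEFINED,
            }
        )
    averages = bundle.quality.averages
    rows.append(
        {
            "item": "average_of_applicable_items",
            "universally_applicable": "",
            "available_registry": "",
            "available_emr": "",
            "completeness_registry": _fmt_pct(averages["completeness_registry"]),
            "completeness_emr": _fmt_pct(averages["completeness_emr"]),
            "correctness": _fmt_pct(averages["correctness"]),
        }
    )
    _write_csv(path, rows)


def write_flow_summary(bundle: "ReportBundle", path: Path) -> None:
    matches = bundle.matches
    reasons = matches.reasons
    rows = [
        {"step": "included_registry", "count": len(bundle.registry)},
        {"step": "included_emr", "count": len(bundle.emr)},
        {"step": "matched_pairs", "count": len(matches.matched_pairs)},
        {"step": "unmatched_registry", "count": len(matches.unmatched_registry)},
        {"step": "unmatched_emr", "count": len(matches.unmatched_emr)},
        {"step": "ambiguous_groups", "count": len(matches.ambiguous)},
    ]
    for reason in sorted({r for r in reasons.values()}):
        rows.append(
            {
                "step": f"unmatched_reason:{reason}",
                "count": sum(1 for v in reasons.values() if v == reason),
            }
        )
    # EMR patients matched to the registry that the denominator query of the
    # registry-submission indicator still does not select
    element = bundle.emr_results.get("1")
    if element is not None and element.denominator.computable:
        selected = element.denominator.selected
        matched_emr = {e for _, e in matches.matched_pairs}
        rows.append(
            {"step": "matched_and_query_selected", "count": len(matched_emr & selected)}
        )
        rows.append(
            {"step": "matched_not_query_selected", "count": len(matched_emr - selected)}
        )
    _write_csv(path, rows)


def write_problems_log(bundle: "ReportBundle", path: Path) -> None:
    _write_csv(path, bundle.problems or [{"category": "", "detail": ""}])


def _write_csv(path: Path, rows: list[dict]) -> None:
    fieldnames = list(rows[0].keys()) if rows else []
    with open(path, "w", newline="") as handle:
        writer = csv.DictWriter(handle, fieldnames=fieldnames)
        writer.writeheader()
        writer.writerows(rows)
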