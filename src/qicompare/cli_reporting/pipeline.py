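"""End-to-end orchestration: load or generate data, match, evaluate, report."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .. import __version__
from ..concordance_stats import (
    AccuracyStats,
    CrossTab,
    OverlapTestResult,
    accuracy_stats,
    cross_classify,
    likelihood_ratios_from_rounded,
    overlapping_proportions_test,
)
from ..data_quality import QualityReport, quality_report
from ..errors import ConfigurationError
from ..indicator_engine import (
    IndicatorResult,
    IndicatorSet,
    compute_indicator,
    harmonise_urgency,
    load_code_lists,
    load_definitions,
    select_patients,
)
from ..io import read_dataset
from ..patient_matching import MatchResult, match_patients
from ..records import PatientRecord, Status
from ..synthetic_data import GeneratorConfig, generate_paired_cohort
from . import reports


class PipelineConfig(BaseModel):
    """Validated configuration of a full pipeline run."""

    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    registry_path: str | None = None
    emr_path: str | None = None
    generator: GeneratorConfig | None = None
    indicators_path: str | None = None
    code_lists_path: str | None = None
    output_dir: str = "qicompare_out"
    significance_level: float = Field(default=0.05, gt=0.0, lt=1.0)
    strict_exclusions: bool = False
    indicator7_require_resection: bool = False
    date_window: int = Field(default=0, ge=0)
    locale: str = "point"  # "point" | "comma"
    seed: int | None = None

    @model_validator(mode="after")
    def _exactly_one_input(self):
        has_paths = self.registry_path is not None and self.emr_path is not None
        if has_paths == (self.generator is not None):
            raise ValueError(
                "supply exactly one of (registry_path+emr_path) or a generator config"
            )
        if self.locale not in ("point", "comma"):
            raise ValueError(f"unknown locale {self.locale!r}")
        return self


@dataclass
class ReportBundle:
    """All artefacts of one run, before serialisation."""

    config: PipelineConfig
    indicator_set: IndicatorSet
    registry: list[PatientRecord]
    emr: list[PatientRecord]
    matches: MatchResult
    registry_results: dict[str, IndicatorResult]
    emr_results: dict[str, IndicatorResult]
    crosstabs: dict[str, CrossTab]
    accuracy: dict[str, AccuracyStats]
    overlap_tests: dict[str, OverlapTestResult]
    quality: QualityReport
    problems: list[dict[str, str]] = field(default_factory=list)
    unmapped_urgency: list[str] = field(default_factory=list)


def _load_inputs(config: PipelineConfig) -> tuple[list[PatientRecord], list[PatientRecord]]:
    if config.generator is not None:
        generator_config = config.generator
        if config.seed is not None:
            generator_config = generator_config.model_copy(update={"seed": config.seed})
        registry, emr, _ = generate_paired_cohort(generator_config)
        return registry, emr
    try:
        registry = read_dataset(config.registry_path)
    except (OSError, ValueError, KeyError) as exc:
        raise ConfigurationError(f"cannot read registry dataset {config.registry_path}: {exc}") from exc
    try:
        emr = read_dataset(config.emr_path)
    except (OSError, ValueError, KeyError) as exc:
        raise ConfigurationError(f"cannot read EMR dataset {config.emr_path}: {exc}") from exc
    return registry, emr


def _collect_problems(bundle: ReportBundle) -> list[dict[str, str]]:
    """Bin observed data-quality problems into the standard categories."""
    problems: list[dict[str, str]] = []

    def add(category: str, detail: str) -> None:
        problems.append({"category": category, "detail": detail})

    for item, iq in bundle.quality.items.items():
        if not iq.available_emr:
            add("data_not_available_in_structured_format", f"EMR item {item} is free text only")
        if not iq.available_registry:
            add("data_not_available_in_structured_format", f"registry item {item} is free text only")
        if iq.correctness.defined and iq.correctness.numerator < iq.correctness.denominator:
            bad = iq.correctness.denominator - iq.correctness.numerator
            add("incorrect_data_items", f"{item}: {bad} effect-inconsistent pair(s)")
    emr_by_id = {r.patient_id: r for r in bundle.emr}
    for _rid, eid in sorted(bundle.matches.matched_pairs):
        record = emr_by_id[eid]
        diag = record.items["diagnosis"]
        op = record.operation_date
        if diag.present and op is not None:
            date = diag.value.get("date")
            if date is not None and date > op:
                add(
                    "lack_of_relations_between_data_items",
                    f"{eid}: diagnosis date after operation date",
                )
            if diag.value.get("location") not in ("colon", "rectum", "rectosigmoid"):
                add("lack_of_detail", f"{eid}: imprecise diagnosis code")
    for pid in bundle.unmapped_urgency:
        add("lack_of_standardisation", f"{pid}: unmapped operation-urgency category")
    for group in bundle.matches.ambiguous:
        add(
            "incomplete_view_of_patient_history",
            f"ambiguous match candidates: registry {group['registry']} / emr {group['emr']}",
        )
    for pid, reason in sorted(bundle.matches.reasons.items()):
        if reason == "missing_key_fields":
            add("incorrect_data_items", f"{pid}: missing matching key fields")
    return problems


def run_pipeline(config: PipelineConfig, write: bool = True) -> ReportBundle:
    """Execute the full comparison pipeline; optionally write the bundle."""
    indicator_set = load_definitions(
        config.indicators_path,
        code_lists=load_code_lists(config.code_lists_path) if config.code_lists_path else None,
        indicator7_require_resection=config.indicator7_require_resection,
    )
    registry, emr = _load_inputs(config)
    code_lists = load_code_lists(config.code_lists_path)
    emr, unmapped = harmonise_urgency(emr, code_lists.get("urgency_mapping", {}))

    matches = match_patients(registry, emr, date_window=config.date_window)

    registry_results = {
        d.id: compute_indicator(registry, d, config.strict_exclusions) for d in indicator_set
    }
    emr_results = {
        d.id: compute_indicator(emr, d, config.strict_exclusions) for d in indicator_set
    }

    crosstabs: dict[str, CrossTab] = {}
    accuracy: dict[str, AccuracyStats] = {}
    overlap_tests: dict[str, OverlapTestResult] = {}
    all_reg = frozenset(r.patient_id for r in registry)
    all_emr = frozenset(e.patient_id for e in emr)
    for definition in indicator_set:
        rr, er = registry_results[definition.id], emr_results[definition.id]
        if rr.denominator.computable and er.denominator.computable:
            element_id = f"{definition.id}.denominator"
            crosstabs[element_id] = cross_classify(
                rr.denominator.selected, er.denominator.selected,
                all_reg, all_emr, matches, element_id,
            )
        if not (rr.numerator.computable and er.numerator.computable):
            continue
        element_id = f"{definition.id}.numerator"
        ct = cross_classify(
            rr.numerator.selected, er.numerator.selected,
            rr.denominator.selected, er.denominator.selected, matches, element_id,
        )
        crosstabs[element_id] = ct
        accuracy[element_id] = accuracy_stats(ct)
        # overlapping-samples comparison of the two percentages
        n1, n2 = len(rr.denominator.selected), len(er.denominator.selected)
        if n1 and n2:
            emr_of_reg = matches.registry_to_emr
            overlap = [
                (rid in rr.numerator.selected, emr_of_reg[rid] in er.numerator.selected)
                for rid in sorted(rr.denominator.selected)
                if emr_of_reg.get(rid) in er.denominator.selected
            ]
            overlap_tests[definition.id] = overlapping_proportions_test(
                len(rr.numerator.selected), n1, len(er.numerator.selected), n2, overlap
            )

    reg_by_id = {r.patient_id: r for r in registry}
    emr_by_id = {e.patient_id: e for e in emr}
    pairs = [
        (reg_by_id[rid], emr_by_id[eid]) for rid, eid in sorted(matches.matched_pairs)
    ]
    quality = quality_report(registry, emr, pairs)

    bundle = ReportBundle(
        config=config,
        indicator_set=indicator_set,
        registry=registry,
        emr=emr,
        matches=matches,
        registry_results=registry_results,
        emr_results=emr_results,
        crosstabs=crosstabs,
        accuracy=accuracy,
        overlap_tests=overlap_tests,
        quality=quality,
        unmapped_urgency=unmapped,
    )
    bundle.problems = _collect_problems(bundle)
    if write:
        write_bundle(bundle)
    return bundle


def write_bundle(bundle: ReportBundle) -> Path:
    """Serialise every artefact of a run into the configured output directory."""
    out = Path(bundle.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    locale = bundle.config.locale
    reports.write_indicator_table(bundle, out / "table_indicators.csv", locale)
    reports.write_crosstab_table(bundle, out / "table_crosstabs.csv")
    reports.write_quality_table(bundle, out / "table_data_quality.csv")
    reports.write_flow_summary(bundle, out / "matching_flow.csv")
    reports.write_problems_log(bundle, out / "problems_log.csv")
    (out / "match_result.json").write_text(
        json.dumps(bundle.matches.to_dict(), indent=1) + "\n"
    )
    config_dump = json.loads(bundle.config.model_dump_json())
    config_dump.pop("output_dir", None)  # keep re-runs byte-identical across dirs
    manifest: dict[str, Any] = {
        "package": "qicompare",
        "version": __version__,
        "config": config_dump,
        "n_registry": len(bundle.registry),
        "n_emr": len(bundle.emr),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return out
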