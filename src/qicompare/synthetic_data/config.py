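"""Generator configuration with schema validation."""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from ..errors import ConfigurationError, EmptyCohortError
from ..records import ITEM_NAMES

_PROB = Field(ge=0.0, le=1.0)


class AnomalyRates(BaseModel):
    """Per-patient probabilities of EMR extraction anomalies."""

    model_config = ConfigDict(extra="forbid")

    missing_diagnosis: float = _PROB
    diagnosis_after_operation: float = _PROB
    imprecise_code: float = _PROB
    wrong_procedure_class: float = _PROB

    def __init__(self, **data):  # defaults of 0 for all rates
        for k in ("missing_diagnosis", "diagnosis_after_operation",
                  "imprecise_code", "wrong_procedure_class"):
            data.setdefault(k, 0.0)
        super().__init__(**data)


class SourceRates(BaseModel):
    """A probability per source."""

    model_config = ConfigDict(extra="forbid")

    registry: float = Field(default=1.0, ge=0.0, le=1.0)
    emr: float = Field(default=1.0, ge=0.0, le=1.0)


class GeneratorConfig(BaseModel):
    """Everything that controls a paired-cohort draw.

    Identical config + seed produce byte-identical datasets.
    """

    model_config = ConfigDict(extra="forbid")

    n_patients: int = Field(ge=1)
    seed: int = 0
    registry_coverage: float = Field(default=1.0, ge=0.0, le=1.0)
    emr_extract_noise: AnomalyRates = Field(default_factory=AnomalyRates)
    #: item -> per-source probability that the value is recorded at all
    per_item_completeness: dict[str, SourceRates] = Field(default_factory=dict)
    #: item -> probability that the EMR value is effect-inconsistent
    per_item_error: dict[str, float] = Field(default_factory=dict)
    #: item -> probability that the registry value is effect-inconsistent
    registry_item_error: dict[str, float] = Field(default_factory=dict)
    #: items stored only as free text in the EMR
    unstructured_items: set[str] = Field(default_factory=set)
    #: share of the missingness mass recorded as explicit 'unknown'
    unknown_fraction: float = Field(default=0.2, ge=0.0, le=1.0)
    #: vocabulary the generated EMR urgency uses before harmonisation
    emr_urgency_vocabulary: str = "registry"
    reporting_year: int = 2011

    @field_validator("per_item_completeness", "per_item_error",
                     "registry_item_error", "unstructured_items")
    @classmethod
    def _known_items(cls, v):
        bad = sorted(set(v) - set(ITEM_NAMES))
        if bad:
            raise ValueError(f"unknown item names: {bad}")
        return v

    @field_validator("per_item_error", "registry_item_error")
    @classmethod
    def _probabilities(cls, v):
        for item, p in v.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability for {item!r} outside [0, 1]: {p}")
        return v

    @field_validator("emr_urgency_vocabulary")
    @classmethod
    def _vocab(cls, v):
        if v not in ("registry", "emr8"):
            raise ValueError(f"unknown urgency vocabulary {v!r}")
        return v


def load_generator_config(path: str | Path) -> GeneratorConfig:
    """Read a YAML or JSON config file, schema-validated."""
    path = Path(path)
    text = path.read_text()
    try:
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    return validate_config(raw)


def validate_config(raw: dict) -> GeneratorConfig:
    try:
        config = GeneratorConfig(**raw)
    except ValidationError as exc:
        if any("n_patients" in str(e.get("loc")) for e in exc.errors()) and raw.get(
            "n_patients"
        ) in (0,):
            raise EmptyCohortError("n_patients must be at least 1") from exc
        raise ConfigurationError(str(exc)) from exc
    return config
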