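"""End-to-end assessment: checklist -> severity -> SNOMED attribution -> explanation.

``assess`` chains the stages into a single JSON-serializable document that is
deterministic for fixed inputs and model: key order is fixed and floats are
rounded to 6 decimals before serialization.  A small schema validator (schema
shipped in package data) checks the document shape.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import metadata, resources
from typing import Any

from .classifier import Checklist, ClassifierModel, generate_checklist
from .errors import PhqScreenError, StageError, ValidationError
from .explain import ExplanationReport, explain
from .ontology import ITEMS, SymptomOntology
from .scoring import SeverityAssessment, diagnose
from .snomed import NoMatch, SnomedMatch, attribute


def _version() -> str:
    try:
        return metadata.version("phqscreen")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def config_hash(config: dict | None) -> str:
    """Stable short hash of the effective configuration."""
    canonical = json.dumps(config or {}, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:16]


@dataclass
class DiagnosisOutput:
    checklist: Checklist
    assessment: SeverityAssessment
    snomed_match: SnomedMatch | NoMatch
    explanation: ExplanationReport
    metrics: dict | None = None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        doc: dict[str, Any] = {
            "checklist": {
                "answers": {k: self.checklist.answers[k] for k in ITEMS},
                "confidences": {k: self.checklist.confidences[k] for k in ITEMS},
                "cues": {
                    k: [
                        {
                            "term": c.term,
                            "span": [c.start, c.end],
                            "frequency_cue": c.frequency_cue,
                        }
                        for c in self.checklist.cues[k]
                    ]
                    for k in ITEMS
                },
            },
            "assessment": {
                "item_scores": {k: self.assessment.item_scores[k] for k in ITEMS},
                "total_score": self.assessment.total_score,
                "band": self.assessment.band,
                "diagnosis_label": self.assessment.diagnosis_label,
                "provenance": self.assessment.provenance,
            },
            "snomed": self.snomed_match.to_record(),
            "explanation": self.explanation.to_dict(),
            "metadata": self.metadata,
        }
        if self.metrics is not None:
            doc["metrics"] = self.metrics
        return _round_floats(doc)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, ensure_ascii=False)


def _round_floats(obj):
    if isinstance(obj, float):
        return round(obj, 6)
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def assess(
    text: str,
    model: ClassifierModel,
    ontology: SymptomOntology,
    snomed_table,
    embedder,
    config: dict | None = None,
    stopwords=None,
    overrides: dict[str, str] | None = None,
) -> DiagnosisOutput:
    """Run the full pipeline on one input text.

    Stage errors propagate wrapped in StageError carrying the stage name.
    """

    def _stage(name, fn):
        try:
            return fn()
        except PhqScreenError as exc:
            raise StageError(name, exc) from exc

    checklist = _stage(
        "checklist",
        lambda: generate_checklist(text, model, ontology, embedder, stopwords),
    )
    assessment = _stage("scoring", lambda: diagnose(checklist))
    match = _stage(
        "attribution",
        lambda: attribute(
            assessment.diagnosis_label, snomed_table, embedder, stopwords, overrides
        ),
    )
    explanation = _stage("explanation", lambda: explain(checklist, assessment, match))
    meta = {
        "config_hash": config_hash(config),
        "seed": int((config or {}).get("seed", 0)),
        "version": _version(),
    }
    return DiagnosisOutput(checklist, assessment, match, explanation, metadata=meta)


# --- minimal schema validation ---------------------------------------------

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
}


def _check(instance, schema, path: str) -> list[str]:
    errors: list[str] = []
    expected = schema.get("type")
    if expected is not None:
        py = _TYPES[expected]
        ok = isinstance(instance, py)
        if expected == "integer" and isinstance(instance, bool):
            ok = False
        if not ok:
            return [f"{path}: expected {expected}, got {type(instance).__name__}"]
    if "enum" in schema and instance not in schema["enum"]:
        errors.append(f"{path}: {instance!r} not in {schema['enum']}")
    if expected == "object":
        for key in schema.get("required", ()):
            if key not in instance:
                errors.append(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in instance:
                errors.extend(_check(instance[key], sub, f"{path}.{key}"))
    if expected == "array" and "items" in schema:
        for i, v in enumerate(instance):
            errors.extend(_check(v, schema["items"], f"{path}[{i}]"))
    return errors


def output_schema() -> dict:
    raw = resources.files("phqscreen.data").joinpath("output_schema.json").read_text(
        encoding="utf-8"
    )
    return json.loads(raw)


def validate_output(doc: dict) -> None:
    """Validate an assess() document against the shipped schema; raise on failure."""
    errors = _check(doc, output_schema(), "$")
    if errors:
        raise ValidationError("output schema violations: " + "; ".join(errors))
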