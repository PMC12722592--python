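"""Dual-detection integration and assessment serialization.

Contextual anomaly spans (statistical) and rule violations (exact knowledge)
are fused into a single list of non-overlapping detections: spans sharing at
least one position merge into one detection with ``source="both"``, where
the rule engine's error type and suggestion take precedence over the
contextual detector's, since knowledge rules are exact while the contextual
model is statistical. Contextual-only detections default to
``spelling_mistake`` — the error family the confusion-set mechanism
realizes — so every detection carries a type.

The assessment never mutates report text: it is an annotation layer,
serialized to a fixed JSON schema for downstream consumers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .context import (
    ContextModel,
    detect_anomalies,
    score_tokens,
    suggest_correction,
)
from .injection import ERROR_TYPES
from .lexicon import Lexicon, default_lexicon
from .rules import RuleSet, RuleViolation, check, default_rules
from .synthesis import Report, ReportMetadata

_SOURCES = ("contextual", "rule", "both")


class SchemaError(ValueError):
    """An assessment document violates the published JSON schema."""


@dataclass(frozen=True)
class Detection:
    source: str
    start: int
    end: int
    error_type: str
    suggestion: str | None
    confidence: float

    def __post_init__(self) -> None:
        if self.source not in _SOURCES:
            raise ValueError(f"bad source {self.source!r}")
        if self.error_type not in ERROR_TYPES:
            raise ValueError(f"bad error type {self.error_type!r}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0, 1]")
        if self.start > self.end:
            raise ValueError("invalid span")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class ReportAssessment:
    report_id: str
    detections: tuple[Detection, ...]

    @property
    def error_count(self) -> int:
        return len(self.detections)

    @property
    def status(self) -> str:
        return "clean" if not self.detections else "flagged"


def _overlap(a: Detection, b: Detection) -> bool:
    return max(a.start, b.start) < min(a.end, b.end)


def merge(
    contextual: Sequence[Detection],
    rule_detections: Sequence[Detection | RuleViolation],
) -> list[Detection]:
    """Fuse contextual and rule detections into non-overlapping spans."""
    pool: list[Detection] = list(contextual)
    for item in rule_detections:
        if isinstance(item, RuleViolation):
            item = Detection(
                source="rule",
                start=item.start,
                end=item.end,
                error_type=item.error_type,
                suggestion=item.suggestion,
                confidence=1.0,
            )
        pool.append(item)
    pool.sort(key=lambda d: (d.start, d.end))

    merged: list[Detection] = []
    cluster: list[Detection] = []
    for det in pool:
        if cluster and any(_overlap(det, c) for c in cluster):
            cluster.append(det)
        else:
            if cluster:
                merged.append(_fuse(cluster))
            cluster = [det]
    if cluster:
        merged.append(_fuse(cluster))
    return merged


def _fuse(cluster: Sequence[Detection]) -> Detection:
    if len(cluster) == 1:
        return cluster[0]
    sources = {d.source for d in cluster}
    rules = [d for d in cluster if d.source in {"rule", "both"}]
    lead = rules[0] if rules else cluster[0]  # rule wins on type & suggestion
    source = "both" if len(sources) > 1 or "both" in sources else cluster[0].source
    return Detection(
        source=source,
        start=min(d.start for d in cluster),
        end=max(d.end for d in cluster),
        error_type=lead.error_type,
        suggestion=lead.suggestion,
        confidence=max(d.confidence for d in cluster),
    )


def contextual_detections(
    model: ContextModel,
    text: str,
    threshold: float,
    lexicon: Lexicon,
) -> list[Detection]:
    """Flag high-surprisal spans and attach confusion-set corrections.

    Confidence is the anomaly strength mapped back to probability scale:
    ``1 − exp(−mean surprisal)``, i.e. one minus the geometric-mean token
    likelihood over the span.
    """
    scores = score_tokens(model, text)
    detections = []
    for start, end in detect_anomalies(scores, threshold):
        mean_surprisal = sum(s.surprisal for s in scores[start:end]) / (end - start)
        confidence = min(1.0, max(0.0, 1.0 - math.exp(-mean_surprisal)))
        suggestion = None
        # the flagged run may extend past the mis-typed word into its
        # surprised neighbours: look for the longest (then leftmost)
        # confusion-set-indexed substring inside the span
        found = None
        for length in range(end - start, 0, -1):
            for i in range(start, end - length + 1):
                candidates = lexicon.confusion_set(text[i : i + length])
                if candidates:
                    found = ((i, i + length), candidates)
                    break
            if found:
                break
        if found:
            sub_span, candidates = found
            suggestion = suggest_correction(model, text, sub_span, candidates)[0].surface
        detections.append(
            Detection(
                source="contextual",
                start=start,
                end=end,
                error_type="spelling_mistake",
                suggestion=suggestion,
                confidence=confidence,
            )
        )
    return detections


def assess(
    text: str,
    metadata: ReportMetadata,
    model: ContextModel,
    threshold: float,
    rules: RuleSet | None = None,
    lexicon: Lexicon | None = None,
    report_id: str = "r000000",
) -> ReportAssessment:
    """Run dual detection on one report text and wrap the merged result."""
    lexicon = lexicon if lexicon is not None else default_lexicon()
    rules = rules if rules is not None else default_rules()
    contextual = contextual_detections(model, text, threshold, lexicon)
    violations = check(text, metadata, rules, lexicon)
    return ReportAssessment(
        report_id=report_id, detections=tuple(merge(contextual, violations))
    )


def assess_report(
    report: Report,
    model: ContextModel,
    threshold: float,
    rules: RuleSet | None = None,
    lexicon: Lexicon | None = None,
) -> ReportAssessment:
    return assess(
        report.text, report.metadata, model, threshold, rules, lexicon, report.id
    )


# ---------------------------------------------------------------------------
# JSON serialization + schema validation
# ---------------------------------------------------------------------------

def assessment_to_dict(assessment: ReportAssessment) -> dict:
    return {
        "report_id": assessment.report_id,
        "status": assessment.status,
        "error_count": assessment.error_count,
        "detections": [
            {
                "source": d.source,
                "start": d.start,
                "end": d.end,
                "error_type": d.error_type,
                "suggestion": d.suggestion,
                "confidence": d.confidence,
            }
            for d in assessment.detections
        ],
    }


def to_json(assessment: ReportAssessment) -> str:
    return json.dumps(assessment_to_dict(assessment), ensure_ascii=False, sort_keys=True)


def validate_assessment_dict(doc: Mapping) -> None:
    """Raise :class:`SchemaError` unless *doc* conforms to the schema."""
    required = {"report_id", "status", "error_count", "detections"}
    if not isinstance(doc, Mapping) or set(doc) != required:
        raise SchemaError(f"top-level keys must be exactly {sorted(required)}")
    if not isinstance(doc["report_id"], str):
        raise SchemaError("report_id must be a string")
    if doc["status"] not in {"clean", "flagged"}:
        raise SchemaError("status must be 'clean' or 'flagged'")
    if not isinstance(doc["error_count"], int) or isinstance(doc["error_count"], bool):
        raise SchemaError("error_count must be an integer")
    detections = doc["detections"]
    if not isinstance(detections, list):
        raise SchemaError("detections must be a list")
    if doc["error_count"] != len(detections):
        raise SchemaError("error_count must equal the number of detections")
    if (doc["status"] == "clean") != (len(detections) == 0):
        raise SchemaError("status must be 'clean' iff there are no detections")
    det_required = {"source", "start", "end", "error_type", "suggestion", "confidence"}
    previous_start = -1
    for item in detections:
        if not isinstance(item, Mapping) or set(item) != det_required:
            raise SchemaError(f"detection keys must be exactly {sorted(det_required)}")
        if item["source"] not in _SOURCES:
            raise SchemaError(f"bad detection source {item['source']!r}")
        if item["error_type"] not in ERROR_TYPES:
            raise SchemaError(f"bad detection error_type {item['error_type']!r}")
        if not (isinstance(item["start"], int) and isinstance(item["end"], int)):
            raise SchemaError("detection span offsets must be integers")
        if item["start"] > item["end"] or item["start"] < 0:
            raise SchemaError("invalid detection span")
        if item["suggestion"] is not None and not isinstance(item["suggestion"], str):
            raise SchemaError("suggestion must be a string or null")
        if not isinstance(item["confidence"], (int, float)) or not 0 <= item["confidence"] <= 1:
            raise SchemaError("confidence must be a number in [0, 1]")
        if item["start"] < previous_start:
            raise SchemaError("detections must be sorted by start")
        previous_start = item["start"]


def assessment_from_dict(doc: Mapping) -> ReportAssessment:
    validate_assessment_dict(doc)
    return ReportAssessment(
        report_id=doc["report_id"],
        detections=tuple(
            Detection(
                source=d["source"],
                start=d["start"],
                end=d["end"],
                error_type=d["error_type"],
                suggestion=d["suggestion"],
                confidence=float(d["confidence"]),
            )
            for d in doc["detections"]
        ),
    )


def from_json(text: str) -> ReportAssessment:
    return assessment_from_dict(json.loads(text))
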