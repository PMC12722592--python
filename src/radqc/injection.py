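"""Systematic error injection: clean reports -> corrupted reports + gold labels.

Seven semantic error types are injected by entity substitution, omission or
insertion, mirroring how erroneous reports are simulated from a high-quality
corpus: spelling mistakes via homophone confusion sets, side confusion via
left/right swaps, wrong measurement units via cross-dimension unit swaps,
sex-/age-/modality-inconsistent terms via metadata-incompatible entities, and
a residual "other" class of character omissions/insertions outside entity
spans.

Every corrupted report carries exact gold annotations (span in the corrupted
text, mechanism, original and corrupted strings, the correction), and the
inverse edits reconstruct the clean text exactly — the property the
evaluation stage relies on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .lexicon import Lexicon, UNIT_DIMENSIONS, default_lexicon
from .synthesis import Report, report_from_record, report_to_record

ERROR_TYPES: tuple[str, ...] = (
    "spelling_mistake",
    "side_confusion",
    "incorrect_measurement_unit",
    "gender_error",
    "age_error",
    "mismatched_imaging_modality",
    "other",
)

#: default type mix: per-type reference-standard proportions (counts
#: 310/35/40/24/18/45/34 out of 506)
DEFAULT_TYPE_MIX: Mapping[str, float] = {
    "spelling_mistake": 310 / 506,
    "side_confusion": 35 / 506,
    "incorrect_measurement_unit": 40 / 506,
    "gender_error": 24 / 506,
    "age_error": 18 / 506,
    "mismatched_imaging_modality": 45 / 506,
    "other": 34 / 506,
}

#: filler characters for "other" insertions (none occurs in any lexicon surface)
_FILLER_CHARS = "的了是在有"

_PUNCTUATION = "：，。；"


class InjectionError(RuntimeError):
    """No viable injection site for the requested error type."""


@dataclass(frozen=True)
class ErrorAnnotation:
    """Gold-standard error; span addresses the CORRUPTED text."""

    error_type: str
    start: int
    end: int
    mechanism: str  # substitute | omit | insert
    original: str  # empty for insert
    corrupted: str  # empty for omit
    suggestion: str

    def __post_init__(self) -> None:
        if self.error_type not in ERROR_TYPES:
            raise ValueError(f"unknown error type {self.error_type!r}")
        if self.mechanism not in {"substitute", "omit", "insert"}:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism == "insert" and self.original:
            raise ValueError("insert annotations carry no original string")
        if self.mechanism == "omit" and self.corrupted:
            raise ValueError("omit annotations carry no corrupted string")
        if self.end - self.start != len(self.corrupted):
            raise ValueError("span length must equal corrupted string length")


@dataclass(frozen=True)
class CorruptedReport:
    clean: Report
    corrupted_text: str
    annotations: tuple[ErrorAnnotation, ...]

    @property
    def is_corrupted(self) -> bool:
        return bool(self.annotations)


def reconstruct_clean(corrupted_text: str, annotations: Sequence[ErrorAnnotation]) -> str:
    """Apply inverse edits right-to-left; must reproduce the clean text."""
    text = corrupted_text
    for ann in sorted(annotations, key=lambda a: a.start, reverse=True):
        text = text[: ann.start] + ann.original + text[ann.end :]
    return text


# ---------------------------------------------------------------------------
# edit planning (clean-text coordinates)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Edit:
    start: int  # clean-text offset
    end: int
    original: str
    replacement: str
    error_type: str
    mechanism: str
    suggestion: str


def _side_pairs(mentions) -> list[tuple[str, str, object]]:
    """(laterality, anatomy_surface, orientation_mention) for adjacent pairs."""
    pairs = []
    for a, b in zip(mentions, mentions[1:]):
        lat = a.attributes.get("laterality")
        if lat in {"left", "right"} and a.end == b.start and "anatomical_location" in b.categories:
            pairs.append((lat, b.surface, a))
    return pairs


def _candidate_edits(report: Report, error_type: str, lexicon: Lexicon) -> list[list[_Edit]]:
    """All viable single edits for *error_type*, grouped per site.

    Each inner list holds the alternative replacements at one site; the
    injector first picks a site, then a replacement, both seeded.
    """
    text = report.text
    meta = report.metadata
    mentions = lexicon.match_entities(text)
    sites: list[list[_Edit]] = []

    if error_type == "spelling_mistake":
        for m in mentions:
            alternatives = lexicon.confusion_set(m.surface)
            if alternatives:
                sites.append([
                    _Edit(m.start, m.end, m.surface, alt, error_type, "substitute", m.surface)
                    for alt in sorted(alternatives)
                ])

    elif error_type == "side_confusion":
        pairs = _side_pairs(mentions)
        counts: dict[tuple[str, str], int] = {}
        for lat, anat, _ in pairs:
            counts[(lat, anat)] = counts.get((lat, anat), 0) + 1
        opposite = {"left": "right", "right": "left"}
        flips = {
            e.attributes.get("laterality"): e.surface
            for e in lexicon.entries_in_category("orientation")
            if e.attributes.get("laterality") in {"left", "right"}
        }
        # a swap is only a *detectable* contradiction if the same (side,
        # anatomy) pair occurs at least twice, so one flip leaves a conflict
        for lat, anat, m in pairs:
            if counts[(lat, anat)] >= 2 and opposite[lat] in flips:
                alt = flips[opposite[lat]]
                sites.append([
                    _Edit(m.start, m.end, m.surface, alt, error_type, "substitute", m.surface)
                ])

    elif error_type == "incorrect_measurement_unit":
        units = [e.surface for e in lexicon.entries_in_category("measurement_unit")]
        for m in mentions:
            if "measurement_unit" not in m.categories:
                continue
            dim = UNIT_DIMENSIONS.get(m.surface)
            wrong = sorted(u for u in units if UNIT_DIMENSIONS.get(u) != dim)
            if wrong:
                sites.append([
                    _Edit(m.start, m.end, m.surface, alt, error_type, "substitute", m.surface)
                    for alt in wrong
                ])

    elif error_type in {"gender_error", "age_error"}:
        if error_type == "gender_error":
            category = "gender_related"

            def incompatible(entry):
                sex = entry.attributes.get("sex_specific")
                return sex is not None and sex != meta.patient_sex

            def matches(mention):
                return "sex_specific" in mention.attributes
        else:
            category = "age_related"

            def incompatible(entry):
                band = entry.attributes.get("age_band")
                return band is not None and not (band[0] <= meta.age_years <= band[1])

            def matches(mention):
                return "age_band" in mention.attributes

        bad = sorted(
            e.surface for e in lexicon.entries_in_category(category) if incompatible(e)
        )
        if bad:
            targets = [m for m in mentions if matches(m)]
            if targets:  # substitute an existing metadata-bound mention
                for m in targets:
                    sites.append([
                        _Edit(m.start, m.end, m.surface, alt, error_type, "substitute", m.surface)
                        for alt in bad if alt != m.surface
                    ])
            else:  # insert an incompatible entity after a punctuation mark
                positions = [i + 1 for i, ch in enumerate(text) if ch in _PUNCTUATION
                             and i + 1 < len(text)]
                for pos in positions:
                    sites.append([
                        _Edit(pos, pos, "", alt, error_type, "insert", "") for alt in bad
                    ])

    elif error_type == "mismatched_imaging_modality":
        devices = lexicon.entries_in_category("device_related")
        for m in mentions:
            if "modality_set" not in m.attributes:
                continue
            wrong = sorted(
                e.surface
                for e in devices
                if meta.modality not in e.attributes.get("modality_set", ())
                and e.surface != m.surface
            )
            if wrong:
                sites.append([
                    _Edit(m.start, m.end, m.surface, alt, error_type, "substitute", m.surface)
                    for alt in wrong
                ])

    elif error_type == "other":
        covered = np.zeros(len(text), dtype=bool)
        for m in mentions:
            covered[m.start : m.end] = True
        for i, ch in enumerate(text):
            if not covered[i] and ch not in "\n":
                # omit this character
                sites.append([_Edit(i, i + 1, ch, "", error_type, "omit", ch)])
        boundary_ok = [
            i
            for i in range(1, len(text))
            if not (covered[i - 1] and covered[i])  # never split an entity
        ]
        for i in boundary_ok:
            sites.append([
                _Edit(i, i, "", ch, error_type, "insert", "") for ch in _FILLER_CHARS
            ])

    else:
        raise ValueError(f"unknown error type {error_type!r}")

    return [s for s in sites if s]


def _apply_edits(clean_text: str, edits: Sequence[_Edit]) -> tuple[str, tuple[ErrorAnnotation, ...]]:
    pieces: list[str] = []
    annotations: list[ErrorAnnotation] = []
    cursor = 0
    offset = 0
    for edit in sorted(edits, key=lambda e: e.start):
        pieces.append(clean_text[cursor : edit.start])
        start = edit.start + offset
        pieces.append(edit.replacement)
        annotations.append(
            ErrorAnnotation(
                error_type=edit.error_type,
                start=start,
                end=start + len(edit.replacement),
                mechanism=edit.mechanism,
                original=edit.original,
                corrupted=edit.replacement,
                suggestion=edit.suggestion,
            )
        )
        cursor = edit.end
        offset += len(edit.replacement) - (edit.end - edit.start)
    pieces.append(clean_text[cursor:])
    return "".join(pieces), tuple(annotations)


def inject(
    report: Report,
    error_type: str,
    rng_seed: int | np.random.Generator,
    lexicon: Lexicon | None = None,
) -> CorruptedReport:
    """Corrupt *report* with exactly one error of *error_type*."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    lexicon = lexicon if lexicon is not None else default_lexicon()
    sites = _candidate_edits(report, error_type, lexicon)
    if not sites:
        raise InjectionError(f"no viable site for error type {error_type!r} in {report.id}")
    site = sites[int(rng.integers(len(sites)))]
    edit = site[int(rng.integers(len(site)))]
    corrupted_text, annotations = _apply_edits(report.text, [edit])
    return CorruptedReport(clean=report, corrupted_text=corrupted_text, annotations=annotations)


def generate_paired_corpus(
    reports: Sequence[Report],
    per_report_error_prob: float,
    type_mix: Mapping[str, float] | None = None,
    rng_seed: int = 0,
    lexicon: Lexicon | None = None,
    max_attempts: int = 7,
    path=None,
) -> list[CorruptedReport]:
    """Independently corrupt each report with the stated probability.

    The error type is drawn from *type_mix*; if the drawn type has no viable
    site in a report, the type is redrawn from the renormalized remaining mix
    (up to *max_attempts* draws), after which the report is left clean.
    """
    if not 0.0 <= per_report_error_prob <= 1.0:
        raise ValueError("per_report_error_prob must be in [0, 1]")
    type_mix = dict(type_mix if type_mix is not None else DEFAULT_TYPE_MIX)
    if set(type_mix) - set(ERROR_TYPES):
        raise ValueError(f"unknown error types {sorted(set(type_mix) - set(ERROR_TYPES))}")
    if any(p < 0 for p in type_mix.values()) or abs(sum(type_mix.values()) - 1.0) > 1e-9:
        raise ValueError("type_mix must be a distribution over error types")
    lexicon = lexicon if lexicon is not None else default_lexicon()
    rng = np.random.default_rng(rng_seed)

    pairs: list[CorruptedReport] = []
    for report in reports:
        if rng.random() >= per_report_error_prob:
            pairs.append(CorruptedReport(report, report.text, ()))
            continue
        remaining = {t: p for t, p in type_mix.items() if p > 0}
        corrupted = None
        for _ in range(max_attempts):
            if not remaining:
                break
            keys = sorted(remaining)
            probs = np.asarray([remaining[k] for k in keys])
            drawn = keys[int(rng.choice(len(keys), p=probs / probs.sum()))]
            try:
                corrupted = inject(report, drawn, rng, lexicon)
                break
            except InjectionError:
                del remaining[drawn]
        pairs.append(corrupted if corrupted is not None
                     else CorruptedReport(report, report.text, ()))
    if path is not None:
        write_paired_corpus(pairs, path)
    return pairs


# ---------------------------------------------------------------------------
# paired JSONL round-trip
# ---------------------------------------------------------------------------

def pair_to_record(pair: CorruptedReport) -> dict:
    record = {
        "id": pair.clean.id,
        "clean_text": pair.clean.text,
        "corrupted_text": pair.corrupted_text,
        "annotations": [
            {
                "type": a.error_type,
                "start": a.start,
                "end": a.end,
                "mechanism": a.mechanism,
                "original": a.original,
                "corrupted": a.corrupted,
                "suggestion": a.suggestion,
            }
            for a in pair.annotations
        ],
        # metadata travels with the pair so rule checking needs no join
        "metadata": {
            k: v for k, v in report_to_record(pair.clean).items()
            if k not in {"id", "findings", "impression"}
        },
    }
    return record


def pair_from_record(record: Mapping) -> CorruptedReport:
    clean_text = record["clean_text"]
    findings, _, impression = clean_text.partition("\n")
    report = report_from_record(
        {"id": record["id"], "findings": findings, "impression": impression,
         **record["metadata"]}
    )
    annotations = tuple(
        ErrorAnnotation(
            error_type=a["type"],
            start=a["start"],
            end=a["end"],
            mechanism=a["mechanism"],
            original=a["original"],
            corrupted=a["corrupted"],
            suggestion=a["suggestion"],
        )
        for a in record["annotations"]
    )
    return CorruptedReport(report, record["corrupted_text"], annotations)


def write_paired_corpus(pairs: Iterable[CorruptedReport], path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for pair in pairs:
            handle.write(json.dumps(pair_to_record(pair), ensure_ascii=False,
                                    sort_keys=True) + "\n")


def read_paired_corpus(path) -> list[CorruptedReport]:
    pairs = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            if line.strip():
                pairs.append(pair_from_record(json.loads(line)))
    return pairs
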