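"""Synthetic Chinese radiology report generation.

Real report corpora of this kind are hospital-private, so every downstream
stage (error injection, the contextual detector, rule checking, evaluation)
runs on reports sampled from declarative templates. Template slots are filled
only with lexicon entries whose attributes are compatible with the sampled
metadata (patient sex, age, modality), which makes the generated corpus
error-free by construction: the generator and the shipped rule set are
mutually consistent, giving a zero-error ground truth analogous to a corpus
cross-proofread by a radiologist panel.

Default stratum proportions follow the baseline collection of the study
setting this package emulates: modality 26.6% DR / 55.7% CT / 17.7% MRI,
85.7% daytime submission, 69.3% attending-radiologist reports. Daytime is
08:00-17:59 and nighttime is its complement.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

from .lexicon import Lexicon, LexiconEntry, default_lexicon

SEXES = ("male", "female")
PERIODS = ("daytime", "nighttime")
TITLES = ("attending", "senior")

#: default stratum mix (baseline-collection proportions)
DEFAULT_MIX: Mapping[str, Mapping[str, float]] = {
    "modality": {"DR": 0.266, "CT": 0.557, "MRI": 0.177},
    "sex": {"male": 0.5, "female": 0.5},
    "period": {"daytime": 0.857, "nighttime": 0.143},
    "title": {"attending": 0.693, "senior": 0.307},
}

#: study window in months (12 baseline + 16 post-deployment)
DEFAULT_N_MONTHS = 28

_SLOT_RE = re.compile(r"\{([A-Za-z_][A-Za-z0-9_]*):([A-Za-z0-9_]+)\}")


class GenerationError(RuntimeError):
    """No lexicon entry is compatible with a slot under the given metadata."""


@dataclass(frozen=True)
class ReportMetadata:
    patient_sex: str
    age_years: int
    modality: str
    submission_period: str
    radiologist_title: str
    month_index: int

    def __post_init__(self) -> None:
        if self.patient_sex not in SEXES:
            raise ValueError(f"bad patient_sex {self.patient_sex!r}")
        if self.modality not in {"DR", "CT", "MRI"}:
            raise ValueError(f"bad modality {self.modality!r}")
        if self.submission_period not in PERIODS:
            raise ValueError(f"bad submission_period {self.submission_period!r}")
        if self.radiologist_title not in TITLES:
            raise ValueError(f"bad radiologist_title {self.radiologist_title!r}")
        if self.age_years < 0:
            raise ValueError("age_years must be >= 0")


@dataclass(frozen=True)
class Report:
    id: str
    metadata: ReportMetadata
    findings: str
    impression: str

    @property
    def text(self) -> str:
        """Findings and impression as one span-addressable string."""
        return self.findings + "\n" + self.impression


@dataclass(frozen=True)
class SlotType:
    name: str
    kind: str  # "entity" | "number"
    category: str | None = None
    surfaces: tuple[str, ...] | None = None
    require: Mapping[str, object] = field(default_factory=dict)
    low: float = 0.0
    high: float = 1.0
    decimals: int = 0


@dataclass(frozen=True)
class Template:
    id: str
    modalities: tuple[str, ...]
    findings: str
    impression: str

    def slots(self) -> list[tuple[str, str]]:
        """(slot_type_name, key) pairs in order of first appearance."""
        seen: list[tuple[str, str]] = []
        for pattern in (self.findings, self.impression):
            for m in _SLOT_RE.finditer(pattern):
                pair = (m.group(1), m.group(2))
                if pair not in seen:
                    seen.append(pair)
        return seen


@dataclass(frozen=True)
class TemplateSet:
    slot_types: Mapping[str, SlotType]
    templates: tuple[Template, ...]

    def for_modality(self, modality: str) -> tuple[Template, ...]:
        return tuple(t for t in self.templates if modality in t.modalities)


def load_templates(path) -> TemplateSet:
    with open(path, encoding="utf-8") as handle:
        return _parse_templates(json.load(handle))


def default_templates() -> TemplateSet:
    data = resources.files("radqc.data")
    with (data / "templates.json").open(encoding="utf-8") as handle:
        return _parse_templates(json.load(handle))


def _parse_templates(doc: Mapping) -> TemplateSet:
    slot_types = {}
    for name, spec in doc["slot_types"].items():
        slot_types[name] = SlotType(
            name=name,
            kind=spec["kind"],
            category=spec.get("category"),
            surfaces=tuple(spec["surfaces"]) if "surfaces" in spec else None,
            require=spec.get("require", {}),
            low=spec.get("low", 0.0),
            high=spec.get("high", 1.0),
            decimals=spec.get("decimals", 0),
        )
    templates = tuple(
        Template(
            id=t["id"],
            modalities=tuple(t["modalities"]),
            findings=t["findings"],
            impression=t["impression"],
        )
        for t in doc["templates"]
    )
    for template in templates:
        for type_name, _ in template.slots():
            if type_name not in slot_types:
                raise ValueError(f"template {template.id}: unknown slot type {type_name!r}")
    return TemplateSet(slot_types=slot_types, templates=templates)


# ---------------------------------------------------------------------------
# slot filling
# ---------------------------------------------------------------------------

def _entry_compatible(entry: LexiconEntry, slot: SlotType, meta: ReportMetadata) -> bool:
    if slot.surfaces is not None and entry.surface not in slot.surfaces:
        return False
    for key, wanted in slot.require.items():
        if key == "age_band_contains":
            band = entry.attributes.get("age_band")
            if band is None or not (band[0] <= meta.age_years <= band[1]):
                return False
        elif isinstance(wanted, str) and wanted.startswith("$"):
            actual = entry.attributes.get(key)
            target = getattr(meta, wanted[1:])
            if actual != target:
                return False
        elif isinstance(wanted, (list, tuple)):
            if entry.attributes.get(key) not in wanted:
                return False
        else:
            if entry.attributes.get(key) != wanted:
                return False
    return True


def _fill_slot(
    slot: SlotType, meta: ReportMetadata, lexicon: Lexicon, rng: np.random.Generator
) -> str:
    if slot.kind == "number":
        if slot.decimals == 0:
            return str(int(rng.integers(int(slot.low), int(slot.high) + 1)))
        value = rng.uniform(slot.low, slot.high)
        return f"{value:.{slot.decimals}f}"
    candidates = [
        e.surface
        for e in lexicon.entries_in_category(slot.category)
        if _entry_compatible(e, slot, meta)
    ]
    if not candidates:
        raise GenerationError(
            f"no lexicon entry compatible with slot {slot.name!r} under metadata {meta}"
        )
    return candidates[int(rng.integers(len(candidates)))]


def _render(pattern: str, fills: Mapping[tuple[str, str], str]) -> str:
    return _SLOT_RE.sub(lambda m: fills[(m.group(1), m.group(2))], pattern)


def _sample_metadata(rng: np.random.Generator, mix: Mapping[str, Mapping[str, float]],
                     n_months: int = DEFAULT_N_MONTHS) -> ReportMetadata:
    def draw(stratum: str) -> str:
        table = mix[stratum]
        keys = sorted(table)
        probs = np.asarray([table[k] for k in keys], dtype=float)
        return keys[int(rng.choice(len(keys), p=probs / probs.sum()))]

    return ReportMetadata(
        patient_sex=draw("sex"),
        age_years=int(rng.integers(1, 91)),
        modality=draw("modality"),
        submission_period=draw("period"),
        radiologist_title=draw("title"),
        month_index=int(rng.integers(0, n_months)),
    )


def _validate_consistency(report: Report, lexicon: Lexicon) -> None:
    meta = report.metadata
    for mention in lexicon.match_entities(report.text):
        sex = mention.attributes.get("sex_specific")
        if sex is not None and sex != meta.patient_sex:
            raise GenerationError(f"{report.id}: sex-specific term {mention.surface!r} "
                                  f"inconsistent with patient_sex={meta.patient_sex}")
        mods = mention.attributes.get("modality_set")
        if mods is not None and meta.modality not in mods:
            raise GenerationError(f"{report.id}: device term {mention.surface!r} "
                                  f"inconsistent with modality={meta.modality}")
        band = mention.attributes.get("age_band")
        if band is not None and not (band[0] <= meta.age_years <= band[1]):
            raise GenerationError(f"{report.id}: age-related term {mention.surface!r} "
                                  f"inconsistent with age={meta.age_years}")


def generate_report(
    rng_seed: int | np.random.Generator,
    templates: TemplateSet | None = None,
    lexicon: Lexicon | None = None,
    metadata: ReportMetadata | None = None,
    report_id: str = "r000000",
    mix: Mapping[str, Mapping[str, float]] | None = None,
) -> Report:
    """Sample one internally consistent report (deterministic under seed)."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    templates = templates if templates is not None else default_templates()
    lexicon = lexicon if lexicon is not None else default_lexicon()
    if metadata is None:
        metadata = _sample_metadata(rng, mix or DEFAULT_MIX)
    pool = templates.for_modality(metadata.modality)
    if not pool:
        raise GenerationError(f"no templates for modality {metadata.modality}")
    template = pool[int(rng.integers(len(pool)))]
    fills: dict[tuple[str, str], str] = {}
    for type_name, key in template.slots():
        fills[(type_name, key)] = _fill_slot(
            templates.slot_types[type_name], metadata, lexicon, rng
        )
    report = Report(
        id=report_id,
        metadata=metadata,
        findings=_render(template.findings, fills),
        impression=_render(template.impression, fills),
    )
    _validate_consistency(report, lexicon)
    return report


def generate_corpus(
    n: int,
    rng_seed: int,
    mix: Mapping[str, Mapping[str, float]] | None = None,
    templates: TemplateSet | None = None,
    lexicon: Lexicon | None = None,
    path=None,
) -> list[Report]:
    """Sample *n* reports; optionally also write them as JSONL to *path*."""
    if n < 0:
        raise ValueError("n must be >= 0")
    mix = mix or DEFAULT_MIX
    for stratum, table in mix.items():
        total = sum(table.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{stratum} proportions sum to {total}, not 1")
    templates = templates if templates is not None else default_templates()
    lexicon = lexicon if lexicon is not None else default_lexicon()
    rng = np.random.default_rng(rng_seed)
    reports = [
        generate_report(rng, templates, lexicon, report_id=f"r{i:06d}", mix=mix)
        for i in range(n)
    ]
    if path is not None:
        write_corpus(reports, path)
    return reports


# ---------------------------------------------------------------------------
# corpus JSONL round-trip
# ---------------------------------------------------------------------------

def report_to_record(report: Report) -> dict:
    meta = report.metadata
    return {
        "id": report.id,
        "sex": meta.patient_sex,
        "age": meta.age_years,
        "modality": meta.modality,
        "period": meta.submission_period,
        "title": meta.radiologist_title,
        "month": meta.month_index,
        "findings": report.findings,
        "impression": report.impression,
    }


def report_from_record(record: Mapping) -> Report:
    return Report(
        id=record["id"],
        metadata=ReportMetadata(
            patient_sex=record["sex"],
            age_years=record["age"],
            modality=record["modality"],
            submission_period=record["period"],
            radiologist_title=record["title"],
            month_index=record["month"],
        ),
        findings=record["findings"],
        impression=record["impression"],
    )


def write_corpus(reports: Iterable[Report], path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for report in reports:
            handle.write(json.dumps(report_to_record(report), ensure_ascii=False,
                                    sort_keys=True) + "\n")


def read_corpus(path) -> list[Report]:
    reports = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            if line.strip():
                reports.append(report_from_record(json.loads(line)))
    return reports
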