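"""Entity-relationship consistency checking.

A declarative database of valid/invalid relations between extracted entity
mentions, report metadata and co-mentions. Each invalid relation maps to one
of the seven semantic error types. The shipped default rule set covers:

* ``sex_consistency`` — a sex-specific entity must match patient sex;
* ``age_consistency`` — an age-banded entity must admit the patient's age;
* ``modality_consistency`` — a device-specific entity must admit the
  report's imaging modality;
* ``laterality_contradiction`` — the same anatomical structure mentioned
  with both left and right laterality within one report (findings versus
  impression); without images, left/right truth is unknowable, so side
  errors are grounded as intra-report contradictions;
* ``unit_context`` — a measurement unit incompatible with its governing
  measurement cue (e.g. an attenuation unit inside a size measurement).

Rules can also be *mined* from a paired clean/corrupted corpus: attribute ×
metadata combinations that occur only in corrupted reports become invalid
relations carrying the gold error type. Declared rules win on id collision.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from .injection import ERROR_TYPES, CorruptedReport
from .lexicon import Lexicon, EntityMention, default_lexicon
from .synthesis import Report, ReportMetadata

_RULE_KINDS = {
    "sex_consistency",
    "age_consistency",
    "modality_consistency",
    "laterality_contradiction",
    "unit_context",
    "attr_combo",
}

#: characters scanned backwards from a unit to find its governing cue
_UNIT_CUE_WINDOW = 14


class RuleError(ValueError):
    pass


@dataclass(frozen=True)
class RelationshipRule:
    id: str
    kind: str
    error_type: str
    params: Mapping[str, object] = field(default_factory=dict)
    validity: str = "invalid"
    suggestion_policy: str = "none"

    def __post_init__(self) -> None:
        if self.kind not in _RULE_KINDS:
            raise RuleError(f"rule {self.id!r}: unknown kind {self.kind!r}")
        if self.validity == "invalid" and self.error_type not in ERROR_TYPES:
            raise RuleError(f"rule {self.id!r}: unknown error type {self.error_type!r}")


@dataclass(frozen=True)
class RuleViolation:
    rule_id: str
    mentions: tuple[EntityMention, ...]
    error_type: str
    start: int
    end: int
    suggestion: str | None = None

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


class RuleSet:
    def __init__(self, rules: Iterable[RelationshipRule] = ()) -> None:
        self._rules: dict[str, RelationshipRule] = {}
        for rule in rules:
            if rule.id in self._rules:
                raise RuleError(f"duplicate rule id {rule.id!r}")
            self._rules[rule.id] = rule

    def __len__(self) -> int:
        return len(self._rules)

    def __iter__(self):
        return iter(self._rules[k] for k in sorted(self._rules))

    def get(self, rule_id: str) -> RelationshipRule | None:
        return self._rules.get(rule_id)

    def merged_with(self, other: "RuleSet") -> "RuleSet":
        """Union of rule sets; rules of *self* win on id collision."""
        combined = dict(other._rules)
        combined.update(self._rules)
        return RuleSet(combined.values())


def load_rules(path) -> RuleSet:
    with open(path, encoding="utf-8") as handle:
        return _parse_rules(json.load(handle))


def default_rules() -> RuleSet:
    data = resources.files("radqc.data")
    with (data / "rules.json").open(encoding="utf-8") as handle:
        return _parse_rules(json.load(handle))


def _parse_rules(doc: Sequence[Mapping]) -> RuleSet:
    rules = []
    for item in doc:
        rules.append(
            RelationshipRule(
                id=item["id"],
                kind=item["kind"],
                error_type=item["error_type"],
                params=item.get("params", {}),
                validity=item.get("validity", "invalid"),
                suggestion_policy=item.get("suggestion_policy", "none"),
            )
        )
    return RuleSet(rules)


# ---------------------------------------------------------------------------
# checking
# ---------------------------------------------------------------------------

def _lateral_anatomy_pairs(mentions: Sequence[EntityMention]):
    """(laterality, anatomy_surface, orientation_mention) for orientation
    mentions immediately followed by an anatomical mention."""
    pairs = []
    for a, b in zip(mentions, mentions[1:]):
        lat = a.attributes.get("laterality")
        if lat in {"left", "right"} and a.end == b.start and "anatomical_location" in b.categories:
            pairs.append((lat, b.surface, a))
    return pairs


def _first_surface(lexicon: Lexicon, category: str, predicate) -> str | None:
    for entry in lexicon.entries_in_category(category):
        if predicate(entry):
            return entry.surface
    return None


def _check_one(
    rule: RelationshipRule,
    text: str,
    metadata: ReportMetadata,
    mentions: Sequence[EntityMention],
    lexicon: Lexicon,
    unit_rules: Sequence[RelationshipRule],
) -> list[RuleViolation]:
    violations: list[RuleViolation] = []

    if rule.kind == "sex_consistency":
        for m in mentions:
            sex = m.attributes.get("sex_specific")
            if sex is not None and sex != metadata.patient_sex:
                suggestion = None
                if rule.suggestion_policy == "compatible_alternative":
                    suggestion = _first_surface(
                        lexicon, "gender_related",
                        lambda e: e.attributes.get("sex_specific") == metadata.patient_sex,
                    )
                violations.append(
                    RuleViolation(rule.id, (m,), rule.error_type, m.start, m.end, suggestion)
                )

    elif rule.kind == "age_consistency":
        for m in mentions:
            band = m.attributes.get("age_band")
            if band is not None and not (band[0] <= metadata.age_years <= band[1]):
                suggestion = None
                if rule.suggestion_policy == "compatible_alternative":
                    suggestion = _first_surface(
                        lexicon, "age_related",
                        lambda e: (b := e.attributes.get("age_band")) is not None
                        and b[0] <= metadata.age_years <= b[1],
                    )
                violations.append(
                    RuleViolation(rule.id, (m,), rule.error_type, m.start, m.end, suggestion)
                )

    elif rule.kind == "modality_consistency":
        for m in mentions:
            mods = m.attributes.get("modality_set")
            if mods is not None and metadata.modality not in mods:
                suggestion = None
                if rule.suggestion_policy == "compatible_alternative":
                    suggestion = _first_surface(
                        lexicon, "device_related",
                        lambda e: metadata.modality in e.attributes.get("modality_set", ()),
                    )
                violations.append(
                    RuleViolation(rule.id, (m,), rule.error_type, m.start, m.end, suggestion)
                )

    elif rule.kind == "laterality_contradiction":
        by_anatomy: dict[str, list[tuple[str, EntityMention]]] = {}
        for lat, anat, mention in _lateral_anatomy_pairs(mentions):
            by_anatomy.setdefault(anat, []).append((lat, mention))
        for anat in sorted(by_anatomy):
            sides = by_anatomy[anat]
            lats = {lat for lat, _ in sides}
            if len(lats) > 1:
                conflicting = tuple(m for _, m in sides)
                counts = Counter(lat for lat, _ in sides)
                suggestion = None
                if rule.suggestion_policy == "majority_side":
                    majority = min(
                        counts, key=lambda lat: (-counts[lat], lat)
                    )  # ties break lexicographically
                    suggestion = _first_surface(
                        lexicon, "orientation",
                        lambda e: e.attributes.get("laterality") == majority,
                    )
                violations.append(
                    RuleViolation(
                        rule.id,
                        conflicting,
                        rule.error_type,
                        min(m.start for m in conflicting),
                        max(m.end for m in conflicting),
                        suggestion,
                    )
                )

    elif rule.kind == "unit_context":
        cue = rule.params["cue"]
        allowed = set(rule.params["allowed_units"])
        all_cues = [str(r.params["cue"]) for r in unit_rules]
        for m in mentions:
            if "measurement_unit" not in m.categories:
                continue
            window = text[max(0, m.start - _UNIT_CUE_WINDOW) : m.start]
            # the rightmost cue occurrence governs this unit
            governing, governing_end = None, -1
            for candidate in all_cues:
                pos = window.rfind(candidate)
                if pos >= 0 and pos + len(candidate) > governing_end:
                    governing, governing_end = candidate, pos + len(candidate)
            if governing == cue and m.surface not in allowed:
                suggestion = None
                if rule.suggestion_policy == "first_allowed_unit":
                    suggestion = sorted(allowed)[0]
                violations.append(
                    RuleViolation(rule.id, (m,), rule.error_type, m.start, m.end, suggestion)
                )

    elif rule.kind == "attr_combo":
        attr = rule.params["attr"]
        attr_value = rule.params["attr_value"]
        meta_key = rule.params["meta"]
        meta_value = rule.params["meta_value"]
        for m in mentions:
            value = m.attributes.get(attr)
            if value is None:
                continue
            if attr == "modality_set":
                formatted = "|".join(value)
            elif attr == "age_band":
                formatted = f"{value[0]}-{value[1]}"
            else:
                formatted = str(value)
            if formatted != attr_value:
                continue
            if meta_key == "age_outside":
                satisfied = not (value[0] <= metadata.age_years <= value[1])
            else:
                satisfied = str(getattr(metadata, meta_key)) == meta_value
            if satisfied:
                violations.append(
                    RuleViolation(rule.id, (m,), rule.error_type, m.start, m.end, None)
                )

    return violations


def check(
    text: str,
    metadata: ReportMetadata,
    rules: RuleSet | None = None,
    lexicon: Lexicon | None = None,
    mentions: Sequence[EntityMention] | None = None,
) -> list[RuleViolation]:
    """All invalid-relation violations in *text*, ordered by (start, rule id)."""
    lexicon = lexicon if lexicon is not None else default_lexicon()
    rules = rules if rules is not None else default_rules()
    if mentions is None:
        mentions = lexicon.match_entities(text)
    unit_rules = [r for r in rules if r.kind == "unit_context"]
    violations: list[RuleViolation] = []
    for rule in rules:
        if rule.validity != "invalid":
            continue
        violations.extend(_check_one(rule, text, metadata, mentions, lexicon, unit_rules))
    violations.sort(key=lambda v: (v.start, v.rule_id))
    return violations


def check_report(report: Report, rules: RuleSet | None = None,
                 lexicon: Lexicon | None = None) -> list[RuleViolation]:
    return check(report.text, report.metadata, rules, lexicon)


# ---------------------------------------------------------------------------
# rule mining
# ---------------------------------------------------------------------------

def _mention_combos(mention: EntityMention, metadata: ReportMetadata):
    """Candidate (attribute, metadata) combination keys for mining."""
    combos = []
    sex = mention.attributes.get("sex_specific")
    if sex is not None:
        combos.append(("sex_specific", sex, "patient_sex", metadata.patient_sex, mention))
    mods = mention.attributes.get("modality_set")
    if mods is not None:
        combos.append(("modality_set", "|".join(mods), "modality", metadata.modality, mention))
    band = mention.attributes.get("age_band")
    if band is not None:
        outside = not (band[0] <= metadata.age_years <= band[1])
        combos.append(
            ("age_band", f"{band[0]}-{band[1]}", "age_outside", str(outside).lower(), mention)
        )
    return combos


def mine_rules(
    paired_corpus: Sequence[CorruptedReport],
    lexicon: Lexicon | None = None,
    min_support: int = 1,
) -> RuleSet:
    """Learn invalid attribute × metadata relations from clean/corrupted pairs.

    A combination observed at least *min_support* times in corrupted reports
    and never in any clean report becomes an invalid rule; its error type is
    the majority gold type among the supporting corrupted mentions.
    """
    if not paired_corpus:
        raise RuleError("paired corpus is empty")
    if not any(pair.annotations for pair in paired_corpus):
        return RuleSet()
    lexicon = lexicon if lexicon is not None else default_lexicon()

    clean_combos: set[tuple] = set()
    corrupted_support: dict[tuple, list[str]] = {}
    for pair in paired_corpus:
        meta = pair.clean.metadata
        for combo in _mention_combos_all(pair.clean.text, meta, lexicon):
            clean_combos.add(combo[:4])
        if not pair.annotations:
            continue
        gold_spans = [(a.start, a.end, a.error_type) for a in pair.annotations]
        for attr, av, mk, mv, mention in _mention_combos_all(
            pair.corrupted_text, meta, lexicon
        ):
            key = (attr, av, mk, mv)
            types = [
                t for s, e, t in gold_spans
                if max(s, mention.start) < min(e, mention.end)
                or (s == e and mention.start <= s <= mention.end)
            ]
            corrupted_support.setdefault(key, []).extend(types)

    mined = []
    for key in sorted(corrupted_support):
        supporters = corrupted_support[key]
        if key in clean_combos or len(supporters) < min_support or not supporters:
            continue
        majority_type = Counter(supporters).most_common(1)[0][0]
        attr, av, mk, mv = key
        mined.append(
            RelationshipRule(
                id=f"mined-{attr}={av}|{mk}={mv}",
                kind="attr_combo",
                error_type=majority_type,
                params={"attr": attr, "attr_value": av, "meta": mk, "meta_value": mv},
                suggestion_policy="none",
            )
        )
    return RuleSet(mined)


def _mention_combos_all(text: str, metadata: ReportMetadata, lexicon: Lexicon):
    for mention in lexicon.match_entities(text):
        yield from _mention_combos(mention, metadata)
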