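"""Entity lexicon, homophone confusion sets and dictionary matching.

The lexicon is the knowledge base the rest of the pipeline leans on: an
11-category vocabulary of radiology-report entities (orientations, anatomy,
units, sex-, age- and device-specific terms, ...) plus homophone /
near-homophone groups that model the dominant spelling-error mechanism in
Chinese text entry (e.g. 上叶 "upper lobe" vs 商业 "business").

Entity extraction is deterministic greedy longest-match over the raw
character stream — no word segmentation — so matching is exactly
reproducible and testable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

ENTITY_CATEGORIES: frozenset[str] = frozenset(
    {
        "orientation",
        "anatomical_location",
        "qualitative",
        "size",
        "measurement_unit",
        "positive_sign",
        "negative_sign",
        "diagnosis",
        "gender_related",
        "device_related",
        "age_related",
    }
)

MODALITIES: frozenset[str] = frozenset({"DR", "CT", "MRI"})

#: admissible keys of ``LexiconEntry.attributes``
ATTRIBUTE_KEYS: frozenset[str] = frozenset(
    {"sex_specific", "modality_set", "age_band", "laterality"}
)

#: measurement-unit dimension classes (used by the error injector to pick a
#: unit of a *different* dimension, which is what makes a unit error semantic
#: rather than a benign rescaling)
UNIT_DIMENSIONS: Mapping[str, str] = {
    "cm": "length",
    "mm": "length",
    "HU": "density",
}


class LexiconError(ValueError):
    """Malformed lexicon resource (bad row, unknown category, ...)."""


@dataclass(frozen=True)
class LexiconEntry:
    surface: str
    categories: frozenset[str]
    attributes: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.surface:
            raise LexiconError("entry surface must be non-empty")
        if not self.categories:
            raise LexiconError(f"entry {self.surface!r} has no categories")
        unknown = set(self.categories) - ENTITY_CATEGORIES
        if unknown:
            raise LexiconError(f"unknown categories {sorted(unknown)} for {self.surface!r}")
        bad_keys = set(self.attributes) - ATTRIBUTE_KEYS
        if bad_keys:
            raise LexiconError(f"unknown attribute keys {sorted(bad_keys)} for {self.surface!r}")


@dataclass(frozen=True)
class HomophoneGroup:
    key: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members) or len(self.members) < 2:
            raise LexiconError(f"homophone group {self.key!r} needs >=2 distinct members")


@dataclass(frozen=True)
class EntityMention:
    """A dictionary match: ``text[start:end] == surface`` (code-point offsets)."""

    surface: str
    start: int
    end: int
    categories: frozenset[str]
    attributes: Mapping[str, object] = field(default_factory=dict)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


class Lexicon:
    """Indexed entries + homophone groups with longest-match lookup."""

    def __init__(
        self,
        entries: Iterable[LexiconEntry] = (),
        groups: Iterable[HomophoneGroup] = (),
    ) -> None:
        self._entries: dict[str, LexiconEntry] = {}
        for entry in entries:
            self.add_entry(entry)
        self._groups: dict[str, HomophoneGroup] = {}
        self._member_to_group: dict[str, str] = {}
        for group in groups:
            self.add_group(group)
        self._max_len = max((len(s) for s in self._entries), default=0)

    # -- construction -----------------------------------------------------
    def add_entry(self, entry: LexiconEntry) -> None:
        # duplicate surfaces merge by category-set union; attributes merge
        # with the later row winning on key collisions
        existing = self._entries.get(entry.surface)
        if existing is not None:
            merged_attrs = dict(existing.attributes)
            merged_attrs.update(entry.attributes)
            entry = LexiconEntry(
                entry.surface, existing.categories | entry.categories, merged_attrs
            )
        self._entries[entry.surface] = entry
        self._max_len = max(getattr(self, "_max_len", 0), len(entry.surface))

    def add_group(self, group: HomophoneGroup) -> None:
        if group.key in self._groups:
            raise LexiconError(f"duplicate homophone group key {group.key!r}")
        self._groups[group.key] = group
        for member in group.members:
            self._member_to_group[member] = group.key

    # -- queries ----------------------------------------------------------
    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, surface: str) -> bool:
        return surface in self._entries

    def get(self, surface: str) -> LexiconEntry | None:
        return self._entries.get(surface)

    @property
    def entries(self) -> tuple[LexiconEntry, ...]:
        return tuple(self._entries[s] for s in sorted(self._entries))

    @property
    def groups(self) -> tuple[HomophoneGroup, ...]:
        return tuple(self._groups[k] for k in sorted(self._groups))

    def entries_in_category(self, category: str) -> tuple[LexiconEntry, ...]:
        if category not in ENTITY_CATEGORIES:
            raise LexiconError(f"unknown category {category!r}")
        return tuple(e for e in self.entries if category in e.categories)

    def confusion_set(self, surface: str) -> list[str]:
        """Homophone-group co-members of *surface* (itself excluded)."""
        key = self._member_to_group.get(surface)
        if key is None:
            return []
        return [m for m in self._groups[key].members if m != surface]

    def match_entities(self, text: str) -> list[EntityMention]:
        """Greedy left-to-right longest-match scan.

        Returned mentions are non-overlapping, sorted by start, and each
        satisfies ``text[start:end] == surface``.
        """
        mentions: list[EntityMention] = []
        i, n = 0, len(text)
        while i < n:
            hit = None
            for length in range(min(self._max_len, n - i), 0, -1):
                candidate = text[i : i + length]
                entry = self._entries.get(candidate)
                if entry is not None:
                    hit = entry
                    break
            if hit is None:
                i += 1
                continue
            mentions.append(
                EntityMention(
                    surface=hit.surface,
                    start=i,
                    end=i + len(hit.surface),
                    categories=hit.categories,
                    attributes=hit.attributes,
                )
            )
            i += len(hit.surface)
        return mentions


def match_entities(text: str, lexicon: Lexicon) -> list[EntityMention]:
    return lexicon.match_entities(text)


def confusion_set(surface: str, lexicon: Lexicon) -> list[str]:
    return lexicon.confusion_set(surface)


# ---------------------------------------------------------------------------
# TSV serialization
#
# Lexicon TSV:   surface<TAB>category[;category...]<TAB>key=value[;key=value...]
# Homophone TSV: group_key<TAB>member[;member...]
# '#'-prefixed lines are comments; UTF-8 throughout.
# ---------------------------------------------------------------------------

def _parse_attributes(raw: str, lineno: int) -> dict[str, object]:
    attrs: dict[str, object] = {}
    for item in raw.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise LexiconError(f"line {lineno}: malformed attribute {item!r}")
        key, value = item.split("=", 1)
        if key not in ATTRIBUTE_KEYS:
            raise LexiconError(f"line {lineno}: unknown attribute key {key!r}")
        if key == "modality_set":
            mods = tuple(sorted(value.split("|")))
            if not set(mods) <= MODALITIES:
                raise LexiconError(f"line {lineno}: bad modality_set {value!r}")
            attrs[key] = mods
        elif key == "age_band":
            lo, hi = value.split("-", 1)
            attrs[key] = (int(lo), int(hi))
        elif key == "sex_specific":
            if value not in {"male", "female"}:
                raise LexiconError(f"line {lineno}: bad sex_specific {value!r}")
            attrs[key] = value
        else:  # laterality
            if value not in {"left", "right", "none"}:
                raise LexiconError(f"line {lineno}: bad laterality {value!r}")
            attrs[key] = value
    return attrs


def _format_attributes(attrs: Mapping[str, object]) -> str:
    parts = []
    for key in sorted(attrs):
        value = attrs[key]
        if key == "modality_set":
            parts.append(f"{key}={'|'.join(value)}")
        elif key == "age_band":
            parts.append(f"{key}={value[0]}-{value[1]}")
        else:
            parts.append(f"{key}={value}")
    return ";".join(parts)


def load_lexicon(path, homophone_path=None) -> Lexicon:
    """Parse the lexicon TSV at *path* (and optionally a homophone TSV)."""
    lexicon = Lexicon()
    with open(path, encoding="utf-8") as handle:
        _read_entries(handle, lexicon)
    if homophone_path is not None:
        with open(homophone_path, encoding="utf-8") as handle:
            _read_groups(handle, lexicon)
    return lexicon


def _read_entries(handle: io.TextIOBase, lexicon: Lexicon) -> None:
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) not in (2, 3):
            raise LexiconError(f"line {lineno}: expected 2 or 3 tab-separated fields")
        surface = fields[0].strip()
        categories = frozenset(c.strip() for c in fields[1].split(";") if c.strip())
        attrs = _parse_attributes(fields[2], lineno) if len(fields) == 3 else {}
        try:
            lexicon.add_entry(LexiconEntry(surface, categories, attrs))
        except LexiconError as exc:
            raise LexiconError(f"line {lineno}: {exc}") from exc


def _read_groups(handle: io.TextIOBase, lexicon: Lexicon) -> None:
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise LexiconError(f"line {lineno}: expected 2 tab-separated fields")
        members = tuple(m.strip() for m in fields[1].split(";") if m.strip())
        try:
            lexicon.add_group(HomophoneGroup(fields[0].strip(), members))
        except LexiconError as exc:
            raise LexiconError(f"line {lineno}: {exc}") from exc


def save_lexicon(lexicon: Lexicon, path, homophone_path=None) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for entry in lexicon.entries:
            row = [entry.surface, ";".join(sorted(entry.categories))]
            if entry.attributes:
                row.append(_format_attributes(entry.attributes))
            handle.write("\t".join(row) + "\n")
    if homophone_path is not None:
        with open(homophone_path, "w", encoding="utf-8") as handle:
            for group in lexicon.groups:
                handle.write(f"{group.key}\t{';'.join(group.members)}\n")


def default_lexicon() -> Lexicon:
    """The lexicon shipped with the package (entities + homophone groups)."""
    data = resources.files("radqc.data")
    lexicon = Lexicon()
    with (data / "lexicon.tsv").open(encoding="utf-8") as handle:
        _read_entries(handle, lexicon)
    with (data / "homophones.tsv").open(encoding="utf-8") as handle:
        _read_groups(handle, lexicon)
    return lexicon
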