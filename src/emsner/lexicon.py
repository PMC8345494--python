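"""Entity schema and synonym lexicon (gazetteer).

The audit targets 17 clinical entities in 3 categories — clinical
procedures, clinical findings and medications.  Each entity carries a list
of synonym surface forms (already normalized, possibly multi-token); a
synonym may be flagged ``exact_only`` to opt out of fuzzy matching even
when it is long enough.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .preprocessing import normalize_text

__all__ = [
    "EntitySchema",
    "Synonym",
    "Lexicon",
    "DEFAULT_SCHEMA",
    "load_lexicon",
    "save_lexicon",
    "starter_lexicon",
]

CLINICAL_PROCEDURE = "Clinical Procedure"
CLINICAL_FINDING = "Clinical Finding"
MEDICATION = "Medication"

#: entity -> category, in canonical order
_DEFAULT_ENTITIES: dict[str, str] = {
    "ECG": CLINICAL_PROCEDURE,
    "Stroke Assessment": CLINICAL_PROCEDURE,
    "Intravenous Cannulation": CLINICAL_PROCEDURE,
    "Burns Cooling": CLINICAL_PROCEDURE,
    "Valsalva Maneuver": CLINICAL_PROCEDURE,
    "Bleeding": CLINICAL_FINDING,
    "Signs Of Obvious Death": CLINICAL_FINDING,
    "Nitroglycerin (GTN)": MEDICATION,
    "Aspirin": MEDICATION,
    "Normal Saline": MEDICATION,
    "Penthrox": MEDICATION,
    "Dextrose/Glucose": MEDICATION,
    "Adrenaline": MEDICATION,
    "Diazepam": MEDICATION,
    "Salbutamol": MEDICATION,
    "Tramadol": MEDICATION,
    "Syntometrine": MEDICATION,
}


@dataclass(frozen=True)
class EntitySchema:
    """Ordered entity inventory and the category of each entity."""

    category: dict[str, str]

    @property
    def entities(self) -> tuple[str, ...]:
        return tuple(self.category)

    @property
    def categories(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for cat in self.category.values():
            seen.setdefault(cat)
        return tuple(seen)

    def __contains__(self, entity: str) -> bool:
        return entity in self.category

    def __len__(self) -> int:
        return len(self.category)


DEFAULT_SCHEMA = EntitySchema(dict(_DEFAULT_ENTITIES))


@dataclass(frozen=True)
class Synonym:
    """One gazetteer surface form: a normalized token tuple, optionally
    restricted to exact matching."""

    tokens: tuple[str, ...]
    exact_only: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        if not self.tokens or any(not t for t in self.tokens):
            raise ValueError(f"empty synonym phrase: {self.tokens!r}")

    @property
    def joined(self) -> str:
        return " ".join(self.tokens)


@dataclass
class Lexicon:
    """Per-entity synonym lists over an :class:`EntitySchema`."""

    schema: EntitySchema
    synonyms: dict[str, list[Synonym]]

    def __post_init__(self) -> None:
        for entity, syns in self.synonyms.items():
            if entity not in self.schema:
                raise ValueError(f"unknown entity {entity!r}")
            if not syns:
                raise ValueError(f"entity {entity!r} has no synonyms")
            seen = set()
            for syn in syns:
                if syn.joined != normalize_text(syn.joined):
                    raise ValueError(
                        f"synonym {syn.joined!r} of {entity!r} is not normalized"
                    )
                if syn.joined in seen:
                    raise ValueError(f"duplicate synonym {syn.joined!r} for {entity!r}")
                seen.add(syn.joined)

    def items(self):
        return self.synonyms.items()

    def phrases(self, entity: str) -> list[Synonym]:
        return self.synonyms[entity]


# ---------------------------------------------------------------------------
# Serialization: YAML (canonical) and flat CSV (entity,category,phrase,exact_only)


def load_lexicon(path: str | Path, schema: EntitySchema | None = None) -> Lexicon:
    """Load a lexicon from a YAML or CSV file.

    YAML layout::

        Aspirin:
          category: Medication
          synonyms:
            - phrase: aspirin
            - phrase: asa
              exact_only: true
    """
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return _lexicon_from_mapping(raw, schema)
    category: dict[str, str] = {}
    synonyms: dict[str, list[Synonym]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            ent = row["entity"]
            category.setdefault(ent, row["category"])
            flag = str(row.get("exact_only", "")).strip().lower() in {"1", "true", "yes"}
            synonyms.setdefault(ent, []).append(
                Synonym(tuple(row["phrase"].split(" ")), flag)
            )
    return Lexicon(schema or EntitySchema(category), synonyms)


def _lexicon_from_mapping(raw: dict, schema: EntitySchema | None) -> Lexicon:
    category: dict[str, str] = {}
    synonyms: dict[str, list[Synonym]] = {}
    for ent, spec in raw.items():
        category[ent] = spec["category"]
        syns = []
        for item in spec["synonyms"]:
            if isinstance(item, str):
                item = {"phrase": item}
            syns.append(
                Synonym(tuple(item["phrase"].split(" ")), bool(item.get("exact_only", False)))
            )
        synonyms[ent] = syns
    return Lexicon(schema or EntitySchema(category), synonyms)


def save_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    raw = {
        ent: {
            "category": lexicon.schema.category[ent],
            "synonyms": [
                {"phrase": s.joined, **({"exact_only": True} if s.exact_only else {})}
                for s in syns
            ],
        }
        for ent, syns in lexicon.items()
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False, allow_unicode=True)


def starter_lexicon() -> Lexicon:
    """The packaged starter gazetteer.

    Seeded from surface forms that appear in real paramedic shorthand
    (``12 lead ecg``, ``gtn spray``, ``i v n s`` ...); users are expected to
    extend it for their own EMS system via :func:`load_lexicon`.
    """
    ref = resources.files("emsner").joinpath("data/starter_lexicon.yaml")
    with ref.open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return _lexicon_from_mapping(raw, DEFAULT_SCHEMA)
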