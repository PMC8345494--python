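"""IOB2 tag scheme utilities and the Mention span type.

The tag inventory is fixed by the schema: one ``B-``/``I-`` pair per entity
plus ``O`` (35 tags for the default 17-entity schema), regardless of which
entities happen to occur in a given split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .lexicon import DEFAULT_SCHEMA, EntitySchema

__all__ = [
    "Mention",
    "tag_vocabulary",
    "mentions_to_iob2",
    "iob2_to_mentions",
    "is_iob2_valid",
]

OUTSIDE = "O"


@dataclass(frozen=True, order=True)
class Mention:
    """One entity occurrence: token span ``[start, end)`` plus entity type.

    ``source`` records provenance (exact / fuzzy gazetteer hit, gold
    annotation, or model prediction) and is ignored by equality so that
    predicted and gold mentions compare by span and type alone.
    """

    start: int
    end: int
    entity: str
    source: str = field(default="gold", compare=False)

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def overlaps(self, other: "Mention") -> bool:
        return self.start < other.end and other.start < self.end

    @property
    def length(self) -> int:
        return self.end - self.start


def tag_vocabulary(schema: EntitySchema = DEFAULT_SCHEMA) -> list[str]:
    """``["O", "B-<e1>", "I-<e1>", ...]`` in schema order."""
    tags = [OUTSIDE]
    for entity in schema.entities:
        tags.append(f"B-{entity}")
        tags.append(f"I-{entity}")
    return tags


def mentions_to_iob2(mentions: Iterable[Mention], n_tokens: int) -> list[str]:
    """Encode non-overlapping mentions as per-token IOB2 tags."""
    tags = [OUTSIDE] * n_tokens
    for m in sorted(mentions):
        if m.end > n_tokens:
            raise ValueError(f"mention {m} exceeds report length {n_tokens}")
        if any(t != OUTSIDE for t in tags[m.start : m.end]):
            raise ValueError(f"overlapping mention {m}")
        tags[m.start] = f"B-{m.entity}"
        for i in range(m.start + 1, m.end):
            tags[i] = f"I-{m.entity}"
    return tags


def iob2_to_mentions(tags: Sequence[str], source: str = "gold") -> list[Mention]:
    """Decode IOB2 tags to mentions; exact inverse of :func:`mentions_to_iob2`
    on valid input.

    Model output need not be IOB2-valid: a stray ``I-e`` whose predecessor is
    not ``B-e``/``I-e`` of the same entity opens a new mention.
    """
    mentions: list[Mention] = []
    start = None
    entity = None
    for i, tag in enumerate(tags):
        if tag == OUTSIDE:
            if start is not None:
                mentions.append(Mention(start, i, entity, source))
                start, entity = None, None
            continue
        prefix, ent = tag.split("-", 1)
        if prefix == "B" or ent != entity:
            if start is not None:
                mentions.append(Mention(start, i, entity, source))
            start, entity = i, ent
    if start is not None:
        mentions.append(Mention(start, len(tags), entity, source))
    return mentions


def is_iob2_valid(tags: Sequence[str]) -> bool:
    prev = OUTSIDE
    for tag in tags:
        if tag.startswith("I-"):
            ent = tag[2:]
            if prev not in (f"B-{ent}", f"I-{ent}"):
                return False
        prev = tag
    return True
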