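"""Gazetteer pseudo-labeling: exact and fuzzy dictionary matching.

Every synonym is matched exactly against contiguous token windows.  Synonyms
whose single-space-joined form is at least 5 characters long (and not
flagged ``exact_only``) are additionally matched *fuzzily*: a window counts
as a hit when its joined character stream can be obtained from the synonym
by deleting exactly one character.  The deleted character may be a space, in
which case two tokens merge, so for a k-token synonym both k- and
(k-1)-token windows are candidates.  Only deletions are tolerated — no
insertions and no substitutions — because paramedic misspellings of this
kind ("asprin", "facial drop") are the dominant recoverable error mode,
while a looser edit-distance rule floods short clinical shorthand with
false positives.

Overlapping candidate matches are resolved greedily with a deterministic
total order: longer span first, exact before fuzzy, leftmost first, then
entity name.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .lexicon import Lexicon, Synonym
from .preprocessing import TokenizedReport
from .tags import Mention, mentions_to_iob2

__all__ = [
    "MatcherConfig",
    "match_exact",
    "match_fuzzy",
    "is_single_deletion",
    "resolve_overlaps",
    "weak_label",
    "weak_label_corpus",
]

FUZZY_MIN_CHARS = 5


@dataclass(frozen=True)
class MatcherConfig:
    """Labeling policy knobs.

    ``fuzzy_min_chars`` gates fuzzy matching by the joined length of the
    synonym; ``allow_substitutions`` widens the fuzzy rule from
    one-deletion to Levenshtein distance 1 (off by default).
    """

    fuzzy: bool = True
    fuzzy_min_chars: int = FUZZY_MIN_CHARS
    allow_substitutions: bool = False


def match_exact(
    tokens: Sequence[str], phrase: Sequence[str]
) -> list[tuple[int, int]]:
    """All windows where *phrase* equals a contiguous token window."""
    if not phrase:
        raise ValueError("empty phrase")
    k = len(phrase)
    phrase = tuple(phrase)
    return [
        (i, i + k)
        for i in range(len(tokens) - k + 1)
        if tuple(tokens[i : i + k]) == phrase
    ]


def is_single_deletion(shorter: str, longer: str) -> bool:
    """True iff *shorter* equals *longer* with exactly one character deleted."""
    if len(shorter) != len(longer) - 1:
        return False
    i = 0
    while i < len(shorter) and shorter[i] == longer[i]:
        i += 1
    return shorter[i:] == longer[i + 1 :]


def _is_levenshtein_one(a: str, b: str) -> bool:
    if a == b:
        return False
    if len(a) == len(b):  # one substitution
        return sum(x != y for x, y in zip(a, b)) == 1
    if len(a) > len(b):
        a, b = b, a
    return is_single_deletion(a, b)


def match_fuzzy(
    tokens: Sequence[str],
    phrase: Sequence[str],
    *,
    min_chars: int = FUZZY_MIN_CHARS,
    allow_substitutions: bool = False,
) -> list[tuple[int, int]]:
    """Windows whose joined text equals the joined phrase or is the phrase
    with one character deleted; matches align with token boundaries.

    Raises ``ValueError`` when the joined phrase is shorter than
    ``min_chars`` — short synonyms must go through :func:`match_exact`.
    """
    joined = " ".join(phrase)
    if len(joined) < min_chars:
        raise ValueError(
            f"phrase {joined!r} shorter than {min_chars} chars; fuzzy matching "
            "is restricted to longer synonyms"
        )
    k = len(phrase)
    L = len(joined)
    lengths = {L, L - 1}
    if allow_substitutions:
        lengths.add(L + 1)
    hits = []
    for width in (k, k - 1) if k > 1 else (k,):
        for i in range(len(tokens) - width + 1):
            window = " ".join(tokens[i : i + width])
            if len(window) not in lengths:
                continue
            if window == joined or is_single_deletion(window, joined):
                hits.append((i, i + width))
            elif allow_substitutions and _is_levenshtein_one(window, joined):
                hits.append((i, i + width))
    return sorted(set(hits))


_SOURCE_RANK = {"exact": 0, "fuzzy": 1}


def resolve_overlaps(
    matches: Sequence[tuple[int, int, str, str]]
) -> list[Mention]:
    """Greedy non-overlapping selection from ``(start, end, entity, source)``
    candidates: longest span first, exact before fuzzy, leftmost, then
    lexicographic entity name.  Returns mentions sorted by start."""
    ordered = sorted(
        set(matches),
        key=lambda m: (-(m[1] - m[0]), _SOURCE_RANK.get(m[3], 2), m[0], m[2]),
    )
    accepted: list[Mention] = []
    for start, end, entity, source in ordered:
        cand = Mention(start, end, entity, source)
        if not any(cand.overlaps(a) for a in accepted):
            accepted.append(cand)
    return sorted(accepted)


def weak_label(
    report: TokenizedReport,
    lexicon: Lexicon,
    config: MatcherConfig = MatcherConfig(),
) -> tuple[list[str], list[Mention]]:
    """Pseudo-label one tokenized report against the gazetteer.

    Returns the IOB2 tag sequence and the resolved mention list.
    """
    tokens = report.tokens
    candidates: list[tuple[int, int, str, str]] = []
    for entity, synonyms in lexicon.items():
        for syn in synonyms:
            exact_spans = match_exact(tokens, syn.tokens)
            candidates += [(s, e, entity, "exact") for s, e in exact_spans]
            if (
                config.fuzzy
                and not syn.exact_only
                and len(syn.joined) >= config.fuzzy_min_chars
            ):
                fuzzy_spans = match_fuzzy(
                    tokens,
                    syn.tokens,
                    min_chars=config.fuzzy_min_chars,
                    allow_substitutions=config.allow_substitutions,
                )
                exact_set = set(exact_spans)
                candidates += [
                    (s, e, entity, "fuzzy")
                    for s, e in fuzzy_spans
                    if (s, e) not in exact_set
                ]
    mentions = resolve_overlaps(candidates)
    return mentions_to_iob2(mentions, len(tokens)), mentions


def weak_label_corpus(
    reports: Sequence[TokenizedReport],
    lexicon: Lexicon,
    config: MatcherConfig = MatcherConfig(),
) -> list[tuple[TokenizedReport, list[str]]]:
    return [(rep, weak_label(rep, lexicon, config)[0]) for rep in reports]
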