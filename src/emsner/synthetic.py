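"""Synthetic paramedic-report generator with known gold entity spans.

Real EMS narratives are restricted data, so this module emulates their
telegraphic style: short reports assembled from entity-free clinical filler
phrases with gazetteer surface forms planted at known token spans.  Entity
relative frequencies default to the mix observed in a large real EMS corpus
(ECG-dominated, roughly half of all mentions), report lengths are uniform
over 30-120 tokens, and a configurable fraction of plantable mentions carry
a single-character-deletion misspelling — the error mode the fuzzy matcher
is built to absorb.

The filler bank is entity-free *by construction*: no filler token occurs in
any gazetteer synonym, and a build-time validator re-scans filler phrases
(and their concatenations) with the weak labeler to prove that no filler
window matches, exactly or fuzzily.  Gold spans are therefore exhaustive
and generator output can serve as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataset import Corpus
from .lexicon import Lexicon, Synonym, starter_lexicon
from .preprocessing import TokenizedReport, normalize_text
from .tags import Mention, mentions_to_iob2
from .weak_labeler import MatcherConfig, weak_label

__all__ = [
    "GeneratorConfig",
    "SyntheticReport",
    "DEFAULT_ENTITY_WEIGHTS",
    "DEFAULT_FILLERS",
    "inject_misspelling",
    "sample_report",
    "generate_corpus",
    "validate_fillers",
]

#: Relative mention frequencies (percent) mirroring the training mix of a
#: real EMS audit corpus; normalized before sampling.
DEFAULT_ENTITY_WEIGHTS: dict[str, float] = {
    "ECG": 50.6,
    "Stroke Assessment": 12.5,
    "Intravenous Cannulation": 3.9,
    "Burns Cooling": 0.1,
    "Valsalva Maneuver": 0.1,
    "Bleeding": 14.1,
    "Signs Of Obvious Death": 0.6,
    "Nitroglycerin (GTN)": 5.0,
    "Aspirin": 3.1,
    "Normal Saline": 2.6,
    "Penthrox": 1.1,
    "Dextrose/Glucose": 0.8,
    "Adrenaline": 0.8,
    "Diazepam": 0.7,
    "Salbutamol": 3.4,
    "Tramadol": 0.6,
    "Syntometrine": 0.1,
}

#: Entity-free filler phrases in paramedic-shorthand style.  Tokens are
#: chosen to be disjoint from every gazetteer synonym token.
DEFAULT_FILLERS: tuple[str, ...] = (
    "hx from pt",
    "pt sitting conscious alert",
    "no trauma no fall",
    "pt complains chest pain crushing in nature non radiating",
    "o a pt lying on bed",
    "o p pt not pallor or diaphoretic",
    "no sob giddiness nausea vomitting",
    "afebrile",
    "sinus rhythm seen",
    "no other medical complaints",
    "noted pt turns lethargic but able to enunciate words clearly",
    "tried to feed pt water and noted dysphagia drooling",
    "went to see gp this morning",
    "gcs 15 slight dementia",
    "no bilateral weakness",
    "pt off hypertension med for long time",
    "usual bp 115 57",
    "pt fell due to slippery floor",
    "unsure hit what object no loc",
    "noted 3 cm laceration",
    "noted dislocated rt shoulder",
    "pt claimed numbness due to old fall",
    "did not see dr",
    "pt unable to give further hx",
    "he does not wish to talk much",
    "stat dose given with total relief",
    "vitals stable throughout conveyance",
    "pt ambulant at scene",
    "nil drug allergies known",
    "family members present at scene",
)

#: mentions-per-report probabilities for 0..4 mentions (mean ~1.2)
_DEFAULT_MENTION_DIST: tuple[float, ...] = (0.25, 0.45, 0.18, 0.08, 0.04)


@dataclass
class GeneratorConfig:
    n_reports: int = 2000
    entity_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ENTITY_WEIGHTS)
    )
    mention_dist: tuple[float, ...] = _DEFAULT_MENTION_DIST
    misspell_prob: float = 0.05
    substitution_prob: float = 0.0  # unrecoverable error mode, off by default
    length_range: tuple[int, int] = (30, 120)
    fillers: tuple[str, ...] = DEFAULT_FILLERS
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.entity_weights or all(w == 0 for w in self.entity_weights.values()):
            raise ValueError("entity_weights must have positive mass")
        if any(w < 0 for w in self.entity_weights.values()):
            raise ValueError("entity_weights must be non-negative")
        for p in (self.misspell_prob, self.substitution_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SyntheticReport:
    """A generated report with exhaustive gold spans and per-mention
    provenance sufficient to reconstruct the clean surface form."""

    report: TokenizedReport
    gold: list[Mention]
    provenance: list[dict]

    @property
    def tags(self) -> list[str]:
        return mentions_to_iob2(self.gold, len(self.report.tokens))


def _deletable_positions(joined: str) -> list[int]:
    """Positions whose removal shortens the normalized joined surface by
    exactly one character.

    Deleting the sole character of a single-character token would also
    collapse an adjacent space — a two-character change that the
    one-missing-character error model cannot represent — so such positions
    are excluded.
    """
    out = []
    for i in range(len(joined)):
        cand = normalize_text(joined[:i] + joined[i + 1 :])
        if len(cand) == len(joined) - 1:
            out.append(i)
    return out


def inject_misspelling(
    surface_tokens: Sequence[str], rng: np.random.Generator
) -> tuple[list[str], int | None]:
    """Delete one character, uniformly over deletable positions of the
    single-space-joined surface; a deleted space merges two tokens.

    Surfaces shorter than 5 joined characters are returned unchanged
    (mirroring the fuzzy matcher's gate).
    """
    joined = " ".join(surface_tokens)
    if len(joined) < 5:
        return list(surface_tokens), None
    positions = _deletable_positions(joined)
    pos = int(rng.choice(positions))
    mutated = normalize_text(joined[:pos] + joined[pos + 1 :])
    return mutated.split(" "), pos


def _inject_substitution(
    surface_tokens: Sequence[str], rng: np.random.Generator
) -> tuple[list[str], int | None]:
    """Replace one letter with a different one — the misspelling mode the
    one-deletion matcher is expected to miss."""
    joined = " ".join(surface_tokens)
    letters = [i for i, ch in enumerate(joined) if ch.isalpha()]
    if len(joined) < 5 or not letters:
        return list(surface_tokens), None
    pos = int(rng.choice(letters))
    alphabet = "abcdefghijklmnopqrstuvwxyz".replace(joined[pos], "")
    repl = alphabet[int(rng.integers(len(alphabet)))]
    mutated = joined[:pos] + repl + joined[pos + 1 :]
    return mutated.split(" "), pos


def _fuzzy_eligible(syn: Synonym, matcher: MatcherConfig) -> bool:
    return (
        not syn.exact_only and len(syn.joined) >= matcher.fuzzy_min_chars
    )


def sample_report(
    lexicon: Lexicon,
    config: GeneratorConfig,
    rng: np.random.Generator,
    report_id: str = "synthetic-0",
) -> SyntheticReport:
    """Assemble one report: filler phrases up to the target length, with
    sampled entity surface forms planted at random gaps (never adjacent to
    each other)."""
    entities = [e for e in config.entity_weights if e in lexicon.synonyms]
    weights = np.array([config.entity_weights[e] for e in entities], dtype=float)
    weights /= weights.sum()
    matcher = MatcherConfig()

    n_mentions = int(
        rng.choice(len(config.mention_dist), p=np.asarray(config.mention_dist) /
                   np.sum(config.mention_dist))
    )
    target_len = int(rng.integers(config.length_range[0], config.length_range[1] + 1))

    filler_tokens: list[list[str]] = []
    total = 0
    while total < target_len:
        phrase = config.fillers[int(rng.integers(len(config.fillers)))]
        toks = phrase.split(" ")
        filler_tokens.append(toks)
        total += len(toks)

    # one mention per distinct gap between filler phrases, so planted
    # surface forms are always separated by at least one filler token
    n_gaps = max(len(filler_tokens) - 1, 0)
    n_mentions = min(n_mentions, n_gaps)
    gaps = sorted(rng.choice(n_gaps, size=n_mentions, replace=False)) if n_mentions else []

    mention_specs = []
    for gap in gaps:
        entity = entities[int(rng.choice(len(entities), p=weights))]
        syns = lexicon.phrases(entity)
        syn = syns[int(rng.integers(len(syns)))]
        tokens = list(syn.tokens)
        misspelled_at = None
        mode = None
        if _fuzzy_eligible(syn, matcher) and rng.random() < config.misspell_prob:
            tokens, misspelled_at = inject_misspelling(tokens, rng)
            mode = "deletion"
        elif config.substitution_prob and rng.random() < config.substitution_prob:
            tokens, misspelled_at = _inject_substitution(tokens, rng)
            mode = "substitution" if misspelled_at is not None else None
        mention_specs.append((gap, entity, syn, tokens, misspelled_at, mode))

    out_tokens: list[str] = []
    gold: list[Mention] = []
    provenance: list[dict] = []
    spec_idx = 0
    for i, toks in enumerate(filler_tokens):
        out_tokens.extend(toks)
        while spec_idx < len(mention_specs) and mention_specs[spec_idx][0] == i:
            gap, entity, syn, mtoks, pos, mode = mention_specs[spec_idx]
            start = len(out_tokens)
            out_tokens.extend(mtoks)
            gold.append(Mention(start, len(out_tokens), entity, source="gold"))
            provenance.append(
                {
                    "entity": entity,
                    "synonym": syn.joined,
                    "misspelled": pos is not None,
                    "mode": mode,
                    "deleted_position": pos,
                }
            )
            spec_idx += 1
    return SyntheticReport(
        TokenizedReport(report_id, tuple(out_tokens)), gold, provenance
    )


def validate_fillers(
    fillers: Sequence[str], lexicon: Lexicon, matcher: MatcherConfig = MatcherConfig()
) -> None:
    """Prove the filler bank entity-free: weak-label every filler phrase and
    every ordered pair of phrases; any hit is a configuration error."""
    phrases = [f.split(" ") for f in fillers]
    for f in fillers:
        if f != normalize_text(f):
            raise ValueError(f"filler {f!r} is not normalized")
    candidates = [toks for toks in phrases]
    candidates += [a + b for a in phrases for b in phrases]
    for i, toks in enumerate(candidates):
        _, mentions = weak_label(
            TokenizedReport(f"filler-{i}", tuple(toks)), lexicon, matcher
        )
        if mentions:
            raise ValueError(
                f"filler text {' '.join(toks)!r} matches lexicon entries "
                f"{[m.entity for m in mentions]}; fillers must be entity-free"
            )


def generate_corpus(
    config: GeneratorConfig,
    lexicon: Lexicon | None = None,
    *,
    validate: bool = True,
) -> tuple[Corpus, list[SyntheticReport]]:
    """Generate ``config.n_reports`` reports with gold IOB2 tags.

    Deterministic under ``config.seed``.  Returns the gold-labeled corpus
    and the per-report provenance records.
    """
    lexicon = lexicon or starter_lexicon()
    if validate:
        validate_fillers(config.fillers, lexicon)
    rng = np.random.default_rng(config.seed)
    synth: list[SyntheticReport] = []
    for i in range(config.n_reports):
        synth.append(sample_report(lexicon, config, rng, report_id=f"synthetic-{i}"))
    corpus = Corpus([(s.report, s.tags) for s in synth])
    return corpus, synth
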