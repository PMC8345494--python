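"""Corpus management: CoNLL I/O, splits, vocabulary, padding, statistics.

A corpus is a list of ``(TokenizedReport, tags)`` pairs.  On disk it is a
CoNLL-2003-style two-column file — ``token<TAB>tag`` per line, a blank line
between reports — which round-trips exactly.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .lexicon import DEFAULT_SCHEMA, EntitySchema
from .preprocessing import TokenizedReport
from .tags import OUTSIDE, Mention, iob2_to_mentions

__all__ = [
    "Corpus",
    "Vocab",
    "round_half_up",
    "read_conll",
    "write_conll",
    "split_corpus",
    "corpus_stats",
    "build_vocab",
    "pad_batch",
    "aggregate_subtoken_tags",
]

PAD = "<pad>"
UNK = "<unk>"


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero), matching
    the rounding used in the printed corpus and metric tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class Corpus:
    """Labeled reports; ``tags[i]`` aligns with ``reports[i].tokens``."""

    reports: list[tuple[TokenizedReport, list[str]]]
    split_tag: str | None = None

    def __post_init__(self) -> None:
        for rep, tags in self.reports:
            if len(rep.tokens) != len(tags):
                raise ValueError(
                    f"report {rep.report_id!r}: {len(rep.tokens)} tokens "
                    f"vs {len(tags)} tags"
                )

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self):
        return iter(self.reports)

    def mentions(self) -> list[list[Mention]]:
        return [iob2_to_mentions(tags) for _, tags in self.reports]


# ---------------------------------------------------------------------------
# CoNLL two-column I/O


def write_conll(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rep, tags in corpus:
            fh.write(f"# id {rep.report_id}\n")
            for tok, tag in zip(rep.tokens, tags):
                fh.write(f"{tok}\t{tag}\n")
            fh.write("\n")


def read_conll(path: str | Path) -> Corpus:
    reports: list[tuple[TokenizedReport, list[str]]] = []
    tokens: list[str] = []
    tags: list[str] = []
    rid: str | None = None

    def flush() -> None:
        nonlocal tokens, tags, rid
        if tokens:
            ident = rid if rid is not None else str(len(reports))
            reports.append((TokenizedReport(ident, tuple(tokens)), tags))
        tokens, tags, rid = [], [], None

    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                flush()
            elif line.startswith("# id "):
                rid = line[5:]
            else:
                tok, tag = line.split("\t")
                tokens.append(tok)
                tags.append(tag)
    flush()
    return Corpus(reports)


# ---------------------------------------------------------------------------
# Splitting


def split_corpus(
    corpus: Corpus,
    fractions: tuple[float, float, float] = (0.95, 0.025, 0.025),
    seed: int = 0,
) -> tuple[Corpus, Corpus, Corpus]:
    """Random disjoint train/dev/test split.

    Dev and test sizes come from cumulative half-up rounding of the
    non-train fractions; the remainder goes to train (so for 44,211 reports
    at 95/2.5/2.5 the sizes are 42,000 / 1105 / 1106).  Deterministic under
    ``seed``.
    """
    f_train, f_dev, f_test = fractions
    if any(f <= 0 for f in fractions) or not math.isclose(sum(fractions), 1.0):
        raise ValueError(f"fractions must be positive and sum to 1: {fractions}")
    n = len(corpus)
    n_dev = int(round_half_up(n * f_dev))
    n_test = int(round_half_up(n * (f_dev + f_test))) - n_dev
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    dev_idx = set(order[:n_dev])
    test_idx = set(order[n_dev : n_dev + n_test])
    parts: dict[str, list] = {"train": [], "dev": [], "test": []}
    for i, item in enumerate(corpus.reports):
        key = "dev" if i in dev_idx else "test" if i in test_idx else "train"
        parts[key].append(item)
    return (
        Corpus(parts["train"], "train"),
        Corpus(parts["dev"], "dev"),
        Corpus(parts["test"], "test"),
    )


# ---------------------------------------------------------------------------
# Corpus statistics (mention counts, token counts, ATE, shares)


def corpus_stats(corpus: Corpus, schema: EntitySchema = DEFAULT_SCHEMA) -> pd.DataFrame:
    """Per-entity mention counts, shares, entity-token counts and ATE
    (average number of tokens per entity mention).

    The returned frame has one row per schema entity; ``ATE`` is rounded half-up to 2 decimals and ``% of Total`` to one
    decimal percent.  Attrs carry the overall entity-token fraction.
    """
    mention_count: Counter[str] = Counter()
    token_count: Counter[str] = Counter()
    total_tokens = 0
    for (rep, tags), mentions in zip(corpus, corpus.mentions()):
        total_tokens += len(rep.tokens)
        for m in mentions:
            mention_count[m.entity] += 1
            token_count[m.entity] += m.length
    total_mentions = sum(mention_count.values())
    total_entity_tokens = sum(token_count.values())
    rows = []
    for entity in schema.entities:
        n_m = mention_count.get(entity, 0)
        n_t = token_count.get(entity, 0)
        rows.append(
            {
                "Category": schema.category[entity],
                "Entity": entity,
                "Entities": n_m,
                "% of Total": round_half_up(100 * n_m / total_mentions, 1)
                if total_mentions
                else 0.0,
                "Tokens": n_t,
                "ATE": round_half_up(n_t / n_m, 2) if n_m else float("nan"),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["total_mentions"] = total_mentions
    df.attrs["total_entity_tokens"] = total_entity_tokens
    df.attrs["total_tokens"] = total_tokens
    df.attrs["entity_token_fraction"] = (
        total_entity_tokens / total_tokens if total_tokens else 0.0
    )
    return df


# ---------------------------------------------------------------------------
# Vocabulary and batching


@dataclass(frozen=True)
class Vocab:
    """Dense token->index map with reserved padding (0) and unknown (1)."""

    index: dict[str, int]

    @property
    def pad_index(self) -> int:
        return self.index[PAD]

    @property
    def unk_index(self) -> int:
        return self.index[UNK]

    def __len__(self) -> int:
        return len(self.index)

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        unk = self.unk_index
        return np.array([self.index.get(t, unk) for t in tokens], dtype=np.int64)


def build_vocab(train_corpus: Corpus, min_count: int = 1) -> Vocab:
    """Vocabulary from the training split only (no dev/test leakage)."""
    counts: Counter[str] = Counter()
    for rep, _ in train_corpus:
        counts.update(rep.tokens)
    index = {PAD: 0, UNK: 1}
    for tok, c in sorted(counts.items()):
        if c >= min_count:
            index[tok] = len(index)
    return Vocab(index)


def pad_batch(
    encoded: Sequence[np.ndarray],
    max_len: int | None = None,
    pad_index: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack variable-length index sequences into a fixed-shape batch.

    Returns ``(batch, mask)`` of shape (B, L); padding positions carry
    ``pad_index`` and mask 0.  Sequences longer than ``max_len`` are
    truncated with a warning.
    """
    if max_len is None:
        max_len = max(len(e) for e in encoded)
    batch = np.full((len(encoded), max_len), pad_index, dtype=np.int64)
    mask = np.zeros((len(encoded), max_len), dtype=bool)
    for i, seq in enumerate(encoded):
        if len(seq) > max_len:
            warnings.warn(
                f"sequence of length {len(seq)} truncated to {max_len}",
                stacklevel=2,
            )
            seq = seq[:max_len]
        batch[i, : len(seq)] = seq
        mask[i, : len(seq)] = True
    return batch, mask


def aggregate_subtoken_tags(
    subtoken_tags: Sequence[str], by_entity_type: bool = False
) -> str:
    """Collapse per-subtoken predictions for one word to a single tag:
    majority vote over non-``O`` tags (all-``O`` words stay ``O``), ties
    broken by first occurrence.

    With ``by_entity_type`` the vote pools ``B-``/``I-`` of the same entity
    and returns the first-seen tag of the winning entity.
    """
    if not subtoken_tags:
        raise ValueError("no subtoken tags for word")
    key = (lambda t: t.split("-", 1)[1]) if by_entity_type else (lambda t: t)
    votes: Counter[str] = Counter()
    first_seen: dict[str, str] = {}
    order: dict[str, int] = {}
    for tag in subtoken_tags:
        if tag == OUTSIDE:
            continue
        k = key(tag)
        votes[k] += 1
        first_seen.setdefault(k, tag)
        order.setdefault(k, len(order))
    if not votes:
        return OUTSIDE
    best = max(votes, key=lambda k: (votes[k], -order[k]))
    return first_seen[best]
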