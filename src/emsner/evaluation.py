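"""Entity-level MUC-5 scoring (strict and entity-type-matching modes) and
token-level weighted metrics.

Each *prediction* is independently categorized against the gold mentions of
its report:

* exact span + type match -> COR in both modes;
* overlapping span (>= 1 shared token), same type -> COR under
  entity-type matching, INC under strict evaluation;
* overlapping span, different type -> INC in both modes;
* no overlap with any gold mention -> SPU.

A gold mention with no overlapping prediction adds one MIS.  Because a gold
mention overlapped by several predictions is counted once per prediction,
POS = COR + INC + PAR + MIS can exceed the number of gold mentions.  PAR is
never populated in the two implemented modes.

From the tallies: P = COR/ACT, R = COR/POS, F1 = 2PR/(P+R), with
ACT = COR + INC + PAR + SPU and POS = COR + INC + PAR + MIS.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .dataset import Corpus, round_half_up
from .tags import OUTSIDE, Mention

__all__ = [
    "STRICT",
    "TYPE_MATCHING",
    "MucCounts",
    "EntityMetrics",
    "muc_align",
    "semeval_metrics",
    "token_metrics",
    "evaluate_corpus",
    "EvaluationReport",
]

STRICT = "strict"
TYPE_MATCHING = "type_matching"
_MODES = (STRICT, TYPE_MATCHING)


@dataclass
class MucCounts:
    """MUC-5 per-prediction category tallies."""

    COR: int = 0
    INC: int = 0
    PAR: int = 0
    MIS: int = 0
    SPU: int = 0

    def __post_init__(self) -> None:
        if min(self.COR, self.INC, self.PAR, self.MIS, self.SPU) < 0:
            raise ValueError("MUC counts must be non-negative")

    @property
    def POS(self) -> int:
        """Recall denominator: gold-side comparisons (COR+INC+PAR+MIS)."""
        return self.COR + self.INC + self.PAR + self.MIS

    @property
    def ACT(self) -> int:
        """Precision denominator: system annotations (COR+INC+PAR+SPU)."""
        return self.COR + self.INC + self.PAR + self.SPU

    def __add__(self, other: "MucCounts") -> "MucCounts":
        return MucCounts(
            self.COR + other.COR,
            self.INC + other.INC,
            self.PAR + other.PAR,
            self.MIS + other.MIS,
            self.SPU + other.SPU,
        )


@dataclass(frozen=True)
class EntityMetrics:
    precision: float
    recall: float
    f1: float
    mode: str = TYPE_MATCHING

    def rounded(self, decimals: int = 3) -> "EntityMetrics":
        return EntityMetrics(
            round_half_up(self.precision, decimals),
            round_half_up(self.recall, decimals),
            round_half_up(self.f1, decimals),
            self.mode,
        )


def muc_align(
    gold: Sequence[Mention], pred: Sequence[Mention], mode: str
) -> MucCounts:
    """Categorize one report's predictions against its gold mentions."""
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {_MODES}")
    counts = MucCounts()
    gold = sorted(gold)
    touched = [False] * len(gold)
    for p in sorted(pred):
        overlapping = [i for i, g in enumerate(gold) if p.overlaps(g)]
        if not overlapping:
            counts.SPU += 1
            continue
        # categorize against the first overlapping gold in span order
        i = overlapping[0]
        touched[i] = True
        g = gold[i]
        if p.start == g.start and p.end == g.end and p.entity == g.entity:
            counts.COR += 1
        elif p.entity == g.entity and mode == TYPE_MATCHING:
            counts.COR += 1
        else:
            counts.INC += 1
    counts.MIS += sum(not t for t in touched)
    return counts


def semeval_metrics(counts: MucCounts, mode: str = TYPE_MATCHING) -> EntityMetrics:
    """Precision, recall and F1 from MUC-5 tallies (full precision; use
    ``.rounded()`` for display at 3 decimals)."""
    if counts.ACT == 0 or counts.POS == 0:
        if counts.ACT == 0:
            warnings.warn("ACT = 0: precision undefined, reported as 0", stacklevel=2)
        if counts.POS == 0:
            warnings.warn("POS = 0: recall undefined, reported as 0", stacklevel=2)
    p = counts.COR / counts.ACT if counts.ACT else 0.0
    r = counts.COR / counts.POS if counts.POS else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return EntityMetrics(p, r, f1, mode)


def token_metrics(
    gold_tags: Sequence[Sequence[str]], pred_tags: Sequence[Sequence[str]]
) -> pd.DataFrame:
    """Token-level precision/recall/F1 per tag class, with the weighted
    average over every class except ``O``.

    Weights are the gold support of each non-``O`` class; ``O`` never
    contributes to the weights or the averages.  Returns one row per
    observed class plus a ``weighted`` row; full precision.
    """
    tp: Counter[str] = Counter()
    fp: Counter[str] = Counter()
    fn: Counter[str] = Counter()
    support: Counter[str] = Counter()
    for g_seq, p_seq in zip(gold_tags, pred_tags):
        if len(g_seq) != len(p_seq):
            raise ValueError("gold and predicted tag sequences differ in length")
        for g, p in zip(g_seq, p_seq):
            support[g] += 1
            if g == p:
                tp[g] += 1
            else:
                fn[g] += 1
                fp[p] += 1
    classes = sorted((set(support) | set(fp)) - {OUTSIDE})
    rows = []
    for c in classes:
        prec = tp[c] / (tp[c] + fp[c]) if tp[c] + fp[c] else 0.0
        rec = tp[c] / (tp[c] + fn[c]) if tp[c] + fn[c] else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        rows.append(
            {"class": c, "precision": prec, "recall": rec, "f1": f1,
             "support": support[c]}
        )
    total = sum(r["support"] for r in rows)
    if total:
        rows.append(
            {
                "class": "weighted",
                "precision": sum(r["precision"] * r["support"] for r in rows) / total,
                "recall": sum(r["recall"] * r["support"] for r in rows) / total,
                "f1": sum(r["f1"] * r["support"] for r in rows) / total,
                "support": total,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    """Both evaluation modes' tallies and metrics, a per-entity breakdown
    (entity-type-matching mode) and the token-level table."""

    counts: dict[str, MucCounts]
    metrics: dict[str, EntityMetrics]
    per_entity: dict[str, MucCounts]
    token_table: pd.DataFrame

    def to_table(self, model: str = "BiLSTM-CRF") -> pd.DataFrame:
        """Render the entity-level results as one row per mode, shaped like
        the standard NER results table."""
        rows = []
        for mode in _MODES:
            c, m = self.counts[mode], self.metrics[mode].rounded()
            rows.append(
                {
                    "Evaluation Mode": "Entity Type Matching"
                    if mode == TYPE_MATCHING
                    else "Strict Evaluation",
                    "Model": model,
                    "COR": c.COR, "INC": c.INC, "MIS": c.MIS, "SPU": c.SPU,
                    "POS": c.POS, "ACT": c.ACT,
                    "Precision": m.precision, "Recall": m.recall, "F1-Score": m.f1,
                }
            )
        return pd.DataFrame(rows)


def evaluate_corpus(gold: Corpus, pred: Corpus) -> EvaluationReport:
    """Score a predicted corpus against gold, report-by-report.

    Reports are aligned by id; a mismatch raises with the offending ids.
    """
    gold_ids = [rep.report_id for rep, _ in gold]
    pred_ids = [rep.report_id for rep, _ in pred]
    if gold_ids != pred_ids:
        offenders = sorted(set(gold_ids).symmetric_difference(pred_ids)) or [
            "(same ids, different order)"
        ]
        raise ValueError(f"gold/pred report ids do not align: {offenders[:10]}")
    counts = {mode: MucCounts() for mode in _MODES}
    per_entity: dict[str, MucCounts] = {}
    gold_mentions = gold.mentions()
    pred_mentions = pred.mentions()
    for g_men, p_men in zip(gold_mentions, pred_mentions):
        for mode in _MODES:
            counts[mode] += muc_align(g_men, p_men, mode)
        entities = {m.entity for m in g_men} | {m.entity for m in p_men}
        for ent in entities:
            per_entity.setdefault(ent, MucCounts())
            per_entity[ent] += muc_align(
                [m for m in g_men if m.entity == ent],
                [m for m in p_men if m.entity == ent],
                TYPE_MATCHING,
            )
    metrics = {mode: semeval_metrics(counts[mode], mode) for mode in _MODES}
    token_table = token_metrics(
        [tags for _, tags in gold], [tags for _, tags in pred]
    )
    return EvaluationReport(counts, metrics, per_entity, token_table)
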