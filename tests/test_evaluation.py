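"""MUC-5 categorization and SemEval'13 metrics, with independent oracles."""

import numpy as np
import pytest

from emsner.dataset import Corpus
from emsner.evaluation import (
    STRICT,
    TYPE_MATCHING,
    MucCounts,
    evaluate_corpus,
    muc_align,
    semeval_metrics,
    token_metrics,
)
from emsner.preprocessing import TokenizedReport
from emsner.tags import Mention, mentions_to_iob2


def reference_muc(gold, pred, mode):
    """Independent re-implementation of the prediction-driven MUC-5
    categorization, written directly from the category definitions."""
    gold = sorted(gold)
    counts = dict(COR=0, INC=0, MIS=0, SPU=0)
    used = set()
    for p in sorted(pred):
        over = [g for g in gold if max(p.start, g.start) < min(p.end, g.end)]
        if not over:
            counts["SPU"] += 1
            continue
        g = over[0]
        used.add((g.start, g.end, g.entity))
        exact = (p.start, p.end, p.entity) == (g.start, g.end, g.entity)
        if exact or (mode == TYPE_MATCHING and p.entity == g.entity):
            counts["COR"] += 1
        else:
            counts["INC"] += 1
    counts["MIS"] = sum(
        (g.start, g.end, g.entity) not in used for g in gold
    )
    return counts


@pytest.mark.parametrize(
    "gold,pred,mode,expected",
    [
        ([Mention(0, 3, "ECG")], [Mention(0, 3, "ECG")], STRICT,
         dict(COR=1, INC=0, MIS=0, SPU=0)),
        ([Mention(0, 3, "ECG")], [Mention(0, 3, "ECG")], TYPE_MATCHING,
         dict(COR=1, INC=0, MIS=0, SPU=0)),
        ([Mention(0, 3, "ECG")], [Mention(1, 3, "ECG")], TYPE_MATCHING,
         dict(COR=1, INC=0, MIS=0, SPU=0)),
        ([Mention(0, 3, "ECG")], [Mention(1, 3, "ECG")], STRICT,
         dict(COR=0, INC=1, MIS=0, SPU=0)),
        ([Mention(0, 3, "ECG")], [Mention(5, 6, "Aspirin")], STRICT,
         dict(COR=0, INC=0, MIS=1, SPU=1)),
        # one gold overlapped by two predictions is counted twice: POS > gold
        ([Mention(0, 3, "ECG")], [Mention(0, 1, "ECG"), Mention(2, 3, "ECG")],
         TYPE_MATCHING, dict(COR=2, INC=0, MIS=0, SPU=0)),
        # overlapping span, wrong type, is INC in both modes
        ([Mention(0, 3, "ECG")], [Mention(1, 3, "Aspirin")], TYPE_MATCHING,
         dict(COR=0, INC=1, MIS=0, SPU=0)),
    ],
)
def test_muc_align_cases(gold, pred, mode, expected):
    counts = muc_align(gold, pred, mode)
    assert dict(COR=counts.COR, INC=counts.INC, MIS=counts.MIS, SPU=counts.SPU) == expected
    assert counts.PAR == 0


def test_muc_align_rejects_unknown_mode():
    with pytest.raises(ValueError, match="mode"):
        muc_align([], [], "partial")


def test_muc_align_agrees_with_reference_on_random_sets(rng):
    """Cross-check against the independent reference scorer on 100 random
    small mention configurations."""
    entities = ["ECG", "Aspirin", "Bleeding"]
    for _ in range(100):
        def sample():
            out = []
            pos = 0
            while pos < 12 and rng.random() < 0.7:
                start = pos + int(rng.integers(0, 3))
                end = start + int(rng.integers(1, 4))
                if end > 14:
                    break
                out.append(Mention(start, end, entities[rng.integers(3)]))
                pos = end + int(rng.integers(0, 2))
            return out

        gold, pred = sample(), sample()
        for mode in (STRICT, TYPE_MATCHING):
            counts = muc_align(gold, pred, mode)
            ref = reference_muc(gold, pred, mode)
            assert dict(
                COR=counts.COR, INC=counts.INC, MIS=counts.MIS, SPU=counts.SPU
            ) == ref


def test_count_conservation_and_mode_dominance(rng):
    entities = ["ECG", "Aspirin"]
    for _ in range(50):
        gold = [Mention(i * 4, i * 4 + int(rng.integers(1, 3)), entities[rng.integers(2)])
                for i in range(rng.integers(0, 4))]
        pred = [Mention(i * 4 + int(rng.integers(0, 2)),
                        i * 4 + int(rng.integers(2, 4)), entities[rng.integers(2)])
                for i in range(rng.integers(0, 4))]
        strict = muc_align(gold, pred, STRICT)
        typem = muc_align(gold, pred, TYPE_MATCHING)
        for c in (strict, typem):
            assert c.POS == c.COR + c.INC + c.MIS
            assert c.ACT == c.COR + c.INC + c.SPU
        assert typem.COR >= strict.COR
        assert semeval_metrics(typem).f1 >= semeval_metrics(strict).f1 - 1e-12


def test_symmetry_swapping_gold_and_pred():
    gold = [Mention(0, 2, "ECG"), Mention(5, 6, "Aspirin")]
    pred = [Mention(0, 2, "ECG"), Mention(8, 9, "Bleeding")]
    a = muc_align(gold, pred, STRICT)
    b = muc_align(pred, gold, STRICT)
    assert (a.MIS, a.SPU) == (b.SPU, b.MIS)
    ma, mb = semeval_metrics(a), semeval_metrics(b)
    assert ma.precision == pytest.approx(mb.recall)
    assert ma.recall == pytest.approx(mb.precision)


def test_semeval_metrics_zero_counts_warn():
    with pytest.warns(UserWarning):
        m = semeval_metrics(MucCounts())
    assert (m.precision, m.recall, m.f1) == (0.0, 0.0, 0.0)


def test_muc_counts_reject_negative():
    with pytest.raises(ValueError):
        MucCounts(COR=-1)


def test_token_metrics_perfect_and_all_outside():
    gold = [["B-ECG", "I-ECG", "O"]]
    assert token_metrics(gold, gold).iloc[-1][["precision", "recall", "f1"]].tolist() == [1, 1, 1]
    table = token_metrics(gold, [["O", "O", "O"]])
    weighted = table[table["class"] == "weighted"].iloc[0]
    assert weighted["recall"] == 0.0


def test_token_metrics_hand_worked_confusion():
    # gold: 3 B-ECG + 1 B-Aspirin + 2 O; predictions confuse one ECG token
    gold = [["B-ECG", "B-ECG", "B-ECG", "B-Aspirin", "O", "O"]]
    pred = [["B-ECG", "B-ECG", "B-Aspirin", "B-Aspirin", "O", "B-ECG"]]
    table = token_metrics(gold, pred).set_index("class")
    # ECG: tp=2, fp=1, fn=1 -> P=R=2/3; Aspirin: tp=1, fp=1, fn=0 -> P=1/2, R=1
    assert table.loc["B-ECG", "precision"] == pytest.approx(2 / 3)
    assert table.loc["B-ECG", "recall"] == pytest.approx(2 / 3)
    assert table.loc["B-Aspirin", "precision"] == pytest.approx(1 / 2)
    assert table.loc["B-Aspirin", "recall"] == pytest.approx(1.0)
    w = table.loc["weighted"]
    assert w["support"] == 4  # O excluded from the weights
    assert w["precision"] == pytest.approx((2 / 3 * 3 + 1 / 2 * 1) / 4)
    assert w["recall"] == pytest.approx((2 / 3 * 3 + 1.0 * 1) / 4)


def test_token_metrics_agree_with_sklearn(rng):
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    classes = ["O", "B-ECG", "I-ECG", "B-Aspirin"]
    gold = [[classes[i] for i in rng.integers(0, 4, size=30)]]
    pred = [[classes[i] for i in rng.integers(0, 4, size=30)]]
    table = token_metrics(gold, pred).set_index("class")
    labels = sorted(set(gold[0]) - {"O"})
    p, r, f, _ = sklearn_metrics.precision_recall_fscore_support(
        gold[0], pred[0], labels=labels, average="weighted", zero_division=0
    )
    w = table.loc["weighted"]
    assert w["precision"] == pytest.approx(p)
    assert w["recall"] == pytest.approx(r)
    assert w["f1"] == pytest.approx(f)


def make_corpus(rows):
    out = []
    for rid, n, mentions in rows:
        out.append((TokenizedReport(rid, ("x",) * n), mentions_to_iob2(mentions, n)))
    return Corpus(out)


def test_evaluate_corpus_identity_and_truncation():
    gold = make_corpus(
        [("a", 6, [Mention(1, 3, "ECG")]), ("b", 4, [Mention(0, 2, "Bleeding")])]
    )
    report = evaluate_corpus(gold, gold)
    assert report.metrics[STRICT].f1 == 1.0
    assert report.metrics[TYPE_MATCHING].f1 == 1.0
    # truncate every multi-token span by its final token: type matching
    # stays perfect, strict does not
    truncated = make_corpus(
        [("a", 6, [Mention(1, 2, "ECG")]), ("b", 4, [Mention(0, 1, "Bleeding")])]
    )
    report = evaluate_corpus(gold, truncated)
    assert report.metrics[TYPE_MATCHING].f1 == 1.0
    assert report.metrics[STRICT].f1 < 1.0


def test_evaluate_corpus_rejects_misaligned_ids():
    gold = make_corpus([("a", 3, [])])
    pred = make_corpus([("zzz", 3, [])])
    with pytest.raises(ValueError, match="zzz"):
        evaluate_corpus(gold, pred)


def test_report_table_shape():
    gold = make_corpus([("a", 6, [Mention(1, 3, "ECG")])])
    table = evaluate_corpus(gold, gold).to_table()
    assert list(table["Evaluation Mode"]) == ["Strict Evaluation", "Entity Type Matching"]
    assert set(table.columns) >= {"COR", "INC", "MIS", "SPU", "POS", "ACT",
                                  "Precision", "Recall", "F1-Score"}
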