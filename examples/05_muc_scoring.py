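"""MUC-5 categorization and SemEval'13 metrics on hand-made predictions.

Each prediction is categorized against the gold spans: COR (correct), INC
(incorrect), MIS (missed gold), SPU (spurious prediction).  Precision is
COR/ACT, recall COR/POS, with ACT = COR+INC+SPU and POS = COR+INC+MIS.
"""

from emsner import Mention, muc_align, semeval_metrics
from emsner.evaluation import STRICT, TYPE_MATCHING

gold = [Mention(0, 3, "ECG"), Mention(10, 11, "Aspirin")]
pred = [Mention(1, 3, "ECG"), Mention(10, 11, "Aspirin"), Mention(20, 21, "Bleeding")]

for mode in (STRICT, TYPE_MATCHING):
    counts = muc_align(gold, pred, mode)
    metrics = semeval_metrics(counts, mode).rounded(3)
    print(
        f"{mode:>13}: COR={counts.COR} INC={counts.INC} MIS={counts.MIS} "
        f"SPU={counts.SPU} POS={counts.POS} ACT={counts.ACT} "
        f"P={metrics.precision} R={metrics.recall} F1={metrics.f1}"
    )
# The truncated ECG span [1,3) counts as INC under strict evaluation but
# COR under entity type matching, so the type-matching F1 is higher; the
# spurious Bleeding prediction costs precision in both modes.
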