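# emsner

Weakly-supervised named entity recognition (NER) for emergency medical
services (EMS) paramedic free-text reports.

Clinical audits of EMS cases check whether paramedics documented the
assessment and treatment steps their protocols require — was an ECG taken,
was aspirin given, was a stroke assessment done.  Auditing free-text case
narratives by hand is slow; `emsner` automates it by recognizing 17
clinical entities (3 categories: clinical procedures, clinical findings,
medications) in telegraphic, abbreviation-heavy paramedic text, **without
hand-labeled training data**:

1. **Preprocess** — lower-case, strip symbols to spaces (keeping `%` and
   `&`), whitespace-tokenize.
2. **Weak labeling** — pseudo-label reports by matching a per-entity
   synonym gazetteer, exactly and *fuzzily* (a window matches a synonym if
   it is missing at most one character, applied only to synonyms of ≥ 5
   joined characters), emitting IOB2 tags.
3. **Tagger** — a BiLSTM-CRF trained on the pseudo-labels: zero-initialized
   word embeddings (dim 100) → bidirectional LSTM (hidden 64 per
   direction) → per-tag emissions → linear-chain CRF.  Training score is
   the CRF log-likelihood `s(y) − log Z` with
   `s(y) = start_{y_1} + Σ_t em_{t,y_t} + Σ_t A_{y_t,y_{t+1}} + end_{y_T}`;
   prediction is the Viterbi path.  Pure NumPy, exact gradients.
4. **Evaluation** — MUC-5 categorization (COR/INC/PAR/MIS/SPU) with
   SemEval'13 metrics `P = COR/ACT`, `R = COR/POS`, `F1 = 2PR/(P+R)` in
   *strict* and *entity-type-matching* modes, plus token-level weighted
   metrics excluding `O`.
5. **Synthetic corpus** — because real EMS narratives are restricted, a
   generator produces paramedic-style reports with known gold spans,
   ECG-dominated entity frequencies and controllable single-deletion
   misspellings, so the whole pipeline is testable end to end.

## Worked example

```python
from emsner import RawReport, preprocess_report, render_annotations, \
    starter_lexicon, weak_label

report = preprocess_report(RawReport(
    "acs-1",
    "given 300 mg asprin stat dose & 1 gtn spray 0.4 mg with total "
    "relieved. 12 lead ecg done: sinus rhythm.",
))
tags, mentions = weak_label(report, starter_lexicon())
print(render_annotations(report, mentions))
```

prints

```
given 300 mg [asprin|Aspirin] stat dose & 1 [gtn spray|Nitroglycerin (GTN)] 0 4 mg with total relieved [12 lead ecg|ECG] done sinus rhythm
```

The misspelled `asprin` is recovered by the one-missing-character fuzzy
rule; `gtn spray` and `12 lead ecg` are exact gazetteer hits.  These IOB2
pseudo-labels are what the tagger trains on.

Scoring a toy prediction set (`examples/05_muc_scoring.py`) shows the two
evaluation modes diverge exactly when spans are truncated:

```
       strict: COR=1 INC=1 MIS=0 SPU=1 POS=2 ACT=3 P=0.333 R=0.5 F1=0.4
type_matching: COR=2 INC=0 MIS=0 SPU=1 POS=2 ACT=3 P=0.667 R=1.0 F1=0.8
```

The `examples/` directory has one short script per capability
(preprocessing, weak labeling, corpus statistics, training + evaluation,
MUC-5 scoring).  A thin CLI mirrors the stages:

```sh
emsner synth --n-reports 2000 --seed 1 --out-text r.tsv --out-gold gold.conll
emsner weaklabel --in r.tsv --out weak.conll
emsner split --in weak.conll --out-prefix corpus --seed 1
emsner train --train corpus.train.conll --dev corpus.dev.conll --out model.npz
emsner predict --model model.npz --in r.tsv --out pred.conll
emsner evaluate --gold gold.conll --pred pred.conll
```

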