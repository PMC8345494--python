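"""Pseudo-label a report against the starter gazetteer.

Exact matching finds verbatim synonyms; fuzzy matching additionally
recovers surfaces missing one character ("asprin" for "aspirin"), but only
for synonyms of 5+ joined characters that are not flagged exact-only.
"""

from emsner import RawReport, preprocess_report, render_annotations, starter_lexicon, weak_label

lexicon = starter_lexicon()
report = preprocess_report(
    RawReport(
        "acs-1",
        "given 300 mg asprin stat dose & 1 gtn spray 0.4 mg with total "
        "relieved. 12 lead ecg done: sinus rhythm.",
    )
)

tags, mentions = weak_label(report, lexicon)
print(render_annotations(report, mentions))
for m in mentions:
    surface = " ".join(report.tokens[m.start : m.end])
    print(f"  [{m.start:2d},{m.end:2d}) {m.entity:<22} {m.source:<6} {surface!r}")
# 'asprin' is recovered by the one-missing-character fuzzy rule (source
# 'fuzzy'); the rest are exact gazetteer hits.  These IOB2 tags are the
# pseudo-labels the tagger trains on.
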