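"""Normalize and tokenize a raw paramedic report.

Paramedic narratives arrive in mixed case, riddled with shorthand
punctuation.  Normalization lower-cases, turns every symbol except '%' and
'&' into a space (so "c/o" splits into "c o" instead of merging), and
collapses whitespace; tokenization then splits on spaces.
"""

from emsner import RawReport, normalize_text, preprocess_report

raw = (
    "o/a- Pt sitting conscious alert. hx fr pt- pt fell due to slippery "
    "floor, noted bleeding, no loc. o/e- noted 3 cm laceration active "
    "bleeding. usual bp @ 115/57"
)

print("raw:       ", raw)
print("normalized:", normalize_text(raw))

report = preprocess_report(RawReport("example-1", raw))
print(f"{len(report.tokens)} tokens; first ten: {list(report.tokens[:10])}")
# Every token is lower-case and contains only letters, digits, '%' or '&';
# the token stream is what the gazetteer labeler and the tagger consume.
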