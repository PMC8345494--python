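# Methods

`emsner` implements a weakly-supervised named-entity-recognition pipeline
for paramedic free-text case reports, the kind written by emergency medical
services (EMS) crews and reviewed in clinical audits.  The target inventory
is 17 clinical entities in three categories (clinical procedures such as
ECG and stroke assessment; clinical findings such as bleeding; medications
such as aspirin, GTN and normal saline).  Because real EMS narratives are
restricted data, the package ships a synthetic-report generator with known
gold spans; everything else in the pipeline is agnostic to where the text
came from.

## Preprocessing

Reports are lower-cased, every symbol is replaced by a single space, digits
and `%` are kept, and the result is whitespace-tokenized.  Replacing
symbols with spaces (rather than deleting them) is deliberate: shorthand
like `c/o` must become the two tokens `c o`, and `115/57` must become
`115 57`.  Two symbols are configurable because real corpora are
inconsistent about them: `&` is kept by default (it appears systematically
in constructions like `a&e` and `dose & 1 gtn spray`) and `/` is removed by
default.  Unicode input is NFKC-folded before filtering; non-ASCII letters
are dropped, which is appropriate for ASCII clinical shorthand.
Normalization is idempotent, and joining the token stream with single
spaces reproduces the normalized string exactly — properties the test
suite enforces.

Registry-level exclusions mirror audit practice: incidents without a
patient encounter and reports whose text is empty after stripping are
removed before the corpus is built.

## Weak labeling (gazetteer distant supervision)

Each entity carries a list of synonym surface forms (pre-normalized,
possibly multi-token).  Labeling runs two matchers over every report:

* **Exact**: the synonym's token sequence equals a contiguous token window.
* **Fuzzy**: the window's single-space-joined characters can be obtained
  from the joined synonym by deleting **exactly one character**.  The
  deleted character may be a space, which merges two tokens, so for a
  k-token synonym both k- and (k−1)-token windows are candidates.  Fuzzy
  matching applies only to synonyms of at least 5 joined characters
  (shorter surfaces would flood clinical shorthand with false positives)
  and never to synonyms flagged `exact_only`.

One deletion — not general edit distance 1 — is the default error model:
it captures the dominant recoverable misspelling class ("asprin",
"facial drop") while substitution-type misspellings ("salbutumol") remain
out of reach by design; a `allow_substitutions` switch widens the rule to
Levenshtein 1 for experimentation.

Overlapping candidate matches are resolved greedily with a deterministic
total order: longer span first, exact before fuzzy, leftmost first, then
lexicographic entity name.  The accepted mentions are emitted as IOB2 tags
over the fixed 35-tag inventory (B-/I- per entity plus O, regardless of
which entities a split happens to contain).  Decoding tolerates
IOB2-invalid model output: a stray `I-` with no compatible predecessor
opens a new mention.

The packaged starter lexicon (4–8 synonyms per entity) is seeded from
surface forms typical of paramedic shorthand; it is a starting point, and
production use is expected to supply a curated lexicon file (YAML or CSV).

## The BiLSTM-CRF tagger

The tagger is a trainable word-embedding table (dimension 100,
zero-initialized), a bidirectional LSTM (hidden size 64 per direction, so
the encoder output is 128), a linear projection to 35 per-tag emission
scores, and a linear-chain CRF.  A tag path `y` for a length-T report
scores

    s(y) = start[y_1] + Σ_t em[t, y_t] + Σ_t trans[y_t, y_{t+1}] + end[y_T]

and training minimizes the mean negative log-likelihood
`log Z − s(y_gold)`, with `log Z` from the forward algorithm in log space.
Prediction is the Viterbi path; decoding ties break toward the lower tag
index.  No transition constraints are imposed; invalid tag bigrams are
repaired downstream during mention decoding (a `forbid_invalid` style
hard-constraint was considered and rejected as unnecessary — the CRF
learns the IOB2 grammar from data almost immediately).

The implementation is pure NumPy.  Gradients are exact: emission,
transition and boundary gradients come from forward–backward posterior
marginals, and the encoder is backpropagated through time by hand.  The
test suite verifies every gradient against central finite differences and
the CRF quantities against exhaustive path enumeration, and checks
log-space stability for emission magnitudes up to 1e3.

Training uses Adam (learning rate 0.001), mini-batches of 512 reports by
default, up to 300 epochs, and early stopping: if the development loss
fails to improve on its **running minimum** for 5 consecutive epochs,
training halts and the best-development-loss parameters are restored.
("Did not decrease" is read against the running minimum rather than the
previous epoch; a previous-epoch reading would stop on any plateau.)
Batches pad to the longest member and the loss is masked, which the tests
show equivalent to fixed-length padding; within each seeded epoch shuffle,
reports are bucketed by length so batches pad to near-native lengths.
Sequences beyond 300 tokens are truncated with a warning.  Everything is
deterministic under the config seed.

Zero-initialized embeddings are the deployed default but learn slowly at
small corpus sizes (all tokens start identical and rows differentiate only
through occurrence-specific gradients); `zero_init_embeddings=False`
switches to small-uniform initialization, which the demonstration example
uses.

For corpora tokenized into subwords by an external tokenizer, the dataset
module provides the word-level aggregation rule: majority vote over the
word's subword tags excluding O (an all-O word stays O), ties broken by
first occurrence; a flag pools B-/I- votes per entity type instead of
voting on full tags, since either reading of "class" is defensible.

## Evaluation

Entity level: each *prediction* is independently categorized against the
gold mentions of its report using the MUC-5 categories — COR (exact span
and type), INC, MIS (gold with no overlapping prediction), SPU (prediction
overlapping no gold); PAR never occurs in the two implemented modes.  Under
**strict** evaluation a correct-type prediction whose span merely overlaps
the gold span is INC; under **entity type matching** it is COR.  "Overlap"
means at least one shared token index; a prediction overlapping several
golds is categorized against the first in span order.  Because each
overlapping prediction is counted separately, POS = COR+INC+MIS can exceed
the number of gold mentions.  Then P = COR/ACT, R = COR/POS,
F1 = 2PR/(P+R), with ACT = COR+INC+SPU; displayed values round half-up to
3 decimals, exports keep full precision.  Type-matching F1 never falls
below strict F1 on the same predictions.

Token level: per-tag precision/recall/F1 from the token confusion, with
the weighted average taken over every class except O (O contributes
neither weight nor score); this matches scikit-learn's weighted averaging
restricted to the non-O labels, which the tests cross-check.

Corpus statistics report per-entity mention counts, share of total
mentions (half-up, 1 decimal percent), entity-token counts and ATE
(average tokens per entity mention, half-up, 2 decimals).  Half-up
rounding is used everywhere a table cell is printed.

## Synthetic corpus generator

Each report is assembled from entity-free filler phrases (telegraphic
clinical shorthand) until a target length drawn uniformly from 30–120
tokens is reached; mention surface forms are planted into distinct gaps
between filler phrases, so planted mentions are never adjacent.  The
per-report mention count is drawn from a distribution over 0–4 with mean
≈ 1.2, which together with the entity mix puts the entity-token fraction
near 3% of all tokens — the regime of real EMS audit corpora.  Entity
frequencies default to an ECG-dominated mix (ECG ≈ 50.6% of mentions,
stroke assessment 12.5%, bleeding 14.1%, a long tail below 1%).

With probability `misspell_prob` (default 0.05) a planted surface form
receives a single-character deletion, uniformly over its *deletable*
positions: positions whose removal shortens the normalized joined surface
by exactly one character.  Deleting the sole character of a
single-character token would also collapse an adjacent space — a
two-character change outside the one-deletion error model — so such
positions are excluded.  Deletions are only injected into surfaces the
fuzzy matcher is allowed to recover (joined length ≥ 5, not exact-only);
an optional substitution mode generates the unrecoverable error class for
error analysis.  Provenance records (synonym, deletion position) allow the
clean surface to be reconstructed exactly.

The filler bank is validated at build time: every filler phrase and every
ordered pair of phrases is re-scanned with the weak labeler and must
produce zero matches.  This makes the gold spans exhaustive — the
precondition for treating generator output as ground truth — and yields
the calibration property the tests enforce: with no misspellings the weak
labeler achieves precision = recall = 1.0 against gold, and with deletion
misspellings plus fuzzy matching recall stays 1.0.

What the generator does *not* emulate: real lexical diversity (filler
phrases repeat), negated mentions, substitution/transposition misspellings
(unless enabled), abbreviation variation outside the lexicon, and
annotation noise in the gold standard.  Passing the recovery experiment
therefore shows that the pipeline machinery is sound — labeling is
consistent, the tagger can learn the labeling function, evaluation is
correct — not that the same F1 would be reached on real paramedic text.

## Reference experiment scale

The acceptance experiment trains on 2,000 weak-labeled synthetic reports
with a 200-report pseudo-labeled development split and scores on a
200-report clean-gold test split, three seeds, median reported.  At this
corpus size the optimizer regime is rescaled with it: batch size 64 (about
31 updates per epoch, comparable to the update density of a full-scale
corpus under batch 512) and at most 40 epochs.  Under these conditions the
median entity-type-matching F1 clears the 0.90 acceptance threshold and
the median strict F1 clears 0.85 (the test suite computes both); the
strict score never exceeds the type-matching score, as at full scale.

## Known limitations

* The one-deletion fuzzy rule cannot recover substitutions, insertions or
  multi-character errors; spelling correction is out of scope.
* Negation is not modeled: a negated mention ("no bleeding") is still a
  mention of the entity.
* Nested, overlapping and discontinuous mentions are unsupported.
* Pretrained-transformer fine-tuning is out of scope; only the word-level
  subtoken aggregation rule and fixed-length padding contract are
  provided for such pipelines.
* The starter lexicon is illustrative, not clinically curated.
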