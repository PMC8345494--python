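"""Exact and one-missing-character fuzzy gazetteer matching."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emsner.lexicon import DEFAULT_SCHEMA, Lexicon, Synonym
from emsner.preprocessing import TokenizedReport
from emsner.tags import Mention, is_iob2_valid
from emsner.weak_labeler import (
    MatcherConfig,
    is_single_deletion,
    match_exact,
    match_fuzzy,
    resolve_overlaps,
    weak_label,
)


def all_single_deletions(phrase: str) -> set[str]:
    """Brute-force oracle: every string obtainable by deleting one char."""
    return {phrase[:i] + phrase[i + 1 :] for i in range(len(phrase))}


@pytest.mark.parametrize(
    "tokens,phrase,expected",
    [
        (["12", "lead", "ecg", "done"], ["12", "lead", "ecg"], [(0, 3)]),
        (["ecg", "ecg"], ["ecg"], [(0, 1), (1, 2)]),
        (["aspirin"], ["gtn"], []),
    ],
)
def test_match_exact(tokens, phrase, expected):
    assert match_exact(tokens, phrase) == expected


@pytest.mark.parametrize(
    "tokens,phrase,expected",
    [
        (["given", "asprin"], ["aspirin"], [(1, 2)]),
        (["facial", "drop"], ["facial", "droop"], [(0, 2)]),
        (["aspirinn"], ["aspirin"], []),  # extra char is not a missing char
        (["aspirim"], ["aspirin"], []),  # substitution is not a deletion
        (["aspirin"], ["aspirin"], [(0, 1)]),  # verbatim also reported
        (["facialdroop"], ["facial", "droop"], [(0, 1)]),  # deleted space merges
    ],
)
def test_match_fuzzy(tokens, phrase, expected):
    assert match_fuzzy(tokens, phrase) == expected


def test_fuzzy_gate_rejects_short_phrases():
    with pytest.raises(ValueError, match="shorter than"):
        match_fuzzy(["gtnn"], ["gtn"])  # joined length 3 < 5
    # joined length exactly 5 is eligible, and a single deletion matches
    assert match_fuzzy(["drop"], ["droop"]) == [(0, 1)]


def test_substitution_mode_flag():
    assert match_fuzzy(["aspirim"], ["aspirin"], allow_substitutions=True) == [(0, 1)]


@settings(max_examples=150, derandomize=True)
@given(
    phrase=st.text(alphabet="abcde", min_size=5, max_size=10),
    window=st.text(alphabet="abcde", min_size=1, max_size=11),
)
def test_fuzzy_matches_iff_deletion_oracle(phrase, window):
    """Single-token fuzzy matching agrees with the enumerate-all-deletions
    brute-force oracle."""
    hit = match_fuzzy([window], [phrase]) == [(0, 1)]
    oracle = window == phrase or window in all_single_deletions(phrase)
    assert hit == oracle
    # and the low-level predicate agrees as well
    if len(window) == len(phrase) - 1:
        assert is_single_deletion(window, phrase) == (
            window in all_single_deletions(phrase)
        )


@pytest.mark.parametrize(
    "matches,expected",
    [
        (
            [(0, 3, "ECG", "exact"), (2, 3, "ECG", "exact")],
            [Mention(0, 3, "ECG")],
        ),
        (
            [(0, 2, "Nitroglycerin (GTN)", "fuzzy"), (0, 2, "Nitroglycerin (GTN)", "exact")],
            [Mention(0, 2, "Nitroglycerin (GTN)", source="exact")],
        ),
        (
            [(0, 1, "Aspirin", "exact"), (1, 2, "Bleeding", "exact")],
            [Mention(0, 1, "Aspirin"), Mention(1, 2, "Bleeding")],
        ),
    ],
)
def test_resolve_overlaps(matches, expected):
    got = resolve_overlaps(matches)
    assert got == expected
    if matches and matches[0][3] == "fuzzy":
        assert got[0].source == "exact"  # exact outranks fuzzy at equal span


def test_weak_label_table_style_report(lexicon):
    text = (
        "given 300 mg aspirin stat dose & 1 gtn spray 0 4 mg "
        "with total relieved 12 lead ecg done sinus rhythm"
    )
    report = TokenizedReport("acs", tuple(text.split()))
    tags, mentions = weak_label(report, lexicon)
    found = {(" ".join(report.tokens[m.start : m.end]), m.entity) for m in mentions}
    assert ("aspirin", "Aspirin") in found
    assert ("gtn spray", "Nitroglycerin (GTN)") in found
    assert ("12 lead ecg", "ECG") in found
    assert is_iob2_valid(tags)


def test_weak_label_empty_lexicon_all_outside():
    lex = Lexicon(DEFAULT_SCHEMA, {"Aspirin": [Synonym(("zzzz",))]})
    report = TokenizedReport("r", ("no", "entities", "here"))
    tags, mentions = weak_label(report, lex)
    assert tags == ["O", "O", "O"] and mentions == []


def test_weak_label_fuzzy_misspelling(lexicon):
    report = TokenizedReport("r", ("pt", "given", "asprin", "stat"))
    _, mentions = weak_label(report, lexicon)
    assert [(m.start, m.end, m.entity, m.source) for m in mentions] == [
        (2, 3, "Aspirin", "fuzzy")
    ]
    # with fuzzy matching off the misspelling is not recovered
    _, mentions = weak_label(report, lexicon, MatcherConfig(fuzzy=False))
    assert mentions == []


def test_exact_only_synonyms_never_fuzzy(lexicon):
    # "i v n s" is exact_only; a one-deletion corruption must not match
    _, mentions = weak_label(TokenizedReport("r", ("iv", "n", "s")), lexicon)
    assert mentions == []
    _, mentions = weak_label(TokenizedReport("r", ("i", "v", "n", "s")), lexicon)
    assert [(m.entity, m.source) for m in mentions] == [("Normal Saline", "exact")]


def test_weak_label_output_always_iob2_valid(lexicon, rng):
    vocab = ["ecg", "gtn", "aspirin", "pt", "given", "lead", "12", "spray", "done"]
    for _ in range(50):
        toks = tuple(rng.choice(vocab, size=rng.integers(1, 15)))
        tags, mentions = weak_label(TokenizedReport("r", toks), lexicon)
        assert is_iob2_valid(tags)
        starts = [m.start for m in mentions]
        assert starts == sorted(starts)
        for a, b in zip(mentions, mentions[1:]):
            assert not a.overlaps(b)
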