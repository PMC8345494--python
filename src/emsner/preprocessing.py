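"""Text normalization and tokenization for paramedic free-text reports.

Paramedic narratives are telegraphic, heavily abbreviated and frequently
typed in all caps.  The pipeline's first stage lower-cases each report,
strips punctuation (every symbol becomes a single space, so ``c/o`` becomes
``c o`` rather than ``co``), keeps digits and the ``%`` sign, and splits on
whitespace.  The ampersand survives by default because it is used
systematically in the source narratives (``a&e``, ``stat dose & 1 gtn
spray``); the slash is removed by default.  Both are configurable.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = [
    "RawReport",
    "TokenizedReport",
    "normalize_text",
    "tokenize",
    "preprocess_report",
    "apply_exclusions",
    "read_raw_reports",
    "write_tokenized_reports",
    "read_tokenized_reports",
]


@dataclass(frozen=True)
class RawReport:
    """One free-text report as recorded, before any normalization."""

    report_id: str
    text: str
    patient_encounter: bool = True

    @property
    def has_text(self) -> bool:
        return bool(self.text.strip())


@dataclass(frozen=True)
class TokenizedReport:
    """A normalized, whitespace-tokenized report.

    Tokens are lower-case and contain only ``a-z``, ``0-9``, ``%`` and
    (by default) ``&``; order preserves reading order.
    """

    report_id: str
    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def text(self) -> str:
        return " ".join(self.tokens)


def normalize_text(
    text: str,
    *,
    keep_ampersand: bool = True,
    keep_slash: bool = False,
) -> str:
    """Lower-case *text* and strip all symbols except ``%`` (and optionally
    ``&`` / ``/``), replacing each removed symbol with a space.

    Removed symbols become spaces — never the empty string — so that
    symbol-joined words split into separate tokens (``115/57`` -> ``115 57``).
    Runs of whitespace collapse to one space and the result is stripped.
    Idempotent: applying it twice equals applying it once.
    """
    kept = "%"
    if keep_ampersand:
        kept += "&"
    if keep_slash:
        kept += "/"
    text = unicodedata.normalize("NFKC", text).lower()
    pattern = "[^a-z0-9" + re.escape(kept) + "]+"
    text = re.sub(pattern, " ", text)
    return re.sub(r"\s+", " ", text).strip()


def tokenize(normalized: str) -> list[str]:
    """Whitespace tokenization of an already-normalized string."""
    if not normalized:
        return []
    return normalized.split(" ")


def preprocess_report(
    report: RawReport,
    *,
    keep_ampersand: bool = True,
    keep_slash: bool = False,
) -> TokenizedReport:
    """Normalize and tokenize one report.

    Raises ``ValueError`` for reports that are empty after normalization,
    mirroring the corpus-construction rule that excludes cases with missing
    text.
    """
    normalized = normalize_text(
        report.text, keep_ampersand=keep_ampersand, keep_slash=keep_slash
    )
    if not normalized:
        raise ValueError(f"report {report.report_id!r} has no text after normalization")
    return TokenizedReport(report.report_id, tuple(tokenize(normalized)))


def apply_exclusions(reports: Iterable[RawReport]) -> list[RawReport]:
    """Drop incidents without a patient encounter and reports with missing
    text, returning the incidents eligible for the NER corpus."""
    return [r for r in reports if r.patient_encounter and r.has_text]


# ---------------------------------------------------------------------------
# File I/O: newline-delimited text, or two-column TSV (report_id <TAB> text)


def read_raw_reports(path: str | Path) -> list[RawReport]:
    """Read reports from a UTF-8 file.

    Lines containing a tab are parsed as ``report_id<TAB>text``; otherwise
    each non-empty line is one report and ids are assigned positionally.
    """
    reports = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if "\t" in line:
                rid, text = line.split("\t", 1)
            else:
                rid, text = str(i), line
            reports.append(RawReport(rid, text))
    return reports


def write_tokenized_reports(reports: Iterable[TokenizedReport], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rep in reports:
            fh.write(f"{rep.report_id}\t{rep.text}\n")


def read_tokenized_reports(path: str | Path) -> list[TokenizedReport]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            rid, text = line.split("\t", 1)
            out.append(TokenizedReport(rid, tuple(tokenize(text))))
    return out
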