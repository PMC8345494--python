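"""Plain-text mention highlighting: ``given [aspirin|Aspirin]``.

A desk-friendly renderer for spot-checking predictions; stripping the
markup restores the token text losslessly.
"""

from __future__ import annotations

import re
from typing import Sequence

from .preprocessing import TokenizedReport
from .tags import Mention

__all__ = ["render_annotations", "strip_annotations"]


def render_annotations(report: TokenizedReport, mentions: Sequence[Mention]) -> str:
    """Inline bracketed markup ``[token ... |ENTITY]`` around each mention."""
    mentions = sorted(mentions)
    for a, b in zip(mentions, mentions[1:]):
        if a.overlaps(b):
            raise ValueError(f"overlapping mentions {a} and {b}")
    parts: list[str] = []
    pos = 0
    for m in mentions:
        if m.end > len(report.tokens):
            raise ValueError(f"mention {m} exceeds report length")
        parts.extend(report.tokens[pos : m.start])
        span = " ".join(report.tokens[m.start : m.end])
        parts.append(f"[{span}|{m.entity}]")
        pos = m.end
    parts.extend(report.tokens[pos:])
    return " ".join(parts)


def strip_annotations(text: str) -> str:
    """Remove the bracketed markup, recovering the plain token text."""
    return re.sub(r"\[([^]|]*)\|[^]]*\]", r"\1", text)
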