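"""Tokenisation and sentence segmentation for clinical notes.

Deliberately simple: lowercased alphanumeric tokens (apostrophes kept inside
words), no stemming, stop-words and negation words retained — the downstream
bag-of-words classifier and negation rules need them. Sentences split on
sentence-final punctuation followed by whitespace, guarded by a short list of
clinical abbreviations so "Dr. Smith" does not break a sentence.
"""

from __future__ import annotations

import re
from typing import NamedTuple

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:'[a-z]+)?", re.IGNORECASE)
_SENT_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s)")

#: Abbreviations whose trailing period never ends a sentence (lowercase, no dot).
ABBREVIATIONS = frozenset(
    "dr mr mrs ms prof st vs eg ie etc approx inc dept wk hx rx".split()
)


class TokenSpan(NamedTuple):
    """A token with its character offsets in the source text."""

    text: str  # lowercased
    start: int
    end: int


def tokenize(text: str, offset: int = 0) -> list[TokenSpan]:
    """Lowercased tokens with character spans (spans offset by *offset*)."""
    return [
        TokenSpan(m.group(0).lower(), m.start() + offset, m.end() + offset)
        for m in _TOKEN_RE.finditer(text)
    ]


def segment_sentences(text: str) -> list[tuple[int, int]]:
    """Split *text* into sentence spans (0-based, half-open).

    Spans are disjoint, ordered, and jointly cover all non-whitespace text;
    any non-empty text yields at least one span.
    """
    if not text.strip():
        return [(0, len(text))] if text else []
    boundaries: list[int] = []
    for m in _SENT_BOUNDARY_RE.finditer(text):
        word = _last_word(text, m.start())
        if word in ABBREVIATIONS:
            continue
        boundaries.append(m.end())
    spans: list[tuple[int, int]] = []
    prev = 0
    for b in boundaries + [len(text)]:
        chunk = text[prev:b]
        if chunk.strip():
            # trim leading/trailing whitespace out of the span
            lead = len(chunk) - len(chunk.lstrip())
            trail = len(chunk) - len(chunk.rstrip())
            spans.append((prev + lead, b - trail))
        prev = b
    return spans


def _last_word(text: str, pos: int) -> str:
    i = pos
    while i > 0 and (text[i - 1].isalnum() or text[i - 1] == "'"):
        i -= 1
    return text[i:pos].lower()
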