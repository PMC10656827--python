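"""Shared low-level text primitives.

One tokenization convention is used everywhere (lexicon normalization,
dictionary matching, negation scope counting, n-gram features): maximal
alphanumeric runs are word tokens, every other non-space character is a
standalone punctuation token. Hyphens and slashes therefore split words
("2nd-degree" -> "2nd", "-", "degree"), which is what typographically noisy
clinical text needs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

TOKEN_RE = re.compile(r"[A-Za-z0-9]+|[^\sA-Za-z0-9]")


@dataclass(frozen=True)
class Token:
    """A token with its half-open character span (note coordinates)."""

    text: str
    begin: int
    end: int

    @property
    def is_word(self) -> bool:
        return self.text[0].isalnum()


def tokenize_text(text: str, offset: int = 0) -> list[Token]:
    """Tokenize ``text``; spans are shifted by ``offset`` (0-based, half-open)."""
    return [
        Token(m.group(0), m.start() + offset, m.end() + offset)
        for m in TOKEN_RE.finditer(text)
    ]


def word_tokens(tokens: list[Token]) -> list[Token]:
    return [t for t in tokens if t.is_word]


def phrase_words(phrase: str) -> list[str]:
    """Lowercased word tokens of a phrase (punctuation dropped)."""
    return [t.text.lower() for t in tokenize_text(phrase) if t.is_word]


def normalize_phrase(phrase: str) -> str:
    """Canonical form: lowercase, punctuation stripped, whitespace collapsed.

    Hyphens act as token separators, so "Child-Protective  Services." and
    "child protective services" normalize identically.
    """
    return " ".join(phrase_words(phrase))
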