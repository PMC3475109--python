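"""Sentence splitting, tokenization with character offsets, and stemming.

All offsets are 0-based, half-open, in Unicode code points, and refer to
the *document* text so that standoff entity annotations and token spans
live in one coordinate system.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator

from ._porter import porter_stem

__all__ = [
    "Token",
    "TokenizedSentence",
    "Document",
    "split_sentences",
    "tokenize",
    "stem",
]

stem = porter_stem

# Abbreviations after which a period never ends a sentence.
_ABBREVIATIONS = frozenset(
    """al etc e.g i.e cf ca vs viz fig figs eq eqs ref refs sec
    no vol dr prof st mr mrs ms approx resp""".split()
)

# sentence-final punctuation followed by whitespace and an uppercase
# letter or a digit
_BOUNDARY = re.compile(r"[.!?]+(?=\s+[A-Z0-9Α-Ω])")

_WORD_CHAR = re.compile(r"[^\W_]", re.UNICODE)  # letter or digit


@dataclass(frozen=True)
class Token:
    """One token of a sentence.

    ``kind`` is ``"word"`` iff the surface contains at least one letter
    or digit; word tokens carry the lowercase Porter stem of their
    surface, punctuation tokens an empty stem.
    """

    surface: str
    start: int
    end: int
    kind: str  # "word" | "punctuation"
    stem: str = ""

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class TokenizedSentence:
    sent_index: int
    start: int
    end: int
    tokens: tuple[Token, ...]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def word_tokens(self) -> tuple[Token, ...]:
        return tuple(t for t in self.tokens if t.kind == "word")

    def text(self, document_text: str) -> str:
        return document_text[self.start : self.end]


@dataclass(frozen=True)
class Document:
    doc_id: str
    text: str
    sentences: tuple[TokenizedSentence, ...] = field(default_factory=tuple)

    @classmethod
    def from_text(cls, doc_id: str, text: str) -> "Document":
        sentences = []
        for i, (s, e) in enumerate(split_sentences(text)):
            tokens = tokenize(text[s:e], offset=s)
            sentences.append(TokenizedSentence(i, s, e, tuple(tokens)))
        return cls(doc_id=doc_id, text=text, sentences=tuple(sentences))

    def sentence_text(self, sent_index: int) -> str:
        s = self.sentences[sent_index]
        return self.text[s.start : s.end]


def _is_abbreviation(text: str, period_pos: int) -> bool:
    """True when the token ending at ``period_pos`` blocks a split."""
    i = period_pos
    j = i
    while j > 0 and not text[j - 1].isspace():
        j -= 1
    token = text[j:i].rstrip(".")
    low = token.lower().lstrip("(\"'")
    if low in _ABBREVIATIONS:
        return True
    # decimal point inside a number is never reached here (no whitespace
    # follows), but "3." before an enumeration item is
    if low.isdigit():
        return True
    # single-letter initials: "J. R. Smith" — an uppercase letter
    # followed by another initial or a capitalized word of length >= 2.
    # A lone capital followed by another lone capital ("... to C. D
    # gives ...") is treated as a sentence end, not an initial.
    if len(low) == 1 and low.isalpha() and token.isupper():
        after = text[period_pos + 1 :]
        if re.match(r"\s+[A-Z]\.", after):
            return True
        if re.match(r"\s+[A-Z][a-z]", after):
            return True
    return False


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Split ``text`` into sentence spans.

    A boundary is sentence-final punctuation (``. ! ?``) followed by
    whitespace and an uppercase letter or digit, except after a known
    abbreviation or a chained single-letter initial. Returned spans are
    trimmed of surrounding whitespace and jointly cover every
    non-whitespace character.
    """
    if not text.strip():
        return []
    breaks = [0]
    for m in _BOUNDARY.finditer(text):
        end = m.end()
        if text[m.start()] == "." and _is_abbreviation(text, m.start()):
            continue
        breaks.append(end)
    breaks.append(len(text))
    spans = []
    for a, b in zip(breaks, breaks[1:]):
        chunk = text[a:b]
        lead = len(chunk) - len(chunk.lstrip())
        trail = len(chunk) - len(chunk.rstrip())
        if a + lead < b - trail:
            spans.append((a + lead, b - trail))
    return spans


def _split_chunk(chunk: str, start: int) -> Iterator[tuple[str, int, int]]:
    """Peel leading/trailing punctuation off a whitespace-delimited chunk.

    Internal hyphens, primes, slashes, commas etc. stay inside the word
    token so chemical names ("L-arabinose", "4'-phosphopantetheine",
    "B/r") survive as single tokens.
    """
    lead = 0
    while lead < len(chunk) and not _WORD_CHAR.match(chunk[lead]):
        yield chunk[lead], start + lead, start + lead + 1
        lead += 1
    trail = len(chunk)
    while trail > lead and not _WORD_CHAR.match(chunk[trail - 1]):
        trail -= 1
    if trail > lead:
        yield chunk[lead:trail], start + lead, start + trail
    for k in range(trail, len(chunk)):
        yield chunk[k], start + k, start + k + 1


def tokenize(sentence_text: str, offset: int = 0) -> list[Token]:
    """Tokenize one sentence, reporting spans shifted by ``offset``."""
    tokens: list[Token] = []
    for m in re.finditer(r"\S+", sentence_text):
        for surface, s, e in _split_chunk(m.group(), m.start()):
            if _WORD_CHAR.search(surface):
                tokens.append(
                    Token(surface, offset + s, offset + e, "word",
                          porter_stem(surface))
                )
            else:
                tokens.append(Token(surface, offset + s, offset + e,
                                    "punctuation"))
    return tokens
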