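"""Protein and small-molecule mention tagging.

The extraction algorithm is tagger-agnostic: it only needs tagged
spans. Two fidelity paths are offered:

* a standoff reader/writer (TSV with character offsets) for annotations
  produced by any external tagger — this is the reference path;
* deliberately simple built-in taggers: case-insensitive longest-match
  dictionary lookup for both entity types, plus an "-ase(s)" suffix rule
  for enzymes that extends multi-word names leftward (so "pyruvate
  dehydrogenase", not just "dehydrogenase", is captured).

After tagging, :func:`resolve_acronyms` removes putative chemical
acronyms (all-uppercase tokens) that are neither defined earlier in the
document nor tagged with sufficient confidence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

from .text import Document, TokenizedSentence

__all__ = [
    "EntityMention",
    "StandoffError",
    "tag_small_molecules",
    "tag_proteins",
    "tag_document",
    "read_standoff",
    "write_standoff",
    "resolve_acronyms",
    "prefer_ase_names",
]

PROTEIN = "PROTEIN"
SMALL_MOLECULE = "SMALL_MOLECULE"
ETYPES = (PROTEIN, SMALL_MOLECULE)

# tokens that terminate leftward extension of a suffix-rule enzyme name
_EXTENSION_STOPWORDS = frozenset(
    """the a an of by to from and or in on with for is are was were this
    that its as at which whose both each into between during other
    catalyze catalyzes catalyzed catalyzing catalyse catalyses catalysed
    catalysing via when where""".split()
)

# common "-ase(s)"-suffixed words that are not enzymes
_ASE_STOPLIST = frozenset(
    """increase increases decrease decreases release releases disease
    diseases phase phases base bases case cases database databases
    purchase purchases baseline please cease ceases""".split()
)


@dataclass(frozen=True)
class EntityMention:
    """A tagged span in document coordinates (0-based, half-open)."""

    doc_id: str
    sent_index: int
    start: int
    end: int
    surface: str
    etype: str
    confidence: float = 1.0
    source: str = "standoff"

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __post_init__(self):
        if self.etype not in ETYPES:
            raise ValueError(f"unknown etype {self.etype!r}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


class StandoffError(ValueError):
    """Raised when a standoff annotation row is inconsistent."""


def _normalize_ws(s: str) -> str:
    return " ".join(s.split())


def _dictionary_matches(
    document: Document,
    sentence: TokenizedSentence,
    dictionary: Iterable[str],
    etype: str,
    source: str,
) -> list[EntityMention]:
    names = {_normalize_ws(n).casefold(): n for n in dictionary if n.strip()}
    if not names:
        return []
    max_tokens = max(len(n.split()) for n in names) + 2
    tokens = [t for t in sentence.tokens if t.kind == "word"]
    candidates = []
    for i in range(len(tokens)):
        for j in range(i, min(i + max_tokens, len(tokens))):
            surface = document.text[tokens[i].start : tokens[j].end]
            if _normalize_ws(surface).casefold() in names:
                candidates.append((tokens[i].start, tokens[j].end, surface))
    # longest match wins, then leftmost
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0]))
    chosen: list[tuple[int, int, str]] = []
    for c in candidates:
        if all(c[1] <= s or c[0] >= e for s, e, _ in chosen):
            chosen.append(c)
    chosen.sort()
    return [
        EntityMention(document.doc_id, sentence.sent_index, s, e, surf,
                      etype, 1.0, source)
        for s, e, surf in chosen
    ]


def tag_small_molecules(
    document: Document,
    sentence: TokenizedSentence,
    dictionary: Iterable[str],
) -> list[EntityMention]:
    """Case-insensitive longest-match dictionary tagging of chemicals."""
    return _dictionary_matches(document, sentence, dictionary,
                               SMALL_MOLECULE, "dictionary")


def _is_enzyme_seed(surface: str) -> bool:
    low = surface.lower()
    return (
        len(low) > 4
        and (low.endswith("ase") or low.endswith("ases"))
        and low not in _ASE_STOPLIST
    )


def _extendable(surface: str) -> bool:
    if surface.lower() in _EXTENSION_STOPWORDS:
        return False
    # lowercase chemical-like modifier or a capitalized word
    return surface[:1].isalpha() or surface[:1].isdigit()


def tag_proteins(
    document: Document,
    sentence: TokenizedSentence,
    dictionary: Iterable[str] = (),
    use_suffix_rule: bool = True,
) -> list[EntityMention]:
    """Dictionary matching plus the "-ase(s)" suffix rule.

    A word token ending in -ase/-ases (length > 4, not on the stoplist
    of non-enzyme words like "increase") seeds a mention which is
    extended leftward over up to three contiguous word tokens, stopping
    at stopwords and punctuation; suffix-rule mentions carry confidence
    0.8, dictionary hits 1.0.
    """
    mentions = _dictionary_matches(document, sentence, dictionary,
                                   PROTEIN, "dictionary")
    if use_suffix_rule:
        tokens = list(sentence.tokens)
        for idx, tok in enumerate(tokens):
            if tok.kind != "word" or not _is_enzyme_seed(tok.surface):
                continue
            first = idx
            for back in range(1, 4):
                k = idx - back
                if k < 0:
                    break
                prev = tokens[k]
                if prev.kind != "word" or not _extendable(prev.surface):
                    break
                first = k
            start, end = tokens[first].start, tok.end
            mentions.append(
                EntityMention(document.doc_id, sentence.sent_index,
                              start, end, document.text[start:end],
                              PROTEIN, 0.8, "suffix")
            )
    # resolve overlaps: dictionary before suffix, then longer, then leftmost
    mentions.sort(key=lambda m: (m.source != "dictionary",
                                 -(m.end - m.start), m.start))
    chosen: list[EntityMention] = []
    for m in mentions:
        if all(m.end <= o.start or m.start >= o.end for o in chosen):
            chosen.append(m)
    return sorted(chosen, key=lambda m: m.start)


def tag_document(
    document: Document,
    molecule_dictionary: Iterable[str] = (),
    protein_dictionary: Iterable[str] = (),
    use_suffix_rule: bool = True,
    apply_acronym_filter: bool = True,
) -> list[EntityMention]:
    """Run the built-in taggers over every sentence of a document."""
    mentions: list[EntityMention] = []
    for sentence in document.sentences:
        molecules = tag_small_molecules(document, sentence,
                                        molecule_dictionary)
        proteins = tag_proteins(document, sentence, protein_dictionary,
                                use_suffix_rule)
        # a chemical name embedded in a tagged enzyme name ("L-Arabinose"
        # inside "L-Arabinose isomerase") is part of the enzyme
        molecules = [
            m for m in molecules
            if not any(p.start <= m.start and m.end <= p.end
                       for p in proteins)
        ]
        mentions.extend(molecules)
        mentions.extend(proteins)
    mentions.sort(key=lambda m: (m.start, m.end))
    if apply_acronym_filter:
        mentions = resolve_acronyms(mentions, document)
    return mentions


_STANDOFF_HEADER = ["doc_id", "start", "end", "surface", "etype", "confidence"]


def read_standoff(
    path: str, documents: Mapping[str, Document]
) -> list[EntityMention]:
    """Read a standoff TSV and validate it against the document texts.

    Every row's surface must equal the document text at its span, its
    offsets must lie inside the document, and its span inside exactly
    one sentence; violations are hard errors naming the row.
    """
    mentions = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return []
        if [h.strip() for h in header[:5]] != _STANDOFF_HEADER[:5]:
            raise StandoffError(
                f"bad standoff header {header!r}; expected {_STANDOFF_HEADER}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or not "".join(row).strip():
                continue
            try:
                doc_id, start_s, end_s, surface, etype = row[:5]
                start, end = int(start_s), int(end_s)
                confidence = float(row[5]) if len(row) > 5 and row[5] else 1.0
            except (ValueError, IndexError) as exc:
                raise StandoffError(f"row {lineno}: malformed: {row!r}") from exc
            if doc_id not in documents:
                raise StandoffError(f"row {lineno}: unknown doc_id {doc_id!r}")
            doc = documents[doc_id]
            if not (0 <= start < end <= len(doc.text)):
                raise StandoffError(
                    f"row {lineno}: span ({start}, {end}) outside document "
                    f"{doc_id!r} of length {len(doc.text)}"
                )
            if doc.text[start:end] != surface:
                raise StandoffError(
                    f"row {lineno}: surface {surface!r} does not match "
                    f"text {doc.text[start:end]!r} at ({start}, {end})"
                )
            if etype not in ETYPES:
                raise StandoffError(f"row {lineno}: unknown etype {etype!r}")
            sent_index = next(
                (s.sent_index for s in doc.sentences
                 if s.start <= start and end <= s.end),
                None,
            )
            if sent_index is None:
                raise StandoffError(
                    f"row {lineno}: span ({start}, {end}) crosses a "
                    f"sentence boundary in {doc_id!r}"
                )
            mentions.append(
                EntityMention(doc_id, sent_index, start, end, surface,
                              etype, confidence, "standoff")
            )
    return mentions


def write_standoff(mentions: Sequence[EntityMention], path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_STANDOFF_HEADER)
        for m in mentions:
            writer.writerow([m.doc_id, m.start, m.end, m.surface,
                             m.etype, repr(m.confidence)])


def _is_acronym(surface: str) -> bool:
    letters = [c for c in surface if c.isalpha()]
    return (
        len(surface) >= 2
        and " " not in surface
        and len(letters) >= 2
        and all(c.isupper() for c in letters)
        and not any(c.islower() for c in surface)
    )


def _defined_acronyms(
    mentions: Sequence[EntityMention], document: Document
) -> set[str]:
    """Acronyms whose first parenthesised occurrence directly follows a
    small-molecule mention, as in "adenosine triphosphate (ATP)"."""
    molecule_ends = {
        m.end for m in mentions
        if m.etype == SMALL_MOLECULE and not _is_acronym(m.surface)
    }
    defined = set()
    for surface in {m.surface for m in mentions if _is_acronym(m.surface)}:
        probe = "(" + surface + ")"
        idx = document.text.find(probe)
        if idx < 0:
            continue
        before = document.text[:idx].rstrip()
        if len(before) in molecule_ends:
            defined.add(surface)
    return defined


def resolve_acronyms(
    mentions: Sequence[EntityMention],
    document: Document,
    min_confidence: float = 0.5,
) -> list[EntityMention]:
    """Filter undefined, low-confidence chemical acronyms.

    A SMALL_MOLECULE mention whose surface is a single all-uppercase
    token of length >= 2 is kept iff it has a parenthesised definition
    preceded by a chemical name ("adenosine triphosphate (ATP)") or its
    confidence is at least ``min_confidence`` (default 0.5, the cut-off
    that admits common undefined acronyms such as NAD). Protein,
    multi-token and lowercase mentions always pass through.
    """
    defined = _defined_acronyms(mentions, document)
    kept = []
    for m in mentions:
        if (
            m.etype == SMALL_MOLECULE
            and _is_acronym(m.surface)
            and m.surface not in defined
            and m.confidence < min_confidence
        ):
            continue
        kept.append(m)
    return kept


def prefer_ase_names(
    mentions: Sequence[EntityMention],
    enable: bool = False,
    bump: float = 0.1,
) -> list[EntityMention]:
    """Optionally boost confidence of protein names ending in -ase(s).

    Disabled by default; when enabled, the bump is additive and capped
    at 1.0.
    """
    if not enable:
        return list(mentions)
    out = []
    for m in mentions:
        low = m.surface.lower()
        if m.etype == PROTEIN and (low.endswith("ase") or low.endswith("ases")):
            out.append(replace(m, confidence=min(1.0, m.confidence + bump)))
        else:
            out.append(m)
    return out
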