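"""Keyword categories, scoring weights and threshold as validated config.

The scoring algorithm keys on five keyword categories: reaction word
stems (EC-nomenclature verbs such as *convert*, *hydrolys*), production
word stems (*form*, *produc*, ...), variants of the verb *catalyze*, the
prepositions, and the coordinating conjunction *and*. Stem categories
are matched by prefix against the Porter stem of a token; prepositions
and the conjunction match by exact lowercase surface.

All list contents live in configuration (YAML), never in code paths; the
module ships defaults that reproduce the canonical weights exactly
(-0.1 / +2 / -1 / +2, threshold 3.0).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, fields, replace
from typing import Optional, TextIO

import yaml

from ._porter import has_strippable_suffix, porter_stem
from .text import Token

__all__ = [
    "KeywordLexicon",
    "ScoringWeights",
    "LexiconError",
    "load_config",
    "dump_config",
    "match_keyword",
    "DEFAULT_LEXICON",
    "DEFAULT_WEIGHTS",
]


class LexiconError(ValueError):
    """Raised for malformed keyword/weight configuration."""


# Canonical exemplar stems, plus a curated extension assembled from
# EC class nomenclature (oxidoreductase/transferase/hydrolase/lyase/
# isomerase/ligase verbs) and common production verbs. The extension is
# marked as such so users can see which entries go beyond the canonical
# exemplars.
_REACTION_EXEMPLARS = ("add", "convert", "hydrolys", "dimeris")
_REACTION_EXTENSION = (
    "convers", "oxid", "reduc", "transfer", "cleav", "ligat",
    "isomeris", "isomeriz", "epoxid", "phosphorylat", "dephosphorylat",
    "dehydrat", "decarboxylat", "condens", "degrad", "dehydrogenat",
    "dimeriz", "hydrat", "carboxylat", "aminat",
)
_PRODUCTION_EXEMPLARS = ("form", "give", "produc", "synthesi")
_PRODUCTION_EXTENSION = ("yield", "generat", "creat", "releas", "biosynthesi")


@dataclass(frozen=True)
class KeywordLexicon:
    reaction_stems: frozenset = frozenset(
        _REACTION_EXEMPLARS + _REACTION_EXTENSION
    )
    production_stems: frozenset = frozenset(
        _PRODUCTION_EXEMPLARS + _PRODUCTION_EXTENSION
    )
    catalyze_variants: frozenset = frozenset({"catalyz", "catalys"})
    prepositions_to: frozenset = frozenset({"to", "into"})
    prepositions_other: frozenset = frozenset({"from", "by"})
    conjunction: str = "and"

    def stem_categories(self):
        return {
            "reaction": self.reaction_stems,
            "production": self.production_stems,
            "catalyze": self.catalyze_variants,
        }


@dataclass(frozen=True)
class ScoringWeights:
    """Canonical weights: each rule's points and the decision threshold.

    The three ``penalize_*`` switches control the individual
    inappropriate-location rules (production stem before the first
    substrate; reaction stem after the last product when the enzyme
    precedes the substrates; to/into inside a same-role block).
    """

    gap_penalty_per_word: float = -0.1
    keyword_reward: float = 2.0
    misplaced_keyword_penalty: float = -1.0
    reaction_plus_production_bonus: float = 2.0
    threshold: float = 3.0
    penalize_production_before_substrate: bool = True
    penalize_reaction_after_product: bool = True
    penalize_to_inside_block: bool = True

    def __post_init__(self):
        if self.gap_penalty_per_word >= 0:
            raise LexiconError("gap_penalty_per_word must be negative")
        if self.keyword_reward <= 0 or self.reaction_plus_production_bonus <= 0:
            raise LexiconError("keyword rewards must be positive")


DEFAULT_LEXICON = KeywordLexicon()
DEFAULT_WEIGHTS = ScoringWeights()


def _validate_stem_entry(entry: str) -> bool:
    """A stem entry is valid when it carries no strippable suffix.

    The stemmer's letter-level normalizations (plural-s removal, final
    y→i, e/double-consonant tidying) may legitimately touch a truncated
    stem such as ``hydrolys``, but the suffix-stripping steps must leave
    it alone: a fully inflected form such as ``formed`` would never
    prefix-match the stems of its own inflection family.
    """
    return not has_strippable_suffix(entry)


def validate(lexicon: KeywordLexicon) -> None:
    """Raise :class:`LexiconError` on malformed keyword lists."""
    cats = lexicon.stem_categories()
    surface_words = (
        set(lexicon.prepositions_to)
        | set(lexicon.prepositions_other)
        | {lexicon.conjunction}
    )
    offenders = []
    for name, stems in cats.items():
        for entry in stems:
            if not entry or entry != entry.lower():
                offenders.append(f"{name}:{entry!r} (not lowercase)")
            elif not _validate_stem_entry(entry):
                offenders.append(
                    f"{name}:{entry!r} (not stem-like; Porter stem is "
                    f"{porter_stem(entry)!r})"
                )
    if offenders:
        raise LexiconError("invalid keyword stems: " + ", ".join(sorted(offenders)))

    names = list(cats)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            # prefix overlap across categories would make matching ambiguous
            clashes = {
                (x, y)
                for x in cats[a]
                for y in cats[b]
                if x.startswith(y) or y.startswith(x)
            }
            if clashes:
                raise LexiconError(
                    f"categories {a!r} and {b!r} overlap: {sorted(clashes)}"
                )
        clash = cats[a] & surface_words
        if clash:
            raise LexiconError(
                f"category {a!r} collides with preposition/conjunction "
                f"words: {sorted(clash)}"
            )
    if lexicon.prepositions_to & lexicon.prepositions_other:
        raise LexiconError("preposition categories overlap")


def _weights_from_mapping(data: dict) -> ScoringWeights:
    known = {f.name for f in fields(ScoringWeights)}
    unknown = set(data) - known
    if unknown:
        raise LexiconError(f"unknown weight keys: {sorted(unknown)}")
    return replace(DEFAULT_WEIGHTS, **data)


def _lexicon_from_mapping(data: dict) -> KeywordLexicon:
    mapping = {
        "reaction": "reaction_stems",
        "production": "production_stems",
        "catalyze": "catalyze_variants",
        "prepositions_to": "prepositions_to",
        "prepositions_other": "prepositions_other",
    }
    unknown = set(data) - set(mapping) - {"conjunction"}
    if unknown:
        raise LexiconError(f"unknown keyword categories: {sorted(unknown)}")
    kwargs = {}
    for key, attr in mapping.items():
        if key in data:
            kwargs[attr] = frozenset(str(v) for v in data[key])
    if "conjunction" in data:
        kwargs["conjunction"] = str(data["conjunction"])
    return replace(DEFAULT_LEXICON, **kwargs)


def load_config(path: Optional[str] = None) -> tuple[KeywordLexicon, ScoringWeights]:
    """Load lexicon + weights from a YAML file, or the defaults.

    Partial files override only the keys they mention; everything else
    keeps its default. Malformed stems (entries the Porter stemmer would
    rewrite by stripping a suffix, i.e. inflected forms) and overlapping
    categories are hard errors listing the offending entries.
    """
    lexicon, weights = DEFAULT_LEXICON, DEFAULT_WEIGHTS
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise LexiconError("config root must be a mapping")
        if "weights" in data:
            weights = _weights_from_mapping(dict(data["weights"]))
        if "keywords" in data:
            lexicon = _lexicon_from_mapping(dict(data["keywords"]))
    validate(lexicon)
    return lexicon, weights


def dump_config(
    lexicon: KeywordLexicon = DEFAULT_LEXICON,
    weights: ScoringWeights = DEFAULT_WEIGHTS,
    stream: Optional[TextIO] = None,
) -> str:
    """Serialize the effective configuration as YAML."""
    data = {
        "weights": {f.name: getattr(weights, f.name) for f in fields(ScoringWeights)},
        "keywords": {
            "reaction": sorted(lexicon.reaction_stems),
            "production": sorted(lexicon.production_stems),
            "catalyze": sorted(lexicon.catalyze_variants),
            "prepositions_to": sorted(lexicon.prepositions_to),
            "prepositions_other": sorted(lexicon.prepositions_other),
            "conjunction": lexicon.conjunction,
        },
    }
    text = yaml.safe_dump(data, sort_keys=False)
    if stream is not None:
        stream.write(text)
    return text


def match_keyword(token: Token, lexicon: KeywordLexicon) -> Optional[str]:
    """Category of a word token, or None.

    Prepositions and the conjunction match by exact lowercase surface
    (so "toward" is not "to"); stem categories match when the token's
    Porter stem equals a listed stem or extends it (prefix match, which
    lets the truncated "hydrolys" hit "hydrolysis" and "hydrolysed").
    """
    if token.kind != "word":
        return None
    surface = token.surface.lower()
    if surface in lexicon.prepositions_to:
        return "prep_to"
    if surface in lexicon.prepositions_other:
        return "prep_other"
    if surface == lexicon.conjunction:
        return "conjunction"
    for category, stems in lexicon.stem_categories().items():
        for s in stems:
            if token.stem == s or token.stem.startswith(s):
                return category
    return None


def roundtrip_config(text: str) -> tuple[KeywordLexicon, ScoringWeights]:
    """Parse a YAML config string (convenience for tests/CLI)."""
    buf = io.StringIO(text)
    data = yaml.safe_load(buf) or {}
    lexicon = _lexicon_from_mapping(dict(data.get("keywords", {})))
    weights = _weights_from_mapping(dict(data.get("weights", {})))
    validate(lexicon)
    return lexicon, weights
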