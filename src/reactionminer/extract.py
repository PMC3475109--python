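"""Core reaction extraction: candidate sentences, role assignments,
positional keyword scoring, and threshold-based prediction.

The algorithm runs in three stages on entity-tagged text:

1. *Sentence selection* — keep sentences containing at least two small
   molecules (an enzyme is not required; roughly a third of reaction
   sentences in the literature name none).
2. *Entity assignment* — enumerate the plausible ways of mapping the
   tagged mentions onto the roles enzyme / substrate / product /
   unassigned. Plausible means: at least one substrate and one product,
   and, in sentence order, the assigned molecules form two contiguous
   role blocks (all substrates before all products or vice versa).
3. *Assignment scoring* — each assignment is scored by four rules
   (gap penalty between the outermost assigned molecules; +2 per
   appropriately-placed keyword; -1 per misplaced keyword; +2 bonus when
   a reaction-side and a production-side keyword co-occur). Assignments
   at or above the threshold (default 3.0) become predicted reactions,
   highest score first, skipping role permutations of an already-emitted
   mention set so one mention set yields one reaction.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO

from .lexicon import KeywordLexicon, ScoringWeights, match_keyword
from .tagging import PROTEIN, SMALL_MOLECULE, EntityMention
from .text import Document, TokenizedSentence

__all__ = [
    "CandidateSentence",
    "RoleAssignment",
    "ScoredAssignment",
    "Participant",
    "Reaction",
    "select_sentences",
    "enumerate_assignments",
    "score_assignment",
    "predict_reactions",
    "extract_document",
    "write_reactions_tsv",
    "write_reactions_jsonl",
    "MAX_MOLECULES",
    "MAX_PROTEINS",
]

logger = logging.getLogger(__name__)

SUBSTRATE = "S"
PRODUCT = "P"
UNASSIGNED = "U"

# combinatorial caps: sentences with more mentions are truncated to the
# highest-confidence ones before enumeration (leftmost wins ties)
MAX_MOLECULES = 8
MAX_PROTEINS = 3


@dataclass(frozen=True)
class CandidateSentence:
    """A sentence with >= 2 small-molecule mentions (span order)."""

    document: Document
    sentence: TokenizedSentence
    molecules: tuple[EntityMention, ...]
    proteins: tuple[EntityMention, ...]

    def __post_init__(self):
        if len(self.molecules) < 2:
            raise ValueError("candidate sentences need >= 2 molecules")

    @property
    def text(self) -> str:
        return self.sentence.text(self.document.text)


@dataclass(frozen=True)
class RoleAssignment:
    """One mapping of mentions to enzyme/substrate/product/unassigned.

    ``pattern`` is aligned with ``molecules`` (sentence order) and uses
    the letters S, P, U.
    """

    enzyme: Optional[EntityMention]
    molecules: tuple[EntityMention, ...]
    pattern: tuple[str, ...]

    def __post_init__(self):
        if len(self.molecules) != len(self.pattern):
            raise ValueError("pattern/molecule length mismatch")
        if SUBSTRATE not in self.pattern or PRODUCT not in self.pattern:
            raise ValueError("need at least one substrate and one product")
        assigned = [r for r in self.pattern if r != UNASSIGNED]
        blocks = [r for r, _ in itertools.groupby(assigned)]
        if len(blocks) != 2:
            raise ValueError("roles must form two contiguous blocks")

    @property
    def substrates(self) -> tuple[EntityMention, ...]:
        return tuple(m for m, r in zip(self.molecules, self.pattern)
                     if r == SUBSTRATE)

    @property
    def products(self) -> tuple[EntityMention, ...]:
        return tuple(m for m, r in zip(self.molecules, self.pattern)
                     if r == PRODUCT)

    @property
    def n_unassigned(self) -> int:
        return sum(1 for r in self.pattern if r == UNASSIGNED)


@dataclass(frozen=True)
class ScoredAssignment:
    assignment: RoleAssignment
    components: tuple[tuple[str, float], ...]
    total: float

    def __post_init__(self):
        if abs(self.total - sum(p for _, p in self.components)) > 1e-9:
            raise ValueError("total must equal the component sum")


@dataclass(frozen=True)
class Participant:
    surface: str
    start: int
    end: int


@dataclass(frozen=True)
class Reaction:
    """A predicted reaction: enzyme (optional), substrates, products."""

    doc_id: str
    sent_index: int
    score: float
    enzyme: Optional[Participant]
    substrates: tuple[Participant, ...]
    products: tuple[Participant, ...]
    evidence: str
    components: tuple[tuple[str, float], ...] = field(default=())

    def __post_init__(self):
        if not self.substrates or not self.products:
            raise ValueError("substrates and products must be non-empty")

    @property
    def substrate_names(self) -> tuple[str, ...]:
        return tuple(p.surface for p in self.substrates)

    @property
    def product_names(self) -> tuple[str, ...]:
        return tuple(p.surface for p in self.products)

    @property
    def enzyme_name(self) -> Optional[str]:
        return self.enzyme.surface if self.enzyme else None


def select_sentences(
    document: Document, mentions: Iterable[EntityMention]
) -> list[CandidateSentence]:
    """Keep exactly the sentences with >= 2 small-molecule mentions."""
    by_sentence: dict[int, list[EntityMention]] = {}
    for m in mentions:
        if m.doc_id == document.doc_id:
            by_sentence.setdefault(m.sent_index, []).append(m)
    candidates = []
    for sentence in document.sentences:
        ms = sorted(by_sentence.get(sentence.sent_index, []),
                    key=lambda m: (m.start, m.end))
        molecules = tuple(m for m in ms if m.etype == SMALL_MOLECULE)
        proteins = tuple(m for m in ms if m.etype == PROTEIN)
        if len(molecules) >= 2:
            candidates.append(
                CandidateSentence(document, sentence, molecules, proteins)
            )
    return candidates


def _patterns(n: int) -> Iterable[tuple[str, ...]]:
    """All contiguous-block role patterns over n molecules.

    Deterministic order (it reproduces the canonical ten-row assignment table for
    n = 3): more molecules assigned first; substrate-block-first before
    product-block-first; assigned index combinations lexicographically;
    block boundary moving rightward.
    """
    for n_assigned in range(n, 1, -1):
        for first_role, second_role in ((SUBSTRATE, PRODUCT),
                                        (PRODUCT, SUBSTRATE)):
            for assigned in itertools.combinations(range(n), n_assigned):
                for boundary in range(1, n_assigned):
                    pattern = [UNASSIGNED] * n
                    for k, idx in enumerate(assigned):
                        pattern[idx] = first_role if k < boundary else second_role
                    yield tuple(pattern)


def enumerate_assignments(candidate: CandidateSentence) -> list[RoleAssignment]:
    """Enumerate the plausible role assignments of a candidate sentence.

    When at least one protein is tagged, every assignment names one of
    the proteins as the enzyme (enzyme-less variants are not generated);
    when no protein is tagged, molecule-only assignments are generated.
    Oversized sentences are truncated to the ``MAX_MOLECULES`` /
    ``MAX_PROTEINS`` highest-confidence mentions with a logged warning.
    """
    molecules = candidate.molecules
    proteins = candidate.proteins
    if len(molecules) > MAX_MOLECULES:
        logger.warning(
            "sentence %s:%d has %d molecule mentions; truncating to %d",
            candidate.document.doc_id, candidate.sentence.sent_index,
            len(molecules), MAX_MOLECULES,
        )
        keep = sorted(molecules, key=lambda m: (-m.confidence, m.start))
        keep = set(keep[:MAX_MOLECULES])
        molecules = tuple(m for m in molecules if m in keep)
    if len(proteins) > MAX_PROTEINS:
        logger.warning(
            "sentence %s:%d has %d protein mentions; truncating to %d",
            candidate.document.doc_id, candidate.sentence.sent_index,
            len(proteins), MAX_PROTEINS,
        )
        keep = sorted(proteins, key=lambda m: (-m.confidence, m.start))
        keep = set(keep[:MAX_PROTEINS])
        proteins = tuple(p for p in proteins if p in keep)

    enzymes: Sequence[Optional[EntityMention]]
    enzymes = proteins if proteins else (None,)
    out = []
    for enzyme in enzymes:
        for pattern in _patterns(len(molecules)):
            out.append(RoleAssignment(enzyme, molecules, pattern))
    return out


def _token_range(tokens, mention: EntityMention) -> tuple[int, int]:
    idxs = [i for i, t in enumerate(tokens)
            if t.start < mention.end and t.end > mention.start]
    return (idxs[0], idxs[-1]) if idxs else (-1, -1)


def score_assignment(
    assignment: RoleAssignment,
    candidate: CandidateSentence,
    lexicon: KeywordLexicon,
    weights: ScoringWeights,
) -> ScoredAssignment:
    """Score one role assignment with an itemized component breakdown.

    Rules (points from ``weights``):

    * gap penalty per word token strictly between the outermost assigned
      substrate/product mentions that is not part of any assigned
      mention (the enzyme counts as assigned);
    * ``keyword_reward`` per keyword token in an appropriate location —
      reaction stem between the enzyme and the nearest substrate;
      reaction stem, production stem or to/into between the substrate
      and product blocks (to/into only with substrates first; "from"
      only with products first); "by" between the last assigned molecule
      and a following enzyme; "and" between the last two mentions of a
      same-role block; a catalyze-variant anywhere when an enzyme is
      assigned;
    * ``misplaced_keyword_penalty`` per uncredited keyword in an
      inappropriate location (see the ``penalize_*`` switches);
    * one ``reaction_plus_production_bonus`` when a reaction-side credit
      (reaction stem or catalyze-variant) co-occurs with a
      production-side credit (production stem or to/into).
    """
    tokens = candidate.sentence.tokens
    enzyme = assignment.enzyme
    substrates = assignment.substrates
    products = assignment.products
    assigned = list(substrates) + list(products)
    if enzyme is not None:
        assigned.append(enzyme)

    ranges = {m: _token_range(tokens, m) for m in assigned}
    in_assigned = set()
    for m in assigned:
        first, last = ranges[m]
        in_assigned.update(range(first, last + 1))

    s_first = min(ranges[m][0] for m in substrates)
    s_last = max(ranges[m][1] for m in substrates)
    p_first = min(ranges[m][0] for m in products)
    p_last = max(ranges[m][1] for m in products)

    def between(a: int, b: int) -> set[int]:
        return {i for i in range(a + 1, b) if i not in in_assigned}

    s_before_p = s_last < p_first
    if s_before_p:
        between_blocks = between(s_last, p_first)
    else:
        between_blocks = between(p_last, s_first)

    enzyme_substrate: set[int] = set()
    by_region: set[int] = set()
    if enzyme is not None:
        e_first, e_last = ranges[enzyme]
        if e_last < s_first:
            enzyme_substrate = between(e_last, s_first)
        elif e_first > s_last:
            enzyme_substrate = between(s_last, e_first)
        mol_last = max(s_last, p_last)
        if e_first > mol_last:
            by_region = between(mol_last, e_first)

    and_regions: set[int] = set()
    for group in (substrates, products):
        if len(group) >= 2:
            a = ranges[group[-2]][1]
            b = ranges[group[-1]][0]
            and_regions |= between(a, b)

    def inside_block(i: int) -> bool:
        return (s_first < i < s_last) or (p_first < i < p_last)

    components: list[tuple[str, float]] = []
    reaction_found = False
    production_found = False

    for i, tok in enumerate(tokens):
        if tok.kind != "word" or i in in_assigned:
            continue
        category = match_keyword(tok, lexicon)
        if category is None:
            continue
        surface = tok.surface.lower()
        credited = None
        if category == "reaction" and (i in enzyme_substrate
                                       or i in between_blocks):
            credited = "reaction"
        elif category == "production" and i in between_blocks:
            credited = "production"
        elif category == "prep_to" and s_before_p and i in between_blocks:
            credited = "prep_to"
        elif (category == "prep_other" and surface == "from"
              and not s_before_p and i in between_blocks):
            credited = "prep_from"
        elif (category == "prep_other" and surface == "by"
              and i in by_region):
            credited = "prep_by"
        elif category == "conjunction" and i in and_regions:
            credited = "conjunction"
        elif category == "catalyze" and enzyme is not None:
            credited = "catalyze"

        if credited is not None:
            components.append(
                (f"keyword:{credited}:{tok.surface}", weights.keyword_reward)
            )
            if credited in ("reaction", "catalyze"):
                reaction_found = True
            if credited in ("production", "prep_to"):
                production_found = True
            continue

        penalized = (
            (category == "production"
             and weights.penalize_production_before_substrate
             and i < s_first)
            or (category == "reaction"
                and weights.penalize_reaction_after_product
                and enzyme is not None
                and s_before_p
                and ranges[enzyme][1] < s_first
                and i > p_last)
            or (category == "prep_to"
                and weights.penalize_to_inside_block
                and inside_block(i))
        )
        if penalized:
            components.append(
                (f"misplaced:{category}:{tok.surface}",
                 weights.misplaced_keyword_penalty)
            )

    if reaction_found and production_found:
        components.append(
            ("reaction_production_bonus", weights.reaction_plus_production_bonus)
        )

    lo = min(ranges[m][0] for m in substrates + products)
    hi = max(ranges[m][1] for m in substrates + products)
    gap_words = sum(
        1 for i in range(lo + 1, hi)
        if i not in in_assigned and tokens[i].kind == "word"
    )
    if gap_words:
        components.append(
            (f"gap_penalty:{gap_words}_words",
             gap_words * weights.gap_penalty_per_word)
        )

    total = sum(p for _, p in components)
    return ScoredAssignment(assignment, tuple(components), total)


def _participant(m: EntityMention) -> Participant:
    return Participant(m.surface, m.start, m.end)


def predict_reactions(
    scored: Sequence[ScoredAssignment],
    candidate: CandidateSentence,
    weights: ScoringWeights,
) -> list[Reaction]:
    """Turn a sentence's scored assignments into predicted reactions.

    Assignments scoring below the threshold are eliminated; survivors
    are taken highest score first (ties: fewer unassigned molecules,
    then enumeration order) and an assignment is skipped when the same
    (enzyme, molecule set) — i.e. any role permutation of an
    already-emitted mention set — has been emitted, so that each mention
    set contributes at most one reaction while genuinely distinct
    reactions in the same sentence are all kept.
    """
    survivors = [
        (sa, order) for order, sa in enumerate(scored)
        if sa.total >= weights.threshold
    ]
    survivors.sort(key=lambda t: (-t[0].total, t[0].assignment.n_unassigned,
                                  t[1]))
    emitted: set = set()
    reactions = []
    for sa, _ in survivors:
        a = sa.assignment
        key = (
            a.enzyme.span if a.enzyme else None,
            frozenset(m.span for m in a.substrates + a.products),
        )
        if key in emitted:
            continue
        emitted.add(key)
        reactions.append(
            Reaction(
                doc_id=candidate.document.doc_id,
                sent_index=candidate.sentence.sent_index,
                score=sa.total,
                enzyme=_participant(a.enzyme) if a.enzyme else None,
                substrates=tuple(_participant(m) for m in a.substrates),
                products=tuple(_participant(m) for m in a.products),
                evidence=candidate.text,
                components=sa.components,
            )
        )
    return reactions


def extract_document(
    document: Document,
    mentions: Iterable[EntityMention],
    lexicon: KeywordLexicon,
    weights: ScoringWeights,
) -> list[Reaction]:
    """Run the full three-stage pipeline over one tagged document."""
    reactions = []
    for candidate in select_sentences(document, mentions):
        scored = [
            score_assignment(a, candidate, lexicon, weights)
            for a in enumerate_assignments(candidate)
        ]
        reactions.extend(predict_reactions(scored, candidate, weights))
    return reactions


def write_reactions_tsv(
    reactions: Sequence[Reaction], fh: TextIO, explain: bool = False
) -> None:
    header = ["doc_id", "sent_index", "score", "enzyme", "substrates",
              "products", "evidence"]
    if explain:
        header.append("components")
    fh.write("\t".join(header) + "\n")
    for r in reactions:
        row = [
            r.doc_id, str(r.sent_index), f"{r.score:g}",
            r.enzyme_name or "",
            ";".join(r.substrate_names), ";".join(r.product_names),
            " ".join(r.evidence.split()),
        ]
        if explain:
            row.append(";".join(f"{n}={p:g}" for n, p in r.components))
        fh.write("\t".join(row) + "\n")


def write_reactions_jsonl(
    reactions: Sequence[Reaction], fh: TextIO, explain: bool = False
) -> None:
    for r in reactions:
        record = {
            "doc_id": r.doc_id,
            "sent_index": r.sent_index,
            "score": r.score,
            "enzyme": r.enzyme_name,
            "substrates": list(r.substrate_names),
            "products": list(r.product_names),
            "evidence": r.evidence,
        }
        if explain:
            record["components"] = [[n, p] for n, p in r.components]
        fh.write(json.dumps(record) + "\n")
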