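"""Evaluation against curated pathways and per-sentence gold records.

The metric battery mirrors how literature-based pathway reconstruction
is scored against a curated database:

* recall(C) — of the gold items annotated in a *corpus* of texts, the
  percentage extracted;
* recall(P) — of the reactions in a curated *pathway*, the percentage
  extracted (each pathway reaction counts once however often it was
  extracted);
* precision — of the extracted items, the percentage that are correct;
* F-score — the harmonic mean of recall(C) and precision.

Matching can be *strict* (exact, case-insensitive) or *sloppy* (credit
without exact boundary agreement). Reactions can be compared ignoring
or including the enzyme, and ubiquitous side metabolites (ATP, NAD,
water, ...) are excluded from the gold before matching, since authors
routinely leave them implicit. Reaction matching preserves direction:
substrates must match substrates and products products. Reactions also
decompose into binary pairs (substrate–product, substrate–enzyme,
product–enzyme) for pair-level scoring.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .extract import Reaction

__all__ = [
    "GoldReaction",
    "PathwayGold",
    "EvalReport",
    "DEFAULT_SIDE_METABOLITES",
    "match_name",
    "decompose_binary",
    "match_reaction",
    "compute_metrics",
    "load_pathway_json",
    "save_pathway_json",
    "load_pathway_tsv",
    "report_table",
]

# cofactor-style participants excluded from recall scoring by default
DEFAULT_SIDE_METABOLITES = frozenset(
    """atp adp amp pi ppi nad nadh nad+ nadp nadph nadp+ coa h2o co2 o2
    nh3 h+ phosphate orthophosphate pyrophosphate water fad fadh2""".split()
) | frozenset({"coenzyme a"})


@dataclass(frozen=True)
class GoldReaction:
    """A curated reaction: <= 1 enzyme, >= 1 substrate and product."""

    substrates: tuple
    products: tuple
    enzyme: Optional[str] = None
    doc_id: Optional[str] = None

    def __post_init__(self):
        if not self.substrates or not self.products:
            raise ValueError("gold reactions need >= 1 substrate and product")


@dataclass(frozen=True)
class PathwayGold:
    pathway_id: str
    reactions: tuple
    side_metabolites: frozenset = DEFAULT_SIDE_METABOLITES


@dataclass
class EvalReport:
    level: str
    mode: str
    recall_C: Optional[float] = None
    recall_P: Optional[float] = None
    precision: Optional[float] = None
    f_score: Optional[float] = None
    counts: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "level": self.level,
            "mode": self.mode,
            "recall_C": self.recall_C,
            "recall_P": self.recall_P,
            "precision": self.precision,
            "f_score": self.f_score,
            "counts": dict(self.counts),
        }


_TOKEN_SPLIT = re.compile(r"[\s\-‐‑–:/]+")


def _name_tokens(name: str) -> list[str]:
    return [t for t in _TOKEN_SPLIT.split(" ".join(name.split()).casefold())
            if t]


def _norm(name: str) -> str:
    return " ".join(name.split()).casefold()


def _is_contiguous_subsequence(short: Sequence[str], long: Sequence[str]) -> bool:
    n = len(short)
    return n > 0 and any(list(long[i:i + n]) == list(short)
                         for i in range(len(long) - n + 1))


def match_name(predicted: str, gold: str, mode: str = "sloppy") -> bool:
    """Name matching with strict or sloppy boundary criteria.

    Strict requires case-insensitive equality after whitespace
    normalization. Sloppy additionally credits a prediction when one
    name's token sequence occurs contiguously inside the other's, or
    when the head token (final word) of either name occurs among the
    other's tokens — so "phosphopantetheine" and even "key precursor of
    the 4'" both count as hits for the gold name
    "4'-phosphopantetheine", while strict matching rejects both.
    """
    if mode not in ("sloppy", "strict"):
        raise ValueError(f"unknown matching mode {mode!r}")
    if _norm(predicted) == _norm(gold):
        return True
    if mode == "strict":
        return False
    p, g = _name_tokens(predicted), _name_tokens(gold)
    if not p or not g:
        return False
    if _is_contiguous_subsequence(p, g) or _is_contiguous_subsequence(g, p):
        return True
    return g[-1] in p or p[-1] in g


ReactionLike = Union[Reaction, GoldReaction]


def _names(reaction: ReactionLike) -> tuple:
    if isinstance(reaction, Reaction):
        return (reaction.enzyme_name, reaction.substrate_names,
                reaction.product_names)
    return reaction.enzyme, tuple(reaction.substrates), tuple(reaction.products)


def decompose_binary(reaction: ReactionLike) -> list[tuple[str, str, str]]:
    """All binary pairs of a reaction.

    Emits every substrate×product pair, plus substrate×enzyme and
    product×enzyme pairs when an enzyme is present; the pair count per
    reaction is therefore |S|·|P| + |S|·[E] + |P|·[E].
    """
    enzyme, substrates, products = _names(reaction)
    pairs = [("substrate-product", s, p) for s in substrates for p in products]
    if enzyme:
        pairs += [("substrate-enzyme", s, enzyme) for s in substrates]
        pairs += [("product-enzyme", p, enzyme) for p in products]
    return pairs


def _filter_side(names: Iterable[str], side: frozenset) -> list[str]:
    side_norm = {_norm(s) for s in side}
    return [n for n in names if _norm(n) not in side_norm]


def match_reaction(
    predicted: ReactionLike,
    gold: GoldReaction,
    mode: str = "sloppy",
    include_enzyme: bool = False,
    side_metabolites: frozenset = frozenset(),
) -> bool:
    """Direction-preserving reaction matching.

    Gold substrates/products are first filtered by the side-metabolite
    set; every remaining gold substrate must match a predicted
    substrate and every remaining gold product a predicted product.
    With ``include_enzyme`` the gold enzyme (when present) must also
    match the predicted enzyme.
    """
    pred_enzyme, pred_s, pred_p = _names(predicted)
    gold_s = _filter_side(gold.substrates, side_metabolites)
    gold_p = _filter_side(gold.products, side_metabolites)
    if not gold_s and not gold_p:
        return False
    for g in gold_s:
        if not any(match_name(p, g, mode) for p in pred_s):
            return False
    for g in gold_p:
        if not any(match_name(p, g, mode) for p in pred_p):
            return False
    if include_enzyme and gold.enzyme is not None:
        if pred_enzyme is None or not match_name(pred_enzyme, gold.enzyme, mode):
            return False
    return True


def _pct(num: int, den: int) -> Optional[float]:
    return 100.0 * num / den if den else None


def _harmonic(a: Optional[float], b: Optional[float]) -> Optional[float]:
    if a is None or b is None:
        return None
    if a + b == 0:
        return 0.0
    return 2 * a * b / (a + b)


def _same_doc(pred_doc: Optional[str], gold_doc: Optional[str]) -> bool:
    return gold_doc is None or pred_doc is None or pred_doc == gold_doc


def compute_metrics(
    predictions: Sequence,
    gold_corpus: Optional[Sequence[GoldReaction]] = None,
    gold_pathway: Optional[PathwayGold] = None,
    level: str = "reaction",
    mode: str = "sloppy",
    include_enzyme: bool = False,
    side_metabolites: Optional[frozenset] = None,
) -> EvalReport:
    """Score predictions at the entity, binary or reaction level.

    ``gold_corpus`` drives recall(C) (items are per-document gold
    reactions, matched within the same document); ``gold_pathway``
    drives recall(P) (each pathway reaction counts once). Precision is
    computed against the pathway when given, otherwise against the
    corpus. Undefined ratios (zero denominators) are reported as None,
    never as 0.
    """
    if gold_corpus is None and gold_pathway is None:
        raise ValueError("at least one of gold_corpus/gold_pathway is required")
    if level not in ("entity", "binary", "reaction"):
        raise ValueError(f"unknown level {level!r}")
    if side_metabolites is None:
        side_metabolites = (gold_pathway.side_metabolites
                            if gold_pathway is not None else frozenset())

    if level == "reaction":
        def hit(pred, gold):
            return (_same_doc(getattr(pred, "doc_id", None), gold.doc_id)
                    and match_reaction(pred, gold, mode, include_enzyme,
                                       side_metabolites))

        pred_items = list(predictions)
        corpus_items = list(gold_corpus) if gold_corpus is not None else None
        pathway_items = (list(gold_pathway.reactions)
                         if gold_pathway is not None else None)
    else:
        side_norm = {_norm(s) for s in side_metabolites}

        def explode(items, is_gold: bool):
            out = []
            for item in items:
                if level == "binary":
                    for ptype, a, b in decompose_binary(item):
                        if is_gold and (_norm(a) in side_norm
                                        or _norm(b) in side_norm):
                            continue
                        out.append((getattr(item, "doc_id", None), ptype, a, b))
                else:  # entity
                    if isinstance(item, str):
                        names = [item]
                    else:
                        enzyme, subs, prods = _names(item)
                        names = list(subs) + list(prods)
                        if enzyme:
                            names.append(enzyme)
                    for n in names:
                        if is_gold and _norm(n) in side_norm:
                            continue
                        out.append((getattr(item, "doc_id", None), n))
            return out

        def hit(pred, gold):
            if not _same_doc(pred[0], gold[0]):
                return False
            if level == "binary":
                return (pred[1] == gold[1]
                        and match_name(pred[2], gold[2], mode)
                        and match_name(pred[3], gold[3], mode))
            return match_name(pred[1], gold[1], mode)

        pred_items = explode(predictions, is_gold=False)
        corpus_items = (explode(gold_corpus, is_gold=True)
                        if gold_corpus is not None else None)
        pathway_items = (explode(gold_pathway.reactions, is_gold=True)
                         if gold_pathway is not None else None)

    counts: dict[str, int] = {"n_predicted": len(pred_items)}
    report = EvalReport(level=level, mode=mode, counts=counts)

    if corpus_items is not None:
        covered = sum(
            1 for g in corpus_items if any(hit(p, g) for p in pred_items)
        )
        counts["corpus_gold"] = len(corpus_items)
        counts["corpus_covered"] = covered
        report.recall_C = _pct(covered, len(corpus_items))
    if pathway_items is not None:
        covered = sum(
            1 for g in pathway_items if any(hit(p, g) for p in pred_items)
        )
        counts["pathway_gold"] = len(pathway_items)
        counts["pathway_covered"] = covered
        report.recall_P = _pct(covered, len(pathway_items))

    reference = pathway_items if pathway_items is not None else corpus_items
    correct = sum(1 for p in pred_items if any(hit(p, g) for g in reference))
    counts["predicted_correct"] = correct
    report.precision = _pct(correct, len(pred_items))
    report.f_score = _harmonic(report.recall_C, report.precision)
    return report


def load_pathway_json(path: str) -> PathwayGold:
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    reactions = tuple(
        GoldReaction(
            substrates=tuple(r["substrates"]),
            products=tuple(r["products"]),
            enzyme=r.get("enzyme"),
        )
        for r in data["reactions"]
    )
    side = data.get("side_metabolites")
    return PathwayGold(
        pathway_id=data["pathway_id"],
        reactions=reactions,
        side_metabolites=(frozenset(side) if side is not None
                          else DEFAULT_SIDE_METABOLITES),
    )


def save_pathway_json(gold: PathwayGold, path: str) -> None:
    data = {
        "pathway_id": gold.pathway_id,
        "reactions": [
            {
                "enzyme": r.enzyme,
                "substrates": list(r.substrates),
                "products": list(r.products),
            }
            for r in gold.reactions
        ],
        "side_metabolites": sorted(gold.side_metabolites),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=2)
        fh.write("\n")


def load_pathway_tsv(path: str) -> PathwayGold:
    """TSV with header ``pathway_id enzyme substrates products``;
    substrates/products are ;-joined."""
    reactions = []
    pathway_id = "pathway"
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != ["pathway_id", "enzyme", "substrates", "products"]:
            raise ValueError(f"bad pathway TSV header {header!r}")
        for row in reader:
            pathway_id, enzyme, subs, prods = row
            reactions.append(
                GoldReaction(
                    substrates=tuple(subs.split(";")),
                    products=tuple(prods.split(";")),
                    enzyme=enzyme or None,
                )
            )
    return PathwayGold(pathway_id=pathway_id, reactions=tuple(reactions))


def report_table(reports: Sequence[EvalReport]) -> str:
    """Human-readable metric table (one row per report)."""
    def fmt(x):
        return "undef" if x is None else f"{x:5.1f}"

    lines = [f"{'level':<10}{'mode':<8}{'recall(C)':>10}{'recall(P)':>10}"
             f"{'precision':>11}{'F-score':>9}"]
    for r in reports:
        lines.append(
            f"{r.level:<10}{r.mode:<8}{fmt(r.recall_C):>10}"
            f"{fmt(r.recall_P):>10}{fmt(r.precision):>11}{fmt(r.f_score):>9}"
        )
    return "\n".join(lines)
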