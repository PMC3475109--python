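"""Packaged example sentences and a seeded synthetic corpus generator.

The four packaged examples are classic sentence shapes from the
metabolic literature — a single-reaction sentence, a three-clause
multi-reaction sentence, a fatty-acid "addition" sentence with no
explicit product, and a database-style reaction passage — each shipped
with hand-built gold mentions and reactions so the whole pipeline is
exercisable without any download.

The synthetic generator emulates the statistical structure of a small
manually-selected training corpus: half the sentences describe exactly
one reaction (30% of those without naming the enzyme), the other half
mention several small molecules without describing a reaction. Planted
reactions are drawn from a linear gold pathway so that network
aggregation and pathway-level evaluation can be tested end to end.
"""

from __future__ import annotations

import json
import os
import random
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .evaluate import GoldReaction, PathwayGold
from .tagging import PROTEIN, SMALL_MOLECULE, EntityMention
from .text import Document

__all__ = [
    "PackagedExample",
    "load_packaged_examples",
    "SyntheticSpec",
    "CorpusBundle",
    "generate_corpus",
    "write_corpus",
    "load_gold_corpus_json",
]


@dataclass(frozen=True)
class PackagedExample:
    name: str
    document: Document
    mentions: tuple
    expected_reactions: tuple
    note: str


def _mention(doc: Document, surface: str, etype: str,
             occurrence: int = 0) -> EntityMention:
    start = -1
    for _ in range(occurrence + 1):
        start = doc.text.find(surface, start + 1)
        if start < 0:
            raise ValueError(f"{surface!r} not found in {doc.doc_id}")
    end = start + len(surface)
    sent_index = next(s.sent_index for s in doc.sentences
                      if s.start <= start and end <= s.end)
    return EntityMention(doc.doc_id, sent_index, start, end, surface,
                         etype, 1.0, "standoff")


def load_packaged_examples() -> list[PackagedExample]:
    """The four packaged example sentences with gold annotations."""
    examples = []

    text = (
        "L-Arabinose isomerase catalyzes the conversion of L-arabinose "
        "to L-ribulose, the first step in the utilization of "
        "n-arabinose by Escherichia coli B/r."
    )
    doc = Document.from_text("isomerase-example", text)
    examples.append(
        PackagedExample(
            name="isomerase",
            document=doc,
            mentions=(
                _mention(doc, "L-Arabinose isomerase", PROTEIN),
                _mention(doc, "L-arabinose", SMALL_MOLECULE),
                _mention(doc, "L-ribulose", SMALL_MOLECULE),
                _mention(doc, "n-arabinose", SMALL_MOLECULE),
            ),
            expected_reactions=(
                GoldReaction(substrates=("L-arabinose",),
                             products=("L-ribulose", "n-arabinose"),
                             enzyme="L-Arabinose isomerase",
                             doc_id="isomerase-example"),
            ),
            note=(
                "Single-reaction exemplar; the illustrated assignment "
                "(enzyme; substrate L-arabinose; products L-ribulose and "
                "n-arabinose) scores +7.2 under the default weights."
            ),
        )
    )

    text = (
        "ZEP catalyses the epoxidation of zeaXanthin to produce "
        "epoxycarotenoid; NCED catalyses the cleavage reaction of "
        "epoxycarotenoids to produce xanthoxin (the first C15 "
        "intermediate); and AAO catalyses the final step of ABA "
        "biosynthesis, which converts ABA aldehyde to ABA."
    )
    doc = Document.from_text("zep-example", text)
    examples.append(
        PackagedExample(
            name="zep",
            document=doc,
            mentions=(
                _mention(doc, "ZEP", PROTEIN),
                _mention(doc, "zeaXanthin", SMALL_MOLECULE),
                _mention(doc, "epoxycarotenoid", SMALL_MOLECULE),
                _mention(doc, "NCED", PROTEIN),
                _mention(doc, "epoxycarotenoids", SMALL_MOLECULE),
                _mention(doc, "xanthoxin", SMALL_MOLECULE),
                _mention(doc, "AAO", PROTEIN),
                _mention(doc, "ABA aldehyde", SMALL_MOLECULE),
                _mention(doc, "ABA", SMALL_MOLECULE, occurrence=2),
            ),
            expected_reactions=(
                GoldReaction(substrates=("zeaXanthin",),
                             products=("epoxycarotenoid",),
                             enzyme="ZEP", doc_id="zep-example"),
                GoldReaction(substrates=("epoxycarotenoids",),
                             products=("xanthoxin",),
                             enzyme="NCED", doc_id="zep-example"),
                GoldReaction(substrates=("ABA aldehyde",),
                             products=("ABA",),
                             enzyme="AAO", doc_id="zep-example"),
            ),
            note="Three reactions in one sentence, one clause each.",
        )
    )

    text = (
        "Enoyl-CoA hydratase catalyzes the second reaction of the fatty "
        "acid β-oxidation, i.e., the syn addition of water to "
        "α,β-unsaturated fatty acyl-CoA thioesters."
    )
    doc = Document.from_text("hydratase-example", text)
    examples.append(
        PackagedExample(
            name="hydratase",
            document=doc,
            mentions=(
                _mention(doc, "Enoyl-CoA hydratase", PROTEIN),
                _mention(doc, "water", SMALL_MOLECULE),
                _mention(doc, "α,β-unsaturated fatty acyl-CoA "
                              "thioesters", SMALL_MOLECULE),
            ),
            expected_reactions=(),
            note=(
                "Known hard case: the reaction is described as a "
                "molecular addition with no explicit product, so there "
                "is no correct ternary extraction from this sentence."
            ),
        )
    )

    text = (
        "At the beginning of this reaction, 1 molecule of 'Oxygen', 1 "
        "molecule of 'H2O', and 1 molecule of '5-Hydroxytryptamine' are "
        "present. At the end of this reaction, 1 molecule of 'NH3', 1 "
        "molecule of '5-Hydroxyindoleacetaldehyde', and 1 molecule of "
        "'H2O2' are present."
    )
    doc = Document.from_text("reactome-example", text)
    examples.append(
        PackagedExample(
            name="reactome-passage",
            document=doc,
            mentions=(
                _mention(doc, "Oxygen", SMALL_MOLECULE),
                _mention(doc, "H2O", SMALL_MOLECULE),
                _mention(doc, "5-Hydroxytryptamine", SMALL_MOLECULE),
                _mention(doc, "NH3", SMALL_MOLECULE),
                _mention(doc, "5-Hydroxyindoleacetaldehyde", SMALL_MOLECULE),
                _mention(doc, "H2O2", SMALL_MOLECULE),
            ),
            expected_reactions=(
                GoldReaction(
                    substrates=("Oxygen", "H2O", "5-Hydroxytryptamine"),
                    products=("NH3", "5-Hydroxyindoleacetaldehyde", "H2O2"),
                    enzyme=None, doc_id="reactome-example",
                ),
            ),
            note=(
                "Database-style passage: the reaction spans two "
                "sentences, a phrasing unlikely in journal prose and "
                "outside the reach of single-sentence extraction."
            ),
        )
    )
    return examples


DEFAULT_TEMPLATES_WITH_ENZYME = (
    "{E} catalyzes the conversion of {S} to {P}.",
    "{S} is converted to {P} by {E}.",
    "{E} catalyzes the reaction that converts {S} into {P}.",
)
DEFAULT_TEMPLATES_WITHOUT_ENZYME = (
    "{S} is converted to {P}.",
    "{S} is hydrolysed to {P}.",
    "{P} is formed from {S}.",
)
DEFAULT_FILLER_TEMPLATES = (
    "{M1} and {M2} were measured in cell extracts.",
    "High levels of {M1} and {M2} were detected.",
    "The ratio of {M1} to {M2} remained constant.",
    "Neither {M1} nor {M2} accumulated in the mutant strain.",
)

DEFAULT_METABOLITES = (
    "glucose", "fructose", "pyruvate", "lactate", "citrate", "isocitrate",
    "succinate", "fumarate", "malate", "oxaloacetate", "glutamate",
    "glutamine", "aspartate", "alanine", "serine", "glycine", "threonine",
    "arabinose", "ribulose", "xylulose", "ribose", "galactose", "mannose",
    "sorbitol", "glycerol", "acetoacetate", "propionate", "butyrate",
    "palmitate", "stearate", "chorismate", "shikimate", "mevalonate",
    "squalene", "ornithine", "citrulline", "putrescine", "spermidine",
    "inosine", "xanthine",
)
DEFAULT_ENZYMES = (
    "hexokinase", "glucokinase", "aldolase", "enolase", "fumarase",
    "aconitase", "invertase", "amylase", "cellulase", "lactase",
    "maltase", "sucrase", "peptidase", "protease", "nuclease",
    "phosphatase", "dehydratase", "racemase", "mutase", "epimerase",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic corpus.

    Defaults mirror the structure of the small manually-selected
    training corpus: equal numbers of reaction and non-reaction
    sentences, and an enzyme named in only 70% of reaction sentences.
    """

    seed: int = 0
    n_sentences: int = 200
    reaction_fraction: float = 0.5
    enzyme_omission: float = 0.3
    distractor_prob: float = 0.0
    sentences_per_doc: int = 5
    pathway_length: int = 10
    templates_with_enzyme: tuple = DEFAULT_TEMPLATES_WITH_ENZYME
    templates_without_enzyme: tuple = DEFAULT_TEMPLATES_WITHOUT_ENZYME
    filler_templates: tuple = DEFAULT_FILLER_TEMPLATES
    metabolites: tuple = DEFAULT_METABOLITES
    enzymes: tuple = DEFAULT_ENZYMES

    def __post_init__(self):
        for name in ("reaction_fraction", "enzyme_omission",
                     "distractor_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.metabolites or not self.enzymes:
            raise ValueError("vocabulary pools must be non-empty")
        if len(self.metabolites) < self.pathway_length + 2:
            raise ValueError(
                "need at least pathway_length + 2 metabolites (the chain "
                "plus a disjoint filler pool)"
            )
        if len(self.enzymes) < self.pathway_length:
            raise ValueError("need at least pathway_length enzymes")


@dataclass
class CorpusBundle:
    documents: list
    mentions: list
    gold_corpus: list  # GoldReaction with doc_id, in planting order
    gold_pathway: PathwayGold

    def enzymeless_fraction(self) -> float:
        """Fraction of planted reaction sentences naming no enzyme."""
        if not self.gold_corpus:
            return 0.0
        return (sum(1 for g in self.gold_corpus if g.enzyme is None)
                / len(self.gold_corpus))


_SLOT = re.compile(r"\{(E|S|P|M1|M2)\}")


def _render(template: str, values: dict) -> tuple[str, list]:
    """Instantiate a template, returning the sentence and slot spans."""
    out = []
    spans = []
    pos = 0
    cursor = 0
    for m in _SLOT.finditer(template):
        out.append(template[pos:m.start()])
        cursor += m.start() - pos
        value = values[m.group(1)]
        spans.append((m.group(1), cursor, cursor + len(value)))
        out.append(value)
        cursor += len(value)
        pos = m.end()
    out.append(template[pos:])
    sentence = "".join(out)
    # sentences must start with a capital for the splitter's benefit
    sentence = sentence[:1].upper() + sentence[1:]
    return sentence, spans


def generate_corpus(spec: SyntheticSpec) -> CorpusBundle:
    """Generate a seeded synthetic corpus with gold annotations.

    The same seed yields a byte-identical corpus. Every planted
    reaction's entities appear verbatim in its sentence, every planted
    reaction is drawn from the linear gold pathway, and filler sentences
    contain at least two molecules but no reaction keywords in scoring
    positions.
    """
    rng = random.Random(spec.seed)
    k = spec.pathway_length
    chain = list(spec.metabolites[: k + 1])
    chain_enzymes = list(spec.enzymes[:k])
    filler_pool = list(spec.metabolites[k + 1:])
    pathway_reactions = tuple(
        GoldReaction(substrates=(chain[i],), products=(chain[i + 1],),
                     enzyme=chain_enzymes[i])
        for i in range(k)
    )
    gold_pathway = PathwayGold(
        pathway_id=f"synthetic-linear-{k}",
        reactions=pathway_reactions,
        side_metabolites=frozenset(),
    )

    n_reaction = round(spec.n_sentences * spec.reaction_fraction)
    plan = ["reaction"] * n_reaction
    plan += ["filler"] * (spec.n_sentences - n_reaction)
    rng.shuffle(plan)

    sentences = []  # (text, [(role, start, end, canonical_name)], gold|None)
    for kind in plan:
        if kind == "reaction":
            ridx = rng.randrange(k)
            reaction = pathway_reactions[ridx]
            omit = rng.random() < spec.enzyme_omission
            template = rng.choice(
                spec.templates_without_enzyme if omit
                else spec.templates_with_enzyme
            )
            values = {"S": reaction.substrates[0],
                      "P": reaction.products[0]}
            if not omit:
                values["E"] = reaction.enzyme
            if spec.distractor_prob and rng.random() < spec.distractor_prob:
                distractor = rng.choice(filler_pool)
                template = template[:-1] + " in the presence of {M1}."
                values["M1"] = distractor
            text, spans = _render(template, values)
            slots = [
                (role, s, e, values[role]) for role, s, e in spans
            ]
            gold = GoldReaction(substrates=reaction.substrates,
                                products=reaction.products,
                                enzyme=None if omit else reaction.enzyme)
            sentences.append((text, slots, gold))
        else:
            template = rng.choice(spec.filler_templates)
            m1, m2 = rng.sample(filler_pool, 2)
            text, spans = _render(template, {"M1": m1, "M2": m2})
            slots = [(role, s, e, {"M1": m1, "M2": m2}[role])
                     for role, s, e in spans]
            sentences.append((text, slots, None))

    documents: list[Document] = []
    mentions: list[EntityMention] = []
    gold_corpus: list[GoldReaction] = []
    for d0 in range(0, len(sentences), spec.sentences_per_doc):
        group = sentences[d0:d0 + spec.sentences_per_doc]
        doc_id = f"synth-{d0 // spec.sentences_per_doc:04d}"
        offsets = []
        cursor = 0
        parts = []
        for text, _, _ in group:
            offsets.append(cursor)
            parts.append(text)
            cursor += len(text) + 1
        doc = Document.from_text(doc_id, " ".join(parts))
        if len(doc.sentences) != len(group):  # pragma: no cover
            raise AssertionError("splitter disagreed with planted sentences")
        documents.append(doc)
        for sidx, (text, slots, gold) in enumerate(group):
            base = offsets[sidx]
            for role, s, e, _name in slots:
                start, end = base + s, base + e
                etype = PROTEIN if role == "E" else SMALL_MOLECULE
                mentions.append(
                    EntityMention(doc_id, sidx, start, end,
                                  doc.text[start:end], etype, 1.0,
                                  "standoff")
                )
            if gold is not None:
                gold_corpus.append(
                    GoldReaction(substrates=gold.substrates,
                                 products=gold.products,
                                 enzyme=gold.enzyme, doc_id=doc_id)
                )
    return CorpusBundle(documents, mentions, gold_corpus, gold_pathway)


def write_corpus(bundle: CorpusBundle, out_dir: str) -> None:
    """Write documents, standoff TSV and gold files under ``out_dir``."""
    from .tagging import write_standoff

    docs_dir = os.path.join(out_dir, "docs")
    os.makedirs(docs_dir, exist_ok=True)
    for doc in bundle.documents:
        with open(os.path.join(docs_dir, f"{doc.doc_id}.txt"), "w",
                  encoding="utf-8") as fh:
            fh.write(doc.text + "\n")
    write_standoff(bundle.mentions, os.path.join(out_dir, "standoff.tsv"))
    with open(os.path.join(out_dir, "gold_corpus.json"), "w",
              encoding="utf-8") as fh:
        json.dump(
            [
                {
                    "doc_id": g.doc_id,
                    "enzyme": g.enzyme,
                    "substrates": list(g.substrates),
                    "products": list(g.products),
                }
                for g in bundle.gold_corpus
            ],
            fh, indent=2,
        )
        fh.write("\n")
    from .evaluate import save_pathway_json

    save_pathway_json(bundle.gold_pathway,
                      os.path.join(out_dir, "gold_pathway.json"))


def load_gold_corpus_json(path: str) -> list[GoldReaction]:
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    return [
        GoldReaction(substrates=tuple(r["substrates"]),
                     products=tuple(r["products"]),
                     enzyme=r.get("enzyme"), doc_id=r.get("doc_id"))
        for r in data
    ]
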