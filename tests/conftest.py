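import random

import pytest

from reactionminer import Document, EntityMention, load_config, select_sentences
from reactionminer.tagging import PROTEIN, SMALL_MOLECULE


@pytest.fixture(scope="session")
def default_config():
    return load_config()


@pytest.fixture(scope="session")
def lexicon(default_config):
    return default_config[0]


@pytest.fixture(scope="session")
def weights(default_config):
    return default_config[1]


def mention(doc: Document, surface: str, etype: str,
            occurrence: int = 0) -> EntityMention:
    """Build a mention by locating the nth occurrence of ``surface``."""
    start = -1
    for _ in range(occurrence + 1):
        start = doc.text.find(surface, start + 1)
        assert start >= 0, f"{surface!r} not in {doc.doc_id}"
    end = start + len(surface)
    sent_index = next(s.sent_index for s in doc.sentences
                      if s.start <= start and end <= s.end)
    return EntityMention(doc.doc_id, sent_index, start, end, surface, etype)


def candidate_from(text: str, molecules, proteins=(), doc_id="t"):
    """One-sentence candidate with mentions found by surface string."""
    doc = Document.from_text(doc_id, text)
    mentions = [mention(doc, m, SMALL_MOLECULE) for m in molecules]
    mentions += [mention(doc, p, PROTEIN) for p in proteins]
    cands = select_sentences(doc, mentions)
    assert len(cands) == 1
    return cands[0]


_FILLER = ["slowly", "rapidly", "thereby", "again", "under", "these",
           "conditions", "while", "cells", "grow"]
_KEYWORDS = ["conversion", "converted", "formed", "produces", "to", "from",
             "by", "and", "catalyzes", "hydrolysis", "gives", "into"]


def random_candidate(rng: random.Random, keyword_free: bool = False,
                     max_molecules: int = 4, max_proteins: int = 2):
    """A random small candidate sentence for property tests."""
    n_mol = rng.randint(2, max_molecules)
    n_prot = rng.randint(0, max_proteins)
    names = [f"metab{chr(ord('A') + i)}" for i in range(n_mol)]
    prots = [f"enzyme{i}ase" for i in range(n_prot)]
    pool = list(_FILLER) + ([] if keyword_free else _KEYWORDS)
    words = []
    entities = names + prots
    rng.shuffle(entities)
    for e in entities:
        words.extend(rng.sample(pool, rng.randint(0, 3)))
        words.append(e)
    words.extend(rng.sample(pool, rng.randint(0, 2)))
    text = "The " + " ".join(words) + "."
    return candidate_from(text, names, prots)
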