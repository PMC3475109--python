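# Methods

## Model

reactionminer treats a metabolic reaction as a ternary relation — an
optional enzyme, one or more substrates, one or more products — and
assumes that such relations are usually expressed within a single
sentence. Extraction is a generate-and-score procedure over tagged
entity mentions:

1. candidate sentences are those containing ≥ 2 small-molecule
   mentions (an enzyme is optional, since roughly 30% of reaction
   sentences in metabolic prose name none);
2. role assignments are enumerated under a *contiguous-block*
   plausibility constraint: at least one substrate and one product,
   and in sentence order the assigned molecules form one substrate
   block and one product block with no interleaving. With one tagged
   protein and three molecules this produces exactly ten assignments
   (4 with all molecules assigned + 6 with one unassigned). The
   deterministic enumeration order is: more molecules assigned first,
   substrate-block-first before product-block-first, assigned index
   combinations lexicographically, block boundary moving rightward.
   When a protein is tagged, every assignment names an enzyme;
   enzyme-less assignments are enumerated only for sentences with no
   tagged protein;
3. each assignment is scored by four positional keyword rules
   (weights below) and assignments at or above the threshold become
   predictions, highest score first, skipping any role permutation of
   an already-emitted mention set.

### Scoring rules and weights

| rule | default | meaning |
|---|---|---|
| gap penalty | −0.1 / word | words between the outermost assigned S/P mentions not inside any assigned entity (enzyme included as assigned) |
| keyword reward | +2 / keyword | keyword token in an appropriate location |
| misplaced keyword | −1 / keyword | keyword token in an inappropriate location |
| reaction+production bonus | +2 once | reaction-side and production-side evidence co-occur |
| decision threshold | 3.0 | assignments below it are discarded |

Appropriate locations: a reaction stem between the enzyme and the
nearest substrate mention, or between the substrate and product
blocks; a production stem between the blocks; *to*/*into* between the
blocks when substrates precede products; *from* between the blocks
when products precede substrates (reversed phrasing, "P is formed from
S"); *by* between the last assigned molecule and a following enzyme;
*and* between the last two mentions of a same-role block; a *catalyze*
variant anywhere in the sentence, provided an enzyme is assigned (a
catalysis verb with no enzyme is uninformative). Inappropriate
locations, each individually switchable in config: a production stem
before the first substrate; a reaction stem after the last product
when the enzyme precedes the substrates; *to*/*into* inside a role
block. A token receives at most one credit, and a credited token is
never also penalized.

The bonus fires when (an appropriately-placed reaction stem **or** a
credited catalyze variant) co-occurs with (an appropriately-placed
production stem **or** a credited *to*/*into*). Treating the
directional preposition as production-side evidence is an
interpretation choice: it is the reading under which the worked
exemplar sentence ("L-Arabinose isomerase catalyzes the conversion of
L-arabinose to L-ribulose, …") comes out at exactly +7.2 points
(+2 *conversion*, +2 *to*, +2 *catalyzes*, +2 bonus, −0.8 for its
eight gap words), and it is pinned by test.

A consequence worth knowing: on that same exemplar the two-molecule
assignment (substrate L-arabinose, product L-ribulose, n-arabinose
unassigned) earns the same keyword credits but only one gap word and
therefore scores 7.9, outranking the three-molecule 7.2 reading. The
top emitted prediction is thus the biochemically correct
two-participant reaction; the 7.2 assignment is emitted second (its
mention set differs). Ranking is purely by score, with ties broken by
fewer unassigned molecules, then enumeration order.

### Keywords and stemming

Keyword stems are matched by prefix against the Porter stem of each
token, so the truncated stem *hydrolys* covers *hydrolysis*,
*hydrolysed*, *hydrolyses*. Prepositions and the conjunction match by
exact lowercase surface (so *toward* is not *to*). The stemmer is the
classic 1980 suffix-stripping algorithm, implemented in-package and
pinned against the example pairs published with the original rule
tables; keeping the stemmer internal guarantees the stem-prefix
contract between lexicon and tokenizer cannot drift with an external
library's revisions.

The shipped reaction list combines the canonical exemplars (*add*,
*convert*, *hydrolys*, *dimeris*) with a curated extension derived
from EC class nomenclature (*oxid*, *reduc*, *transfer*, *cleav*,
*ligat*, *isomeris/-iz*, *epoxid*, *phosphorylat*, …); the production
list (*form*, *give*, *produc*, *synthesi*, *yield*, *generat*, …) was
assembled the same way. All lists and weights live in YAML config, not
code. Config validation rejects a stem entry when the stemmer's
suffix-stripping steps would rewrite it (e.g. *formed*, whose *-ed* is
stripped, would never prefix-match its own inflection family), while
permitting entries touched only by the letter-level normalizations
(plural-s, final y→i, e-tidying) that legitimately affect truncated
stems such as *hydrolys*. Cross-category prefix overlap is also an
error, which keeps keyword categorisation a function.

## Entity tagging

The scorer is tagger-agnostic; the reference input path is a standoff
TSV (`doc_id  start  end  surface  etype  confidence`, 0-based
half-open offsets in Unicode code points) validated against the
document text. Two deliberately simple built-in taggers are provided
for self-contained use: case-insensitive longest-match dictionary
lookup, and an enzyme suffix rule that seeds on *-ase/-ases* word
tokens (length > 4, stoplisted against *increase*, *disease*, *phase*,
…) and extends left over up to three contiguous modifier tokens, so
*pyruvate dehydrogenase* is captured rather than bare *dehydrogenase*.
The leftward cap and stopword list are boundary conventions, chosen to
bound false spans.

Chemical acronym filtering: a small-molecule mention consisting of a
single all-uppercase token (≥ 2 letters) is kept only if its first
parenthesised occurrence directly follows another chemical mention
("adenosine triphosphate (ATP)") or its tagger confidence is ≥ 0.5 —
the latter admits household acronyms such as NAD that are used without
definition. The filter never touches proteins, multi-token or
lowercase mentions, and is monotone in confidence. An optional,
disabled-by-default confidence bump (+0.1) for protein names ending in
*-ase(s)* is available for taggers that over-generate candidate names.

## Network assembly

Predictions merge into a reaction network when identical after name
normalization (lowercase, whitespace collapse, trailing punctuation
strip, then an optional user-supplied synonym map applied to a fixed
point). Identity is deliberately surface-level — no ontology
grounding. Each merged reaction records its extraction count and
supporting (document, sentence) evidence; the graph view renders a
reaction as substrate→enzyme plus enzyme→product arrows (or a direct
substrate→product arrow when no enzyme was found). Exports (GraphML,
TSV) are emitted in sorted order and are byte-stable.

## Evaluation

Metrics follow the pathway-reconstruction convention: recall(C) over
gold items annotated in a corpus, recall(P) over the reactions of a
curated pathway (each counted once however often extracted), precision
over predictions, F-score the harmonic mean of recall(C) and
precision. Zero denominators yield "undefined", never 0. Reaction
matching is direction-preserving (substrates must match substrates),
optionally enzyme-inclusive, and filters a configurable side-metabolite
set (ATP, ADP, NAD(H), CoA, H₂O, …) from the gold first, because
authors routinely leave cofactors implicit. Reactions also decompose
into substrate–product, substrate–enzyme and product–enzyme pairs for
binary-level scoring; the pair count per reaction is
|S|·|P| + (|S|+|P|)·[enzyme present].

*Sloppy* name matching credits a prediction when the names are equal
(case-insensitive), when one name's token sequence occurs contiguously
inside the other's, or when the head token of either name occurs among
the other's tokens (names tokenized on whitespace, hyphens and
colons). This reproduces the intended behaviour on hard boundary
cases: *phosphopantetheine*, *4′-phosphopantetheine moiety* and even
*key precursor of the 4′* all count as sloppy hits for the gold name
*4′-phosphopantetheine*, while strict matching accepts only the exact
name. Whether a direction-swapped match should earn recall credit was
an open choice; direction is enforced, pinned by test.

## Synthetic corpus

The generator emulates the structure of a small hand-picked training
corpus: `n_sentences` (default 200) split half-and-half between
reaction sentences and filler sentences that mention ≥ 2 molecules
without describing a reaction; reaction sentences omit the enzyme with
probability 0.3. Planted reactions are drawn from a linear
10-step gold pathway so network aggregation and recall(P) are
exercisable; vocabulary pools (40 metabolites, 20 enzyme names) are
config data, as are the sentence templates, so users can add phrasings
(e.g. the fatty-acid "addition of water" style the rules handle
poorly) without code changes. An optional distractor probability
appends an uninvolved molecule to reaction sentences. The same integer
seed yields a byte-identical corpus.

What the generator does *not* emulate: tagger noise (mentions are
gold), anaphora, negation/speculation, cross-sentence reactions,
article sectioning, and the long, multi-clause sentences of real
prose. Perfect recovery on the zero-noise corpus therefore
demonstrates internal consistency of the pipeline — that canonical
phrasings score above threshold and are emitted with the right roles —
not real-literature performance, which on published pathway
evaluations of this family of methods runs at roughly 30–90% recall
and 14–60% precision depending on pathway and matching mode.

## Numerical and degenerate-input conventions

Scores are plain floats; the component breakdown must sum to the total
within 1e-9 (enforced by the `ScoredAssignment` invariant). Sentences
with more than 8 molecule or 3 protein mentions are truncated to the
highest-confidence mentions (leftmost on ties) before enumeration,
with a logged warning — an uncapped 12-molecule sentence would
otherwise enumerate tens of thousands of assignments for negligible
fixture benefit. Empty documents, sentences without mentions, and
empty prediction lists flow through every stage without error. The
sentence splitter is a rule-based approximation (terminal punctuation
followed by whitespace and a capital/digit, with abbreviation,
decimal-number and initials exceptions); it is deterministic and exact
on all packaged fixtures but is not a statistical model, and documents
relying on exotic sentence punctuation may split differently than a
trained splitter would.

## Problem sizes used in the shipped checks

The acceptance script runs the worked example (1 sentence, 4
mentions), a 50-sentence zero-noise corpus for end-to-end
recall/precision, and a 2000-sentence corpus (1000 reaction sentences)
for the enzyme-omission rate; the property suites in the test
directory each draw ≥ 1000 seeded random cases. These sizes keep the
whole battery under a few seconds while leaving the binomial noise on
rate estimates (±~1.5 percentage points at n = 1000) well inside the
asserted tolerances.
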