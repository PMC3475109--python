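# reactionminer

Rule-based extraction of **metabolic reactions** — ternary relations of
the form *enzyme, substrate(s) → product(s)* — from free text, with
pathway-network assembly and a pathway-oriented evaluation suite. It is
aimed at curators and systems biologists who want candidate reactions
mined from the literature to seed or cross-check pathway databases, and
at text-mining researchers who need a transparent, fully inspectable
baseline for the metabolic relation-extraction task.

## The algorithm

Given text in which protein and small-molecule names have been tagged
(by any tagger — annotations are exchanged as character-offset standoff
records), extraction proceeds in three stages per sentence:

1. **Sentence selection.** Keep sentences containing at least two small
   molecules. An enzyme name is *not* required: a substantial fraction
   of reaction sentences (about 30% in metabolic literature) name none.
2. **Entity assignment.** Enumerate the plausible ways of mapping the
   tagged mentions onto roles E (enzyme), S (substrate), P (product) or
   unassigned: at least one S and one P, and the assigned molecules
   must form two contiguous blocks in sentence order (no S–P–S
   interleaving). For one protein and three molecules this yields
   exactly ten assignments.
3. **Assignment scoring.** Each assignment receives a score

   * −0.1 per word between the outermost assigned S/P mentions that
     belongs to no assigned entity (a compactness penalty),
   * +2 per keyword in an appropriate location — reaction stems
     (*convert*, *hydrolys-*, …) between enzyme and substrate or
     between the S and P blocks; production stems (*form*, *produc-*,
     …) and *to*/*into* between the blocks; *from* for reversed
     phrasings; *by* before a trailing enzyme; *and* inside a
     multi-member role block; *catalyze* variants anywhere when an
     enzyme is assigned,
   * −1 per keyword in an inappropriate location (e.g. a production
     word before the first substrate),
   * +2 bonus when reaction-side and production-side evidence co-occur.

   Keywords are matched by Porter-stem prefix, so one truncated stem
   covers a whole inflection family. Assignments scoring ≥ 3.0 become
   predicted reactions, highest score first; role permutations of an
   already-emitted mention set are skipped, so a sentence can yield
   several *distinct* reactions but never the same mention set twice.

Predictions aggregate into a directed network (substrate → enzyme →
product arrows, weighted by extraction count) and are scored against
curated pathways with recall(C), recall(P), precision and F-score,
under strict or sloppy name matching, ignoring or including the enzyme,
with ubiquitous side metabolites (ATP, NAD, H₂O, …) excluded from gold.

## Worked example

```sh
cat > sentence.txt <<'EOF'
L-Arabinose isomerase catalyzes the conversion of L-arabinose to L-ribulose, the first step in the utilization of n-arabinose by Escherichia coli B/r.
EOF
printf 'L-arabinose\nL-ribulose\nn-arabinose\n' > molecules.txt
reactionminer extract sentence.txt --molecule-dict molecules.txt --explain
```

The built-in “-ase” suffix tagger finds the enzyme *L-Arabinose
isomerase*; the dictionary tagger finds the three sugars. Four
assignments clear the 3.0 threshold (score, enzyme, substrates →
products, component breakdown):

```
7.9  L-Arabinose isomerase  L-arabinose → L-ribulose
     catalyzes +2, conversion +2, to +2, bonus +2, gap(1 word) −0.1
7.2  L-Arabinose isomerase  L-arabinose → L-ribulose; n-arabinose
     catalyzes +2, conversion +2, to +2, bonus +2, gap(8 words) −0.8
7.1  L-Arabinose isomerase  L-arabinose → n-arabinose
3.3  L-Arabinose isomerase  L-ribulose → n-arabinose
```

The top prediction is the correct reaction (L-arabinose → L-ribulose,
catalyzed by the isomerase): the verb *catalyzes*, the reaction noun
*conversion* between enzyme and substrate, and the preposition *to*
between substrate and product each contribute +2, their co-occurrence
adds the +2 bonus, and the single intervening word (*to*) costs −0.1.
The three-molecule reading of the same sentence scores 7.2 — its eight
gap words cost −0.8 — and is emitted as a lower-ranked alternative.

Other entry points: `reactionminer synth` writes a seeded synthetic
corpus with gold annotations, `reactionminer evaluate` scores JSONL
predictions against gold reactions, `reactionminer network` exports a
GraphML/TSV pathway network, and `reactionminer dump-config` prints the
effective keyword lists and weights (all of which can be overridden
from a YAML file).

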