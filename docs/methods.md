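# Methods

This note documents the models and procedures implemented in `semres`, the
parameters that matter, the numerical choices, what the synthetic data
generator does and does not emulate, and the known limitations.

## Semantic annotation

### Matching score

A chunk `T` and a lexical variant `S` are compared as **bags of words**
(repeated tokens count with multiplicity). With
`info(S) = −Σ_w log P(w | Background)` in natural log,

```
sim(C, T) = max_{S ∈ lex(C)} ( info(S ∩ T) − info(S − T) ) / info(S)
```

Because the bag of `S` partitions exactly into `S ∩ T` and `S − T`, the score
equals `2·cov − 1` with `cov = info(S ∩ T)/info(S) ∈ [0, 1]`, hence
`sim ∈ [−1, 1]` with +1 iff some variant is fully covered and −1 iff no
variant shares a token. The score is a ratio of infos, so it is invariant to
the logarithm base; natural log is used throughout (tf·idf ranking is
monotone-invariant to the base as well).

### Background model and OOV floor

Word probabilities come from a counts table (`word <TAB> count`); counts are
preferred over probabilities so an out-of-vocabulary floor can be derived:
unseen words get `1/(2·N)` where `N` is the total token count — half the mass
of a hapax. The floor is strictly positive so `info` is always finite and any
non-empty variant has positive information.

### Tokenization

Case-folding and punctuation stripping, no stemming by default (the score is
defined over surface bags of words; morphology is a separate concern). A
light plural-stripping stemmer is available as a `TokenPolicy(stem=True)`
switch. The same policy object is carried by the lexicon so both sides of
every comparison normalize identically.

### Chunking

The chunker is rule-based and sits behind `chunk_text` so a POS-based chunker
could be swapped in: maximal runs of non-stopword tokens delimited by
stopwords or sentence punctuation, plus every contiguous sub-window of a run
up to 6 tokens. Emitting sub-windows guarantees that an entity mention
embedded in a larger run ("protein sequences" inside "align protein
sequences") is itself a candidate chunk. Overlapping chunks are annotated
independently; a per-(concept, variant, score) pass then keeps only minimal
spans so that term frequency counts *mentions*, not enclosing windows.
Grouping by score keeps annotation anti-monotone in the threshold (raising
the threshold can only remove annotations).

### Selection

Per chunk, concepts with `sim ≥ threshold` (default 0.7) are ranked by score,
then by how many chunk tokens the matched variant covers; all concepts still
tied after both criteria are returned — downstream refinement (concept
selection, narrower/broader substitution) is the intended disambiguation
mechanism, not the annotator. Output is ordered by (span start, span end,
concept id) and is a pure function of its inputs.

## Facet extraction

The generic pattern is `(noun-phrase)? relation E-noun-phrase`. The shipped
pattern table (`src/semres/data/default_patterns.yaml`) defines input, output
and method rows; species and disease are extracted via semantic types
(defaults: species ← {Bacterium, Virus, Mammal, Species}, disease ←
{Disease}). New facets are added purely by configuration.

Decisions where the design was genuinely open:

* **Relation matching** is case-insensitive on normalized token subsequences,
  so multi-word relations ("Based on", "Carries out") match anywhere.
* **Leading NP forms.** Keyword rows (`inputs?`/`outputs?` before a copula)
  *require* the keyword as the head of the phrase immediately preceding the
  relation; otherwise bare "is"/"are" would fire both input and output facets
  on every copula. Entity rows record the preceding noun phrase (or pronoun
  "it") when present and leave NP empty otherwise. Rows like "given" record
  no NP.
* **E-noun-phrase scope**: the earliest annotated span starting within 5
  tokens after the relation, widened to the widest annotated span at that
  start; its nested annotations all contribute concepts. The window size is a
  parameter (`window=5`).

## Requirements model

Tasks carry explicit facet values as free text (annotated like any
description) or as concept-id lists (taken literally with tf = 1). Facet
origins are merged with priority **explicit > text-extracted > propagated**.

`propagate_io` fills a missing input facet with the union of the task's
dependencies' output vectors, and a missing output with the union of its
dependents' input vectors (union = weight-summing merge). Each pass reads
only the state it started from; passes repeat until nothing changes, so one
call returns the fixpoint and the operation is idempotent. Propagation never
crosses a task that has no vector to give: inputs do not turn into outputs.

## Topic-based ranking

Per facet (and for the whole description, the "task level") a
concept×resource tf·idf matrix is factorized with seeded NMF
(`init="random"`, fixed `random_state`, 500 iterations); the concept factor is
column-normalized into `P(c|t)`, the resource factor into `P(t|ws)`. A
resource without a given facet backs off to its whole-description vector so
every resource has a distribution for every facet.

Numerical choices:

* `SMOOTHING_EPS = 1e-6` is added to every cell before normalization, so all
  probabilities are strictly positive and the normalization invariants
  (`Σ_c P(c|t) = 1`, `Σ_k P(t|ws) = 1`) hold to 1e-9.
* Query concepts absent from a facet's concept index contribute a constant
  `1e-6`, which scales all resources equally and never reorders them.
* Likelihoods are accumulated in log space and exponentiated once; products
  over a handful of concepts stay far from underflow, and the log form agrees
  with direct products to 1e-9 on small instances.
* If the requested number of topics exceeds the matrix rank budget
  (`min(#concepts, #resources)`), the factorization runs at the feasible size
  and is padded with empty topics that smoothing keeps valid.
* Ties in the final ranking break by resource id, so rankings are total and
  reproducible; with one topic all resources receive identical likelihoods by
  construction.

Default combination weights: `α = 0.5`, the remaining mass split equally over
the facets present in the query (`α = 1` when there are none). The number of
topics is exposed as configuration; the CLI defaults to 7, matching the
number of broad bioinformatics task families used in the evaluation design,
but there is no principled universal value — treat it as a knob.

## Synthetic data generator

`semres.synthetic` produces every input format with known ground truth. Its
defaults are the package's study conditions: 40 concepts in a rooted tree
(depth 4, branching 3), up to 2 variants per concept of 1–2 words, 50
resources split evenly over 2 planted topics, 100 queries, ~8 concepts
embedded per resource, facet sentences on every resource.

What it emulates: descriptions that mention domain concepts by exact lexical
variants amid uninformative filler; facet statements in relational form
("X gets/returns/implements Y"); topically coherent resources; Zipf-like
word frequencies in the background model.

What it deliberately does not emulate — and hence what passing tests do *not*
show about real catalogue text: morphological and spelling variation between
mention and variant, ambiguous surface forms shared by concepts (variant
words are disjoint across concepts by default; the `variant_overlap` knob
re-introduces sharing for stress tests), mentions interrupted by stopwords,
mixed-topic resources, and realistic description length distributions.
Planted recall/precision of 1.0 is a *correctness* property of the machinery
under clean conditions, not a performance claim; on real data annotation
quality is bounded by lexicon coverage, which is exactly why the repository
loader is format-based and pluggable.

Determinism: all randomness flows through `numpy.random.default_rng` seeded
from the spec, and all files are written with sorted keys and fixed newlines,
so equal seeds give byte-identical workspaces, indices and rankings.

## Evaluation metrics

Set precision/recall/F over retrieved vs relevant ids (precision of an empty
retrieved list is undefined and reported as 0 with a warning), precision at a
cutoff k over the available prefix, and average precision for ranked lists.
Facet extraction is scored tag-by-tag: each gold tag is paired with the
extracted concept maximizing F over their resource sets (lexicographically
smallest concept on ties), and P/R of the chosen pairs are macro-averaged
with weight `1/|tags|`. The harmonic F uses the same (tag, concept) pair in
numerator and denominator.

## Known limitations

* The rule-based chunker has no syntactic knowledge; it over-generates
  candidate chunks and relies on the scoring threshold to stay precise.
* Word-sense disambiguation is limited to score/coverage ranking plus manual
  refinement; genuinely ambiguous variants yield multiple annotations.
* NMF is one way to realize the topic tables; the estimator interface is the
  contract, not the factorization. Likelihoods from different facet tables
  are combined linearly without calibration, so α/β weights are meaningful
  only relative to each other.
* The extraction pattern table is curated, not learned; coverage of unusual
  phrasings depends entirely on configuration.
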