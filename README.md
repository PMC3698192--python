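# semres

Semantic retrieval of life-science web resources that are described only by
free text. Open metadata registries (service catalogues, tool registries)
rarely carry structured metadata: input/output data types, the method behind a
tool, or the species and diseases involved usually live inside an informal
prose description. `semres` is a library for finding the right resource
anyway. It normalizes both resource descriptions and the user's requirements
into a shared concept space, extracts faceted metadata from the text, and
ranks resources against text-rich, faceted queries.

It is aimed at people building search over biomedical tool/service
catalogues, and at anyone who needs unsupervised dictionary-based concept
annotation with an information-theoretic matching score.

## The model

**Semantic annotation.** A knowledge repository supplies concepts `C`, each
with lexical variants `lex(C)`, semantic types and an `is_a` taxonomy. Text
chunks `T` (noun-phrase candidates) are matched against variants with an
information-coverage score over bags of words:

```
sim(C, T) = max_{S ∈ lex(C)}  ( info(S ∩ T) − info(S − T) ) / info(S)
info(S)   = − Σ_{w ∈ S} log P(w | Background)
```

`sim ∈ [−1, 1]`: +1 when some variant is fully covered by the chunk, −1 when
no variant shares a word with it. Annotations require `sim ≥ 0.7` by default.
A description becomes a sparse tf·idf semantic vector with
`idf(C) = max_{S ∈ lex(C)} info(S)`.

**Facet extraction.** Instances of facets (input, output, method, species,
disease) are pulled from annotated text by extraction patterns of the generic
form `(noun-phrase)? relation E-noun-phrase` — where the E-noun-phrase is any
noun phrase containing at least one annotation — and directly from annotation
semantic types (e.g. `Disease`). Each facet of a description is the semantic
vector over the union of its instances' concepts.

**Requirements model.** A goal plus tasks with free-text descriptions,
explicit facet values and dependencies (a DAG). Tasks are normalized like any
description; a task missing its input facet inherits the outputs of the tasks
it depends on (and symmetrically for outputs).

**Ranking.** A topic model ties query concepts to resources. For facet `f`
and resource `ws_j`:

```
P(q | ws_j, f) = Π_{c_i ∈ q} Σ_k P(c_i ∈ f | t_k) · P(t_k | ws_j, f)
score(q, ws_j) = α · P(q | ws_j) + Σ_f β_f · P(q | ws_j, f),   α + Σ_f β_f = 1
```

The two probability tables come from a seeded non-negative factorization of
the concept×resource tf·idf matrix, column-normalized with epsilon smoothing.
Likelihoods are accumulated in log space. A cosine baseline over the raw
vectors is included for comparison.

Everything is testable offline: `semres.synthetic` generates a complete
workspace (repository, background word counts, resource corpus, requirements
model, relevance and facet gold standards) with known planted ground truth.

## Worked example

`examples/` contains one narrative script per capability
(`annotate_description.py`, `extract_facets.py`, `rank_resources.py`,
`evaluate_retrieval.py`). For instance:

```
$ python examples/annotate_description.py
description: 'build phylogenetic trees from a multiple sequence alignment with clustal'

  [ 6,24) 'phylogenetic trees'                   -> EDAM_0084 via 'phylogenetic trees' (sim=1.000)
  [32,59) 'multiple sequence alignment'          -> EDAM_0492 via 'multiple sequence alignment' (sim=1.000)
  [41,59) 'sequence alignment'                   -> EDAM_0492 via 'sequence alignment' (sim=1.000)
  [65,72) 'clustal'                              -> Wiki:W1234 via 'clustal' (sim=1.000)

tf·idf semantic vector (weight = mention count x max variant information):
  EDAM_0084: 8.420
  EDAM_0492: 19.216
  Wiki:W1234: 5.911
```

Each line is one annotation: character span, the chunk text, the concept it
maps to, the variant that matched, and the coverage score (1.0 = the variant
is fully present). The vector weights are `tf × idf`: `EDAM_0492` was
mentioned twice (the full phrase and its embedded head), and rare words carry
more information than common ones.

A thin CLI mirrors the shell-level workflow:

```
semres fixtures --seed 4 --out ws          # emit a synthetic workspace
semres annotate --workspace ws --corpus ws/resources.jsonl --out ws/ann.jsonl
semres rank --workspace ws --corpus ws/resources.jsonl \
            --requirements ws/requirements.json --topics 2 --seed 4
```

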