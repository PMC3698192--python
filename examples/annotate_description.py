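"""Annotate a free-text description against a small concept repository.

Builds a four-concept repository in memory, annotates one sentence, and prints
each annotation (span, concept, matched variant, information-coverage score)
plus the resulting tf·idf semantic vector. A score of 1.0 means every word of
the matched lexical variant occurs in the text chunk; the default threshold
0.7 discards weaker partial matches.
"""

from semres import (
    BackgroundModel,
    Concept,
    Repository,
    annotate,
    build_lexicon,
    to_vector,
)

repo = Repository({
    "EDAM_0492": Concept("EDAM_0492", frozenset({"sequence alignment", "multiple sequence alignment"})),
    "EDAM_0084": Concept("EDAM_0084", frozenset({"phylogenetic tree", "phylogenetic trees"})),
    "UMLS:C0033684": Concept("UMLS:C0033684", frozenset({"protein sequence", "protein sequences"}),
                             frozenset({"Protein"})),
    "Wiki:W1234": Concept("Wiki:W1234", frozenset({"clustal"})),
})
background = BackgroundModel.from_counts({
    "sequence": 900, "alignment": 300, "multiple": 800, "phylogenetic": 120,
    "tree": 500, "trees": 400, "protein": 700, "clustal": 40,
    "build": 1000, "from": 5000, "with": 5000,
})
lexicon = build_lexicon(repo)

text = "build phylogenetic trees from a multiple sequence alignment with clustal"
annotations = annotate(text, lexicon, background)

print(f"description: {text!r}\n")
for a in annotations:
    print(f"  [{a.start:2d},{a.end:2d}) {text[a.start:a.end]!r:38s} -> {a.concept_id}"
          f" via {a.variant!r} (sim={a.score:.3f})")

vector = to_vector(annotations, lexicon, background)
print("\ntf·idf semantic vector (weight = mention count x max variant information):")
for cid, w in sorted(vector.weights.items()):
    print(f"  {cid}: {w:.3f}")
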