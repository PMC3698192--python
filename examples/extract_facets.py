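"""Extract faceted metadata (input/output/method, species/disease) from
annotated descriptions.

Two mechanisms are shown: extraction patterns of the form
``(noun-phrase)? relation E-noun-phrase`` (the E-noun-phrase is an annotated
chunk following a facet-specific relation token such as "given" or "finds"),
and semantic types, where an annotation whose concept is typed e.g. Disease
directly defines the disease facet.
"""

from semres import (
    BackgroundModel,
    Concept,
    Repository,
    annotate,
    build_lexicon,
    extract_by_pattern,
    extract_by_semantic_type,
    facet_vectors,
    load_patterns,
)

repo = Repository({
    "UMLS:C0033684": Concept("UMLS:C0033684", frozenset({"protein sequence"}), frozenset({"Protein"})),
    "EDAM_0857": Concept("EDAM_0857", frozenset({"similar sequences"})),
    "UMLS:C0030567": Concept("UMLS:C0030567", frozenset({"parkinson disease"}), frozenset({"Disease"})),
})
background = BackgroundModel.from_counts({
    "protein": 700, "sequence": 900, "sequences": 600, "similar": 800,
    "parkinson": 30, "disease": 400, "search": 1000, "given": 2000,
    "blast": 100, "finds": 900, "related": 700, "genes": 500,
})
lexicon = build_lexicon(repo)
patterns = load_patterns()  # shipped pattern table: input/output/method rows

texts = [
    "search a similar sequence given a protein sequence",
    "BLAST finds similar sequences related to parkinson disease",
]
all_instances = []
for text in texts:
    annotations = annotate(text, lexicon, background)
    instances = extract_by_pattern(text, annotations, patterns)
    instances += extract_by_semantic_type(annotations, repo, patterns)
    all_instances += instances
    print(f"{text!r}")
    for inst in instances:
        np_part = f"NP={inst.np!r} " if inst.np else ""
        rel_part = f"R={inst.relation!r} " if inst.relation else "(semantic type) "
        print(f"  facet={inst.facet:8s} {np_part}{rel_part}C={sorted(inst.concepts)}")
    print()

print("per-facet semantic vectors (union of instance concepts, tf·idf):")
for facet, vec in sorted(facet_vectors(all_instances, lexicon, background).items()):
    print(f"  {facet}: {vec}")
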