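# Default facet extraction configuration.
#
# Each facet lists pattern rows of the generic form
#     (noun-phrase)? relation E-noun-phrase
# where the E-noun-phrase is any noun phrase containing at least one semantic
# annotation. `np` declares the allowed leading noun-phrase form:
#   keyword — the preceding noun phrase must match `np_regex` (e.g. "input"),
#             otherwise the row does not fire (a bare copula is too generic);
#   none    — no leading noun phrase is recorded;
#   entity  — the preceding noun phrase (an annotated entity, a plain subject,
#             or the pronoun "it") is recorded when present, else left empty.
# `semantic_types` extracts facet instances directly from annotations whose
# concepts carry one of the listed types.
facets:
  input:
    semantic_types: []
    patterns:
      - np: keyword
        np_regex: "inputs?"
        relations: ["is", "are"]
      - np: none
        relations: ["given", "taking"]
      - np: entity
        relations: ["gets"]
  output:
    semantic_types: []
    patterns:
      - np: keyword
        np_regex: "outputs?"
        relations: ["is", "are"]
      - np: entity
        relations:
          ["constructs", "finds", "retrieves", "calculates", "contains",
           "produces", "extracts", "returns"]
  method:
    semantic_types: []
    patterns:
      - np: entity
        relations:
          ["maps", "executes", "performs", "implements", "applies",
           "applying", "runs", "running", "based on", "computes",
           "carries out", "processes"]
  species:
    semantic_types: ["Bacterium", "Virus", "Mammal", "Species"]
    patterns: []
  disease:
    semantic_types: ["Disease"]
    patterns: []
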