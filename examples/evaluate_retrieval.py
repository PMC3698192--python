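"""Score retrieval and facet extraction against a gold standard.

Generates a workspace with planted relevance, ranks all 100 queries, and
reports mean P@5/P@10, mean average precision and mean P/R/F; then scores
pattern-extracted facet concepts against the planted facet gold standard with
the macro-averaged best-mapping metric (each gold tag paired with the
extracted concept maximizing F).
"""

import tempfile
from pathlib import Path

from semres import (
    FixtureSpec,
    GoldStandard,
    Task,
    annotate,
    average_precision,
    build_lexicon,
    estimate_topic_model,
    extract_by_pattern,
    facet_macro_average,
    load_corpus,
    load_facet_gs,
    load_patterns,
    load_relevance,
    load_repository,
    make_workspace,
    normalize_corpus,
    precision_at_k,
    precision_recall_f,
    rank,
    to_vector,
)
from semres.synthetic import generate_corpus, generate_kr

with tempfile.TemporaryDirectory() as tmp:
    spec = FixtureSpec(seed=3)
    paths = make_workspace(spec, Path(tmp))
    gt = generate_corpus(spec, generate_kr(spec))
    repo, background = load_repository(paths["concepts"], paths["taxonomy"], paths["background"])
    lexicon = build_lexicon(repo)
    patterns = load_patterns()
    raw = load_corpus(paths["resources"])
    corpus = normalize_corpus(raw, lexicon, background, repo, patterns)
    topic_model = estimate_topic_model(corpus, n_topics=spec.n_topics, seed=spec.seed)
    relevance = load_relevance(paths["relevance"])

    p5s, p10s, aps, fs = [], [], [], []
    for q in gt.queries:
        vec = to_vector(annotate(q["description"], lexicon, background), lexicon, background)
        ranked = [r.resource_id for r in rank(Task(q["id"], q["description"], vector=vec),
                                              corpus, topic_model)]
        rel = relevance[q["id"]]
        p5s.append(precision_at_k(ranked, rel, 5))
        p10s.append(precision_at_k(ranked, rel, 10))
        aps.append(average_precision(ranked, rel))
        fs.append(precision_recall_f(ranked, rel)[2])
    n = len(gt.queries)
    print(f"retrieval over {n} queries, {len(corpus)} resources:")
    print(f"  mean P@5  = {sum(p5s)/n:.3f}")
    print(f"  mean P@10 = {sum(p10s)/n:.3f}")
    print(f"  MAP       = {sum(aps)/n:.3f}")
    print(f"  mean F    = {sum(fs)/n:.3f}  (whole ranked list is 'retrieved')")

    # facet extraction vs planted gold standard: treat planted concepts as
    # gold tags and extracted concepts as system concepts
    gs = load_facet_gs(paths["facet_gs"])
    extracted = GoldStandard()
    for rec in raw:
        anns = annotate(rec["description"], lexicon, background)
        for inst in extract_by_pattern(rec["description"], anns, patterns):
            for cid in inst.concepts:
                extracted.facet_concepts.setdefault(inst.facet, {}).setdefault(cid, set()).add(rec["id"])
    print("\nfacet extraction (macro-average over best tag->concept mappings):")
    for facet in sorted(gs.facet_concepts):
        merged = GoldStandard(
            facet_tags={facet: gs.facet_concepts[facet]},
            facet_concepts={facet: extracted.facet_concepts.get(facet, {})},
        )
        p, r = facet_macro_average(merged, facet)
        print(f"  {facet:8s} P={p:.3f} R={r:.3f}")
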