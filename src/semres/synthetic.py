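"""Synthetic fixture generator: knowledge repository, background table,
resource corpus, requirements model and gold standards with known ground truth.

The generator emulates the statistical structure the retrieval model assumes:

* a concept repository whose taxonomy is a rooted tree of configurable depth
  and branching, each concept carrying one or two-word lexical variants drawn
  from a synthetic vocabulary with Zipf-distributed background counts;
* resources whose free-text descriptions embed *exact* variant strings of
  concepts sampled from a planted topic mixture, surrounded by filler words;
* facet sentences instantiating the shipped extraction patterns
  ("<name> gets <variant>", "<name> returns <variant>",
  "<name> implements <variant>"), recorded in a facet gold standard;
* a relevance gold standard marking, for each query, the resources sharing the
  query's planted topic.

Variant words are disjoint across concepts by default, and the filler
vocabulary is disjoint from all variant words, so planted-concept recall and
precision are provable properties rather than empirical luck; an overlap knob
re-introduces ambiguity for stress tests. Everything is a pure function of the
spec's seed: the same spec writes byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

_CONSONANTS = "bcdfglmnprstvz"
_VOWELS = "aeiou"

_SEMANTIC_TYPES = ("Data", "Protein", "Method", "Disease", "Mammal", "Bacterium")
_SOURCES = ("UMLS", "Wiki", "myGR", "EDAM")

# facet sentence templates use relations present in the shipped pattern table
_FACET_TEMPLATES = {
    "input": "{name} gets {mention}.",
    "output": "{name} returns {mention}.",
    "method": "{name} implements {mention}.",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic workspace; same seed means identical bytes."""

    seed: int = 0
    n_concepts: int = 40
    taxonomy_depth: int = 4
    branching: int = 3
    variants_per_concept: int = 2
    vocab_size: int = 400
    n_resources: int = 50
    n_topics: int = 2
    n_queries: int = 100
    concepts_per_resource: int = 8
    concepts_per_query: int = 3
    #: probability that a resource description carries each facet sentence
    facet_template_rate: float = 1.0
    #: filler words inserted between consecutive concept mentions
    filler_run: int = 3
    #: fraction of variant *word slots* reused across concepts (ambiguity knob)
    variant_overlap: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_concepts", "taxonomy_depth", "branching", "variants_per_concept",
                     "vocab_size", "n_resources", "n_topics", "n_queries",
                     "concepts_per_resource", "concepts_per_query"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("facet_template_rate", "variant_overlap"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


def _word(rng: np.random.Generator, syllables: int) -> str:
    return "".join(
        _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]
        for _ in range(syllables)
    )


def _make_vocab(rng: np.random.Generator, n: int, syllables: int) -> list[str]:
    words: list[str] = []
    seen: set[str] = set()
    while len(words) < n:
        w = _word(rng, syllables)
        if w not in seen:
            seen.add(w)
            words.append(w)
    return words


@dataclass(frozen=True)
class SyntheticKR:
    """In-memory view of a generated knowledge repository."""

    concept_ids: tuple[str, ...]
    variants: dict[str, tuple[str, ...]]
    semantic_types: dict[str, str]
    parents: dict[str, str | None]
    background_counts: dict[str, int]
    filler_words: tuple[str, ...]


def _tree_ids(spec: FixtureSpec) -> tuple[list[str], dict[str, str | None]]:
    """Concept ids in BFS order over a rooted tree, capped at n_concepts and at
    the full tree of the given depth/branching."""
    full = sum(spec.branching**level for level in range(spec.taxonomy_depth + 1))
    n = min(spec.n_concepts, full)
    prefixes = {"UMLS": "UMLS:C", "Wiki": "Wiki:W", "myGR": "myGR:D", "EDAM": "EDAM_"}
    ids = [f"{prefixes[_SOURCES[i % len(_SOURCES)]]}{1000 + i}" for i in range(n)]
    parents: dict[str, str | None] = {ids[0]: None}
    for i in range(1, n):
        parents[ids[i]] = ids[(i - 1) // spec.branching]
    return ids, parents


def generate_kr(spec: FixtureSpec) -> SyntheticKR:
    """Generate the repository content (concepts, taxonomy, background counts)."""
    rng = np.random.default_rng(spec.seed)
    ids, parents = _tree_ids(spec)
    n = len(ids)

    # variant vocabulary: 4-syllable words, disjoint from 2-syllable filler
    needed = n * spec.variants_per_concept * 2
    variant_vocab = _make_vocab(rng, max(needed, 4), syllables=4)
    filler_vocab = tuple(_make_vocab(rng, max(spec.vocab_size - needed, 20), syllables=2))

    variants: dict[str, tuple[str, ...]] = {}
    cursor = 0
    for cid in ids:
        n_var = 1 + int(rng.integers(spec.variants_per_concept))
        vs = []
        for _ in range(n_var):
            n_words = 1 + int(rng.integers(2))  # 1- or 2-word variants
            words = []
            for _ in range(n_words):
                if spec.variant_overlap > 0 and cursor > 0 and rng.random() < spec.variant_overlap:
                    words.append(variant_vocab[int(rng.integers(cursor))])
                else:
                    words.append(variant_vocab[cursor])
                    cursor += 1
            vs.append(" ".join(words))
        variants[cid] = tuple(dict.fromkeys(vs))

    semantic_types = {cid: _SEMANTIC_TYPES[int(rng.integers(len(_SEMANTIC_TYPES)))] for cid in ids}

    # Zipf-like background counts over every word the generator can emit
    all_words = sorted({w for vs in variants.values() for v in vs for w in v.split()} | set(filler_vocab))
    order = rng.permutation(len(all_words))
    counts = {}
    for rank_idx, widx in enumerate(order, start=1):
        counts[all_words[widx]] = max(1, int(100_000 / rank_idx))

    return SyntheticKR(
        concept_ids=tuple(ids),
        variants=variants,
        semantic_types=semantic_types,
        parents=parents,
        background_counts=counts,
        filler_words=filler_vocab,
    )


def write_kr(kr: SyntheticKR, outdir: str | Path) -> dict[str, Path]:
    """Write concepts.tsv, taxonomy.tsv and background.tsv; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    concepts_path = outdir / "concepts.tsv"
    taxonomy_path = outdir / "taxonomy.tsv"
    background_path = outdir / "background.tsv"
    with open(concepts_path, "w", encoding="utf-8", newline="\n") as fh:
        for cid in kr.concept_ids:
            source = cid.split(":")[0] if ":" in cid else cid.split("_")[0]
            for variant in kr.variants[cid]:
                fh.write(f"{cid}\t{variant}\t{kr.semantic_types[cid]}\t{source}\n")
    with open(taxonomy_path, "w", encoding="utf-8", newline="\n") as fh:
        for cid in kr.concept_ids:
            parent = kr.parents[cid]
            if parent is not None:
                fh.write(f"{cid}\t{parent}\n")
    with open(background_path, "w", encoding="utf-8", newline="\n") as fh:
        for word in sorted(kr.background_counts):
            fh.write(f"{word}\t{kr.background_counts[word]}\n")
    return {"concepts": concepts_path, "taxonomy": taxonomy_path, "background": background_path}


def make_kr(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the knowledge repository file set."""
    return write_kr(generate_kr(spec), outdir)


@dataclass(frozen=True)
class SyntheticCorpus:
    """In-memory view of the generated corpus with its ground truth."""

    resources: tuple[dict, ...]           # JSONL records
    resource_topics: dict[str, int]       # planted topic per resource
    planted_concepts: dict[str, frozenset[str]]  # per resource, all embedded concepts
    facet_gs: tuple[tuple[str, str, str], ...]   # (facet, concept, resource)
    queries: tuple[dict, ...]             # {id, description, topic}
    query_concepts: dict[str, frozenset[str]]
    relevance: dict[str, frozenset[str]]  # query -> relevant resources


def _topic_blocks(kr: SyntheticKR, n_topics: int) -> list[list[str]]:
    ids = list(kr.concept_ids)
    return [ids[k::n_topics] for k in range(n_topics)]


def _mention(rng: np.random.Generator, kr: SyntheticKR, cid: str) -> str:
    vs = kr.variants[cid]
    return vs[int(rng.integers(len(vs)))]


def _filler(rng: np.random.Generator, kr: SyntheticKR, n: int) -> list[str]:
    return [kr.filler_words[int(rng.integers(len(kr.filler_words)))] for _ in range(n)]


def generate_corpus(spec: FixtureSpec, kr: SyntheticKR) -> SyntheticCorpus:
    """Generate resources, queries and gold standards from planted topics."""
    rng = np.random.default_rng(spec.seed + 1)
    blocks = _topic_blocks(kr, spec.n_topics)
    if any(not b for b in blocks):
        raise ValueError(
            f"n_topics ({spec.n_topics}) exceeds the number of generated concepts ({len(kr.concept_ids)})"
        )

    resources = []
    resource_topics: dict[str, int] = {}
    planted: dict[str, frozenset[str]] = {}
    facet_gs: list[tuple[str, str, str]] = []
    for j in range(spec.n_resources):
        rid = f"res{j:04d}"
        name = f"svc{j:04d}"
        topic = j % spec.n_topics
        block = blocks[topic]
        picked = [block[int(i)] for i in rng.choice(len(block), size=min(spec.concepts_per_resource, len(block)), replace=False)]
        sentences = []
        embedded: set[str] = set(picked)
        for facet, template in _FACET_TEMPLATES.items():
            if rng.random() < spec.facet_template_rate:
                cid = picked[int(rng.integers(len(picked)))]
                sentences.append(template.format(name=name, mention=_mention(rng, kr, cid)))
                facet_gs.append((facet, cid, rid))
        body: list[str] = []
        for cid in picked:
            body.extend(_filler(rng, kr, int(rng.integers(1, spec.filler_run + 1))))
            body.append(_mention(rng, kr, cid))
        body.extend(_filler(rng, kr, int(rng.integers(1, spec.filler_run + 1))))
        sentences.append(" ".join(body) + ".")
        resources.append({"id": rid, "name": name, "description": " ".join(sentences), "tags": []})
        resource_topics[rid] = topic
        planted[rid] = frozenset(embedded)

    queries = []
    query_concepts: dict[str, frozenset[str]] = {}
    relevance: dict[str, frozenset[str]] = {}
    by_topic: dict[int, frozenset[str]] = {
        k: frozenset(r for r, t in resource_topics.items() if t == k) for k in range(spec.n_topics)
    }
    for qi in range(spec.n_queries):
        qid = f"q{qi:04d}"
        topic = qi % spec.n_topics
        block = blocks[topic]
        picked = [block[int(i)] for i in rng.choice(len(block), size=min(spec.concepts_per_query, len(block)), replace=False)]
        words: list[str] = []
        for cid in picked:
            words.append(_mention(rng, kr, cid))
            words.extend(_filler(rng, kr, 1))
        queries.append({"id": qid, "description": " ".join(words), "topic": topic})
        query_concepts[qid] = frozenset(picked)
        relevance[qid] = by_topic[topic]

    return SyntheticCorpus(
        resources=tuple(resources),
        resource_topics=resource_topics,
        planted_concepts=planted,
        facet_gs=tuple(facet_gs),
        queries=tuple(queries),
        query_concepts=query_concepts,
        relevance=relevance,
    )


def write_corpus(corpus: SyntheticCorpus, outdir: str | Path) -> dict[str, Path]:
    """Write resources.jsonl, queries.jsonl, relevance.tsv and facet_gs.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "resources": outdir / "resources.jsonl",
        "queries": outdir / "queries.jsonl",
        "relevance": outdir / "relevance.tsv",
        "facet_gs": outdir / "facet_gs.tsv",
    }
    with open(paths["resources"], "w", encoding="utf-8", newline="\n") as fh:
        for rec in corpus.resources:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    with open(paths["queries"], "w", encoding="utf-8", newline="\n") as fh:
        for rec in corpus.queries:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    with open(paths["relevance"], "w", encoding="utf-8", newline="\n") as fh:
        for qid in sorted(corpus.relevance):
            for rid in sorted(corpus.relevance[qid]):
                fh.write(f"{qid}\t{rid}\n")
    with open(paths["facet_gs"], "w", encoding="utf-8", newline="\n") as fh:
        for facet, cid, rid in corpus.facet_gs:
            fh.write(f"{facet}\tconcept\t{cid}\t{rid}\n")
    return paths


def make_corpus(spec: FixtureSpec, kr: SyntheticKR, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the corpus file set."""
    return write_corpus(generate_corpus(spec, kr), outdir)


def generate_requirements(spec: FixtureSpec, kr: SyntheticKR) -> dict:
    """A small chain-dependency requirements model over planted concepts.

    Five tasks; the middle task omits its input so I/O propagation has work to
    do, and the last task sets an explicit output facet value.
    """
    rng = np.random.default_rng(spec.seed + 2)
    ids = list(kr.concept_ids)
    pick = lambda: ids[int(rng.integers(len(ids)))]  # noqa: E731
    mention = lambda cid: _mention(rng, kr, cid)  # noqa: E731
    c = [pick() for _ in range(6)]
    tasks = [
        {"id": "t1", "description": f"search {mention(c[0])} given {mention(c[1])}",
         "facets": {}, "depends_on": []},
        {"id": "t2", "description": f"analyze {mention(c[2])}",
         "facets": {"output": [c[2]]}, "depends_on": ["t1"]},
        {"id": "t3", "description": f"process {mention(c[3])} data",
         "facets": {}, "depends_on": ["t2"]},
        {"id": "t4", "description": f"compare {mention(c[4])} results",
         "facets": {"input": [c[4]]}, "depends_on": ["t3"]},
        {"id": "t5", "description": f"report on {mention(c[5])}",
         "facets": {"output": [c[5]]}, "depends_on": ["t4"]},
    ]
    return {"goal": "analyze planted concepts across synthetic resources", "tasks": tasks}


def make_workspace(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Write a complete workspace: repository, corpus, requirements model."""
    outdir = Path(outdir)
    kr = generate_kr(spec)
    paths = write_kr(kr, outdir)
    paths |= write_corpus(generate_corpus(spec, kr), outdir)
    req_path = outdir / "requirements.json"
    req_path.write_text(json.dumps(generate_requirements(spec, kr), indent=1, sort_keys=True), encoding="utf-8")
    paths["requirements"] = req_path
    return paths
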