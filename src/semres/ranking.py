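"""Topic-based probabilistic ranking of resources against a faceted query.

Each resource is represented by the tf·idf semantic vector of its description
plus per-facet vectors. A latent-topic model ties query concepts to resources:
for every facet f (and for the whole description, treated as the task level)
two tables are estimated over a fixed topic set t_1..t_n:

* ``P(c ∈ f | t_k)`` — concept given topic,
* ``P(t_k | ws_j, f)`` — topic given resource.

The query likelihood of a resource for a facet is then

    P(q | ws_j, f) = prod_{c_i in q} sum_k P(c_i ∈ f | t_k) · P(t_k | ws_j, f)

accumulated in log space, and facet likelihoods combine linearly with the
task-level likelihood under weights α + Σ_f β_f = 1.

Topic tables come from a seeded non-negative matrix factorization of the
concept×resource tf·idf matrix, column-normalized (with epsilon smoothing so
no likelihood is exactly zero) into the two probability tables. The estimator
sits behind :func:`estimate_topic_model` so alternatives can be swapped in.
A cosine similarity over the raw vectors is provided as a semantics-only
baseline that ignores topical context.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, EstimationError
from .requirements import Task
from .vectors import SemanticVector, cosine

#: Facet key under which the whole-description (task-level) tables live.
TASK_LEVEL = "__task__"

#: Smoothing mass added to every table cell before renormalization.
SMOOTHING_EPS = 1e-6

#: Probability used for query concepts absent from a facet's concept index.
#: Constant across topics and resources, so unseen concepts never reorder.
UNSEEN_CONCEPT_P = 1e-6

INDEX_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ResourceRecord:
    """A corpus entry: free-text description plus its derived vectors."""

    id: str
    name: str
    description: str
    vector: SemanticVector = field(default_factory=SemanticVector)
    facet_vectors: dict[str, SemanticVector] = field(default_factory=dict)
    tags: tuple[str, ...] = ()


@dataclass(frozen=True)
class FacetTables:
    """Topic tables for one facet: concept index + the two probability tables."""

    concept_ids: tuple[str, ...]
    resource_ids: tuple[str, ...]
    p_concept_given_topic: np.ndarray  # concepts × topics, columns sum to 1
    p_topic_given_resource: np.ndarray  # topics × resources, columns sum to 1


@dataclass(frozen=True)
class TopicModel:
    """Per-facet probability tables over a shared set of latent topics."""

    n_topics: int
    facets: dict[str, FacetTables]

    def table(self, facet: str) -> FacetTables:
        try:
            return self.facets[facet]
        except KeyError:
            raise ConfigurationError(f"no topic tables for facet {facet!r}") from None


@dataclass(frozen=True)
class RankedResource:
    """One ranking entry: likelihoods, combined score and 1-based rank."""

    resource_id: str
    task_likelihood: float
    facet_likelihoods: dict[str, float]
    score: float
    rank: int


def load_corpus(path: str | Path) -> list[dict]:
    """Read a resource corpus JSONL file: {id, name, description, tags[]}."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(json.loads(line))
    return records


def normalize_corpus(raw_records, lexicon, background, repository, patterns=None, threshold=None) -> list[ResourceRecord]:
    """Annotate every corpus record and build its semantic + facet vectors."""
    from .annotate import DEFAULT_THRESHOLD, annotate, to_vector
    from .facets import extract_by_pattern, extract_by_semantic_type, facet_vectors, load_patterns

    if patterns is None:
        patterns = load_patterns()
    if threshold is None:
        threshold = DEFAULT_THRESHOLD
    out = []
    for rec in raw_records:
        anns = annotate(rec["description"], lexicon, background, threshold)
        vec = to_vector(anns, lexicon, background)
        instances = extract_by_pattern(rec["description"], anns, patterns)
        instances += extract_by_semantic_type(anns, repository, patterns)
        fvecs = facet_vectors(instances, lexicon, background)
        out.append(
            ResourceRecord(
                id=str(rec["id"]),
                name=str(rec.get("name", rec["id"])),
                description=rec["description"],
                vector=vec,
                facet_vectors=fvecs,
                tags=tuple(rec.get("tags") or ()),
            )
        )
    return out


def _facet_matrix(corpus, facet: str) -> tuple[tuple[str, ...], np.ndarray]:
    """Concept×resource tf·idf matrix for a facet, backing off to the
    whole-description vector for resources without that facet."""
    vectors = []
    for r in corpus:
        if facet == TASK_LEVEL:
            vectors.append(r.vector)
        else:
            vectors.append(r.facet_vectors.get(facet) or r.vector)
    concept_ids = tuple(sorted(set().union(*(v.concepts for v in vectors))))
    pos = {c: i for i, c in enumerate(concept_ids)}
    X = np.zeros((len(concept_ids), len(corpus)))
    for j, v in enumerate(vectors):
        for c, w in v.weights.items():
            X[pos[c], j] = w
    return concept_ids, X


def estimate_topic_model(corpus, n_topics: int, seed: int, facets=None) -> TopicModel:
    """Estimate topic tables for the task level and every requested facet.

    Seeded NMF of each facet's concept×resource matrix: the concept factor is
    column-normalized into P(c|t), the resource factor into P(t|ws). Both
    tables get ``SMOOTHING_EPS`` added before normalization so every cell is
    strictly positive. Deterministic for a fixed seed.
    """
    from sklearn.decomposition import NMF

    if n_topics < 1:
        raise ConfigurationError(f"n_topics must be >= 1, got {n_topics}")
    corpus = sorted(corpus, key=lambda r: r.id)
    if not corpus or all(not r.vector for r in corpus):
        raise EstimationError("cannot estimate topics: every resource vector is empty")
    if facets is None:
        facets = sorted(set().union(*(set(r.facet_vectors) for r in corpus)))
    tables: dict[str, FacetTables] = {}
    for facet in [TASK_LEVEL, *facets]:
        concept_ids, X = _facet_matrix(corpus, facet)
        if X.size == 0 or not X.any():
            continue
        k = min(n_topics, min(X.shape))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # NMF convergence chatter on tiny matrices
            model = NMF(n_components=k, init="random", random_state=seed, max_iter=500)
            W = model.fit_transform(X)  # concepts × k
        H = model.components_  # k × resources
        if k < n_topics:  # pad with empty topics; smoothing keeps columns valid
            W = np.hstack([W, np.zeros((W.shape[0], n_topics - k))])
            H = np.vstack([H, np.zeros((n_topics - k, H.shape[1]))])
        W = W + SMOOTHING_EPS
        H = H + SMOOTHING_EPS
        tables[facet] = FacetTables(
            concept_ids=concept_ids,
            resource_ids=tuple(r.id for r in corpus),
            p_concept_given_topic=W / W.sum(axis=0, keepdims=True),
            p_topic_given_resource=H / H.sum(axis=0, keepdims=True),
        )
    return TopicModel(n_topics=n_topics, facets=tables)


def log_facet_likelihood(query_vector: SemanticVector, resource_id: str, facet: str, topics: TopicModel) -> float:
    """log P(q | ws, f): sum over distinct query concepts of the log of the
    topic-marginalized concept probability."""
    if not query_vector:
        warnings.warn("empty query vector; likelihood defined as 1")
        return 0.0
    t = topics.table(facet)
    try:
        j = t.resource_ids.index(resource_id)
    except ValueError:
        raise ConfigurationError(f"resource {resource_id!r} not in topic tables for {facet!r}") from None
    pos = {c: i for i, c in enumerate(t.concept_ids)}
    p_t = t.p_topic_given_resource[:, j]
    total = 0.0
    for c in sorted(query_vector.concepts):
        i = pos.get(c)
        p = UNSEEN_CONCEPT_P if i is None else float(t.p_concept_given_topic[i] @ p_t)
        total += math.log(p)
    return total


def facet_likelihood(query_vector: SemanticVector, resource: ResourceRecord | str, facet: str, topics: TopicModel) -> float:
    """P(q | ws, f), computed in log space and exponentiated."""
    rid = resource.id if isinstance(resource, ResourceRecord) else resource
    return math.exp(log_facet_likelihood(query_vector, rid, facet, topics))


def combined_score(task_likelihood: float, facet_likelihoods: dict[str, float], alpha: float, betas: dict[str, float]) -> float:
    """α·P(q|ws) + Σ_f β_f·P(q|ws,f), under α + Σβ_f = 1 (within 1e-9)."""
    if alpha < 0 or any(b < 0 for b in betas.values()):
        raise ConfigurationError("alpha and betas must be non-negative")
    total = alpha + sum(betas.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"alpha + sum(betas) must be 1, got {total}")
    missing = set(betas) - set(facet_likelihoods)
    if missing:
        raise ConfigurationError(f"betas reference facets without likelihoods: {sorted(missing)}")
    return alpha * task_likelihood + sum(b * facet_likelihoods[f] for f, b in betas.items())


def default_weights(query_facets) -> tuple[float, dict[str, float]]:
    """α = 0.5 with the remaining mass split equally across the query's
    facets; α = 1 when the query has none."""
    facets = sorted(query_facets)
    if not facets:
        return 1.0, {}
    beta = 0.5 / len(facets)
    return 0.5, {f: beta for f in facets}


def rank(
    query: Task,
    corpus,
    topics: TopicModel,
    alpha: float | None = None,
    betas: dict[str, float] | None = None,
    top_k: int | None = None,
) -> list[RankedResource]:
    """Rank a corpus against a normalized query task.

    Resources sort by combined score descending, ties broken by resource id;
    ranks are 1-based. Only facets present both in the query and in the topic
    model participate. Empty corpus yields an empty list.
    """
    if query.vector is None:
        raise ConfigurationError(f"query task {query.id!r} is not normalized")
    usable_facets = [f for f in sorted(query.facet_vectors) if query.facet_vectors[f] and f in topics.facets]
    if alpha is None and betas is None:
        alpha, betas = default_weights(usable_facets)
    elif betas is None:
        betas = {}
    results = []
    for resource in corpus:
        rid = resource.id if isinstance(resource, ResourceRecord) else resource
        task_l = facet_likelihood(query.vector, rid, TASK_LEVEL, topics)
        facet_ls = {
            f: facet_likelihood(query.facet_vectors[f], rid, f, topics) for f in usable_facets
        }
        score = combined_score(task_l, facet_ls, alpha, betas)
        results.append((rid, task_l, facet_ls, score))
    results.sort(key=lambda r: (-r[3], r[0]))
    if top_k is not None:
        results = results[:top_k]
    return [
        RankedResource(resource_id=rid, task_likelihood=tl, facet_likelihoods=fl, score=s, rank=i + 1)
        for i, (rid, tl, fl, s) in enumerate(results)
    ]


def cosine_baseline(query_vector: SemanticVector, resource_vector: SemanticVector) -> float:
    """Plain cosine similarity between tf·idf vectors (no topics)."""
    return cosine(query_vector, resource_vector)


def save_index(path: str | Path, corpus, topics: TopicModel | None = None) -> None:
    """Persist resource vectors and topic tables as versioned JSON."""
    payload = {
        "format_version": INDEX_FORMAT_VERSION,
        "resources": [
            {
                "id": r.id,
                "name": r.name,
                "description": r.description,
                "vector": r.vector.to_dict(),
                "facet_vectors": {f: v.to_dict() for f, v in sorted(r.facet_vectors.items())},
                "tags": list(r.tags),
            }
            for r in corpus
        ],
    }
    if topics is not None:
        payload["topic_model"] = {
            "n_topics": topics.n_topics,
            "facets": {
                f: {
                    "concept_ids": list(t.concept_ids),
                    "resource_ids": list(t.resource_ids),
                    "p_concept_given_topic": t.p_concept_given_topic.tolist(),
                    "p_topic_given_resource": t.p_topic_given_resource.tolist(),
                }
                for f, t in sorted(topics.facets.items())
            },
        }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")


def load_index(path: str | Path) -> tuple[list[ResourceRecord], TopicModel | None]:
    """Load an index written by :func:`save_index`."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("format_version") != INDEX_FORMAT_VERSION:
        raise ConfigurationError(f"unsupported index format: {payload.get('format_version')}")
    corpus = [
        ResourceRecord(
            id=r["id"],
            name=r["name"],
            description=r["description"],
            vector=SemanticVector(r["vector"]),
            facet_vectors={f: SemanticVector(v) for f, v in r["facet_vectors"].items()},
            tags=tuple(r.get("tags") or ()),
        )
        for r in payload["resources"]
    ]
    topics = None
    if "topic_model" in payload:
        tm = payload["topic_model"]
        topics = TopicModel(
            n_topics=tm["n_topics"],
            facets={
                f: FacetTables(
                    concept_ids=tuple(t["concept_ids"]),
                    resource_ids=tuple(t["resource_ids"]),
                    p_concept_given_topic=np.asarray(t["p_concept_given_topic"]),
                    p_topic_given_resource=np.asarray(t["p_topic_given_resource"]),
                )
                for f, t in tm["facets"].items()
            },
        )
    return corpus, topics
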