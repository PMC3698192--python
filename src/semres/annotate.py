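"""Unsupervised semantic annotation of free text against a concept lexicon.

The annotator links noun-phrase-like chunks of a description to repository
concepts with an information-coverage score::

    sim(C, T) = max_{S in lex(C)} (info(S ∩ T) - info(S - T)) / info(S)

where S and T are bags of words, S ∩ T keeps shared tokens (min multiplicity)
and S - T the variant tokens the chunk misses. Because the bag of S partitions
into S ∩ T and S - T, sim is always in [-1, 1]: +1 when every variant token
occurs in the chunk, -1 when none does. Annotations with
``sim >= threshold`` (default 0.7) are kept; per chunk, only top-scoring
concepts survive, ties resolved by greater token coverage of the chunk, then
by concept id.

Concept weights for retrieval use ``idf(C) = max_{S in lex(C)} info(S)`` and
``tf(C)`` = number of annotations of C in the description.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

from .errors import UndefinedScoreError
from .repository import BackgroundModel, Concept, Lexicon, info
from .tokens import DEFAULT_POLICY, STOPWORDS, TokenPolicy, token_spans
from .vectors import SemanticVector

DEFAULT_THRESHOLD = 0.7
#: Longest sub-window (in tokens) emitted inside a maximal chunk run.
MAX_WINDOW = 6

_SENTENCE_BREAK = frozenset(".;!?")


@dataclass(frozen=True)
class Chunk:
    """A candidate entity mention: a character span plus its token bag."""

    start: int
    end: int
    tokens: tuple[str, ...]
    is_noun_phrase: bool = True

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise ValueError("chunk span must be non-empty")
        if not self.tokens:
            raise ValueError("chunk token bag must be non-empty")

    @property
    def bag(self) -> Counter:
        return Counter(self.tokens)


@dataclass(frozen=True)
class SemanticAnnotation:
    """A chunk linked to one concept via a matched lexical variant."""

    start: int
    end: int
    concept_id: str
    variant: str
    score: float


def _maximal_runs(text: str, policy: TokenPolicy) -> list[list[tuple[int, int, str]]]:
    """Runs of non-stopword tokens delimited by stopwords / sentence breaks."""
    runs: list[list[tuple[int, int, str]]] = []
    current: list[tuple[int, int, str]] = []
    prev_end = 0
    for start, end, raw in token_spans(text):
        broke = any(ch in _SENTENCE_BREAK for ch in text[prev_end:start])
        tok = policy.normalize_token(raw)
        if broke or tok in STOPWORDS:
            if current:
                runs.append(current)
                current = []
            if tok not in STOPWORDS:
                current.append((start, end, tok))
        else:
            current.append((start, end, tok))
        prev_end = end
    if current:
        runs.append(current)
    return runs


def chunk_text(text: str, policy: TokenPolicy = DEFAULT_POLICY, max_window: int = MAX_WINDOW) -> list[Chunk]:
    """Noun-phrase candidate chunks of ``text``.

    Rule-based: maximal runs of non-stopword tokens between stopword or
    sentence-punctuation boundaries, plus every contiguous sub-window of a run
    up to ``max_window`` tokens, so that an embedded entity mention is always
    one of the candidates. Deterministic; ordered by (start, end). Empty or
    all-stopword text yields an empty list.
    """
    chunks: dict[tuple[int, int], Chunk] = {}
    for run in _maximal_runs(text, policy):
        n = len(run)
        spans = [(0, n)] + [
            (i, j) for i in range(n) for j in range(i + 1, min(i + max_window, n) + 1)
        ]
        for i, j in spans:
            start, end = run[i][0], run[j - 1][1]
            if (start, end) not in chunks:
                chunks[(start, end)] = Chunk(start=start, end=end, tokens=tuple(t for _, _, t in run[i:j]))
    return [chunks[key] for key in sorted(chunks)]


def _bag_partition(variant_bag: Counter, chunk_bag: Counter) -> tuple[Counter, Counter]:
    inter = Counter({w: min(n, chunk_bag[w]) for w, n in variant_bag.items() if w in chunk_bag})
    inter = +inter
    diff = variant_bag - chunk_bag
    return inter, diff


def best_variant(
    variants, chunk_bag: Counter, background: BackgroundModel, policy: TokenPolicy = DEFAULT_POLICY
) -> tuple[float, str, int]:
    """(score, variant, coverage) maximizing sim, then chunk-token coverage.

    ``coverage`` is the number of chunk tokens (with multiplicity) the winning
    variant accounts for. Variants with zero information (empty after
    normalization) are skipped with a warning; if all are skipped the score is
    undefined.
    """
    best: tuple[float, int, str] | None = None
    for variant in sorted(variants):
        s_bag = policy.bag(variant)
        denom = info(s_bag, background)
        if denom == 0.0:
            warnings.warn(f"variant {variant!r} has zero information; skipped", stacklevel=2)
            continue
        inter, diff = _bag_partition(s_bag, chunk_bag)
        score = (info(inter, background) - info(diff, background)) / denom
        coverage = sum(inter.values())
        if best is None or (score, coverage) > (best[0], best[1]):
            best = (score, coverage, variant)
    if best is None:
        raise UndefinedScoreError("all lexical variants have zero information")
    return best[0], best[2], best[1]


def sim(concept: Concept, chunk: Chunk | Counter, background: BackgroundModel, policy: TokenPolicy = DEFAULT_POLICY) -> float:
    """Information coverage of the chunk by the concept's best lexical variant."""
    bag = chunk.bag if isinstance(chunk, Chunk) else chunk
    score, _, _ = best_variant(concept.lex, bag, background, policy)
    return score


def annotate(
    description: str,
    lexicon: Lexicon,
    background: BackgroundModel,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[SemanticAnnotation]:
    """Annotate a description against the lexicon.

    Per chunk the top-sim concepts at or above ``threshold`` are selected;
    score ties are broken in favor of variants covering more chunk tokens, and
    concepts still tied after that are all returned (downstream refinement may
    prune). Output is ordered by (start, end, concept id) and is a pure
    function of its inputs.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    annotations: list[SemanticAnnotation] = []
    for chunk in chunk_text(description, lexicon.policy):
        bag = chunk.bag
        scored: list[tuple[float, int, str, str]] = []
        for cid in lexicon.candidates(bag):
            try:
                score, variant, coverage = best_variant(
                    lexicon.variants_of(cid), bag, background, lexicon.policy
                )
            except UndefinedScoreError:
                continue
            if score >= threshold:
                scored.append((score, coverage, cid, variant))
        if not scored:
            continue
        top_score = max(s for s, _, _, _ in scored)
        top_cov = max(c for s, c, _, _ in scored if s == top_score)
        for score, coverage, cid, variant in sorted(scored, key=lambda x: x[2]):
            if score == top_score and coverage == top_cov:
                annotations.append(
                    SemanticAnnotation(chunk.start, chunk.end, cid, variant, score)
                )
    annotations = _minimal_spans(annotations)
    annotations.sort(key=lambda a: (a.start, a.end, a.concept_id))
    return annotations


def _minimal_spans(annotations: list[SemanticAnnotation]) -> list[SemanticAnnotation]:
    """Keep, per (concept, variant, score), only annotations whose span
    contains no smaller annotation of the same group — overlapping windows
    around one mention collapse to the mention itself, so tf counts mentions.
    Grouping includes the score so that raising the threshold can only remove
    whole groups, never promote a previously suppressed wider span."""
    by_key: dict[tuple[str, str, float], list[SemanticAnnotation]] = {}
    for a in annotations:
        by_key.setdefault((a.concept_id, a.variant, a.score), []).append(a)
    kept: list[SemanticAnnotation] = []
    for group in by_key.values():
        for a in group:
            contains_other = any(
                (a.start <= b.start and b.end <= a.end)
                and (b.start, b.end) != (a.start, a.end)
                for b in group
            )
            if not contains_other:
                kept.append(a)
    return kept


def idf(concept_or_variants, background: BackgroundModel, policy: TokenPolicy = DEFAULT_POLICY) -> float:
    """Inverse document frequency of a concept: max info over its variants."""
    variants = concept_or_variants.lex if isinstance(concept_or_variants, Concept) else concept_or_variants
    infos = [info(policy.bag(v), background) for v in variants]
    infos = [x for x in infos if x > 0.0]
    if not infos:
        raise UndefinedScoreError("all lexical variants have zero information")
    return max(infos)


def to_vector(
    annotations: list[SemanticAnnotation],
    lexicon: Lexicon,
    background: BackgroundModel,
) -> SemanticVector:
    """tf·idf semantic vector of one description's annotation set."""
    tf = Counter(a.concept_id for a in annotations)
    return SemanticVector(
        {cid: n * idf(lexicon.variants_of(cid), background, lexicon.policy) for cid, n in tf.items()}
    )
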