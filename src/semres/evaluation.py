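"""IR metrics and facet-extraction gold-standard metrics.

Retrieval quality is measured with set precision/recall/F over a relevance
gold standard, precision at a cutoff k, and (for ranked lists) average
precision. Facet extraction is scored against a gold standard of per-facet
*tags*: for a tag t and an extracted concept c, precision and recall compare
the resource sets annotated with each; the per-facet summary macro-averages
over tags, pairing each tag with the concept that maximizes F.
"""

from __future__ import annotations

import csv
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from .errors import UnknownConceptError


@dataclass
class GoldStandard:
    """Relevance and facet assignments used to score the system."""

    #: query id -> set of relevant resource ids
    relevant: dict[str, set[str]] = field(default_factory=dict)
    #: facet -> tag -> resource ids carrying the tag
    facet_tags: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    #: facet -> concept -> resource ids annotated with the concept
    facet_concepts: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def tags(self, facet: str) -> set[str]:
        return set(self.facet_tags.get(facet, ()))

    def concepts(self, facet: str) -> set[str]:
        return set(self.facet_concepts.get(facet, ()))


def load_relevance(path: str | Path) -> dict[str, set[str]]:
    """Query-relevance TSV: ``query_id <TAB> resource_id`` per row."""
    rel: dict[str, set[str]] = defaultdict(set)
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if len(row) >= 2 and row[0].strip():
                rel[row[0].strip()].add(row[1].strip())
    return dict(rel)


def load_facet_gs(path: str | Path) -> GoldStandard:
    """Facet GS TSV: ``facet <TAB> tag|concept <TAB> label <TAB> resource_id``."""
    gs = GoldStandard()
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if len(row) < 4 or not row[0].strip():
                continue
            facet, kind, label, rid = (c.strip() for c in row[:4])
            target = gs.facet_tags if kind == "tag" else gs.facet_concepts
            target.setdefault(facet, {}).setdefault(label, set()).add(rid)
    return gs


def precision_recall_f(retrieved, relevant) -> tuple[float, float, float]:
    """Set precision, recall and F1 of a retrieved list against a relevant set.

    Precision is undefined for an empty retrieved list and reported as 0 with
    a warning; F is 0 whenever P + R is 0.
    """
    retrieved = list(retrieved)
    relevant = set(relevant)
    hits = len(set(retrieved) & relevant)
    if not retrieved:
        warnings.warn("empty retrieved list: precision undefined, reported as 0")
        p = 0.0
    else:
        p = hits / len(set(retrieved))
    r = hits / len(relevant) if relevant else 0.0
    f = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return p, r, f


def precision_at_k(retrieved, relevant, k: int) -> float:
    """Precision over the first min(k, len(retrieved)) items of a ranked list."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    retrieved = list(retrieved)[:k]
    if not retrieved:
        return 0.0
    relevant = set(relevant)
    return sum(1 for r in retrieved if r in relevant) / len(retrieved)


def average_precision(retrieved, relevant) -> float:
    """Average precision of a ranked list (mean of P@i at each relevant hit)."""
    relevant = set(relevant)
    if not relevant:
        return 0.0
    hits = 0
    total = 0.0
    for i, rid in enumerate(retrieved, start=1):
        if rid in relevant:
            hits += 1
            total += hits / i
    return total / len(relevant)


def facet_pair_metrics(t: str, c: str, gs: GoldStandard, facet: str) -> tuple[float, float, float]:
    """P/R/F of one (tag, concept) pair for a facet.

    P = |res(t) ∩ res(c)| / |res(c)|, R = |res(t) ∩ res(c)| / |res(t)|,
    F harmonic; empty denominators give 0 with a warning.
    """
    try:
        res_t = gs.facet_tags[facet][t]
    except KeyError:
        raise UnknownConceptError(f"tag {t!r} not in gold standard for facet {facet!r}") from None
    try:
        res_c = gs.facet_concepts[facet][c]
    except KeyError:
        raise UnknownConceptError(f"concept {c!r} not in gold standard for facet {facet!r}") from None
    inter = len(res_t & res_c)
    if not res_c or not res_t:
        warnings.warn("empty resource set in facet gold standard; metric reported as 0")
    p = inter / len(res_c) if res_c else 0.0
    r = inter / len(res_t) if res_t else 0.0
    f = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return p, r, f


def facet_macro_average(gs: GoldStandard, facet: str) -> tuple[float, float]:
    """Macro-averaged P and R for a facet over best (tag, concept) mappings.

    For each tag the concept maximizing F is chosen (lexicographically
    smallest concept id on ties); P and R of those pairs are averaged with
    weight 1/|tags|. An empty concept set gives (0, 0) with a warning.
    """
    tags = sorted(gs.tags(facet))
    if not tags:
        raise UnknownConceptError(f"no tags in gold standard for facet {facet!r}")
    concepts = sorted(gs.concepts(facet))
    if not concepts:
        warnings.warn(f"no extracted concepts for facet {facet!r}; macro-average is (0, 0)")
        return 0.0, 0.0
    p_sum = r_sum = 0.0
    for t in tags:
        # highest F; lexicographically smallest concept id on ties
        best = min(
            ((facet_pair_metrics(t, c, gs, facet), c) for c in concepts),
            key=lambda pair: (-pair[0][2], pair[1]),
        )
        (p, r, _), _ = best
        p_sum += p
        r_sum += r
    n = len(tags)
    return p_sum / n, r_sum / n
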