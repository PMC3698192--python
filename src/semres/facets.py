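"""Facet extraction from semantically annotated descriptions.

Resource descriptions rarely carry structured metadata; facts like input and
output data types, the method implemented, or the species and diseases a
resource covers live inside the free text. Two complementary techniques pull
them out of an annotated description:

* **Extraction patterns** of the generic form
  ``(noun-phrase)? relation E-noun-phrase`` — the relation is a facet-specific
  token (e.g. ``given``, ``finds``, ``implements``) and the E-noun-phrase is
  any noun phrase containing at least one semantic annotation. The concepts
  annotated inside the E-noun-phrase become the facet values.
* **Semantic types** — annotations whose concepts carry a type mapped to a
  facet (e.g. ``Disease``, ``Mammal``) define that facet directly, with no
  pattern involved.

Each facet of a description is finally represented by a semantic vector over
the union of concepts of all its instances.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path

import yaml

from .annotate import SemanticAnnotation, idf
from .errors import ConfigurationError
from .repository import BackgroundModel, Lexicon, Repository
from .tokens import DEFAULT_POLICY, PRONOUNS, STOPWORDS, TokenPolicy, token_spans
from .vectors import SemanticVector

#: Maximum token distance between a relation token and the start of its
#: E-noun-phrase.
DEFAULT_WINDOW = 5

_NP_KINDS = ("keyword", "none", "entity")


@dataclass(frozen=True)
class FacetPattern:
    """One row of the pattern table: an NP form plus its relation tokens."""

    facet: str
    relations: tuple[str, ...]
    np_kind: str = "none"
    np_regex: str | None = None

    def __post_init__(self) -> None:
        if not self.relations:
            raise ConfigurationError(f"pattern for facet {self.facet!r} has no relation tokens")
        if self.np_kind not in _NP_KINDS:
            raise ConfigurationError(f"unknown np form {self.np_kind!r}")
        if self.np_kind == "keyword" and not self.np_regex:
            raise ConfigurationError(f"keyword pattern for facet {self.facet!r} needs np_regex")


@dataclass(frozen=True)
class FacetInstance:
    """An extracted facet value: facet, optional NP, relation, concept set."""

    facet: str
    np: str
    relation: str
    concepts: frozenset[str]
    start: int = 0  # character offset of the relation (pattern rows) or annotation


@dataclass(frozen=True)
class FacetConfig:
    """Pattern rows plus semantic-type map for a configured facet set."""

    patterns: tuple[FacetPattern, ...]
    type_map: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def facets(self) -> set[str]:
        return {p.facet for p in self.patterns} | set(self.type_map)


def load_patterns(path: str | Path | None = None) -> FacetConfig:
    """Load a facet configuration from YAML; ``None`` loads the shipped default."""
    if path is None:
        text = (importlib_resources.files("semres") / "data" / "default_patterns.yaml").read_text()
    else:
        text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "facets" not in raw:
        raise ConfigurationError("pattern file must define a top-level 'facets' map")
    patterns: list[FacetPattern] = []
    type_map: dict[str, frozenset[str]] = {}
    for facet, cfg in raw["facets"].items():
        cfg = cfg or {}
        for row in cfg.get("patterns") or []:
            patterns.append(
                FacetPattern(
                    facet=facet,
                    relations=tuple(str(r) for r in row.get("relations", [])),
                    np_kind=row.get("np", "none"),
                    np_regex=row.get("np_regex"),
                )
            )
        types = cfg.get("semantic_types") or []
        if types:
            type_map[facet] = frozenset(str(t) for t in types)
    return FacetConfig(patterns=tuple(patterns), type_map=type_map)


def _preceding_phrase(tokens: list[tuple[int, int, str]], norm: list[str], rel_start: int) -> tuple[str, list[int]]:
    """Maximal run of non-stopword tokens ending right before token ``rel_start``."""
    j = rel_start - 1
    picked: list[int] = []
    while j >= 0 and norm[j] not in STOPWORDS:
        picked.append(j)
        j -= 1
    picked.reverse()
    if not picked:
        return "", []
    return " ".join(tokens[k][2] for k in picked), picked


def extract_by_pattern(
    description: str,
    annotations: list[SemanticAnnotation],
    patterns,
    window: int = DEFAULT_WINDOW,
    policy: TokenPolicy = DEFAULT_POLICY,
) -> list[FacetInstance]:
    """Apply extraction patterns over an annotated description.

    For every occurrence of a relation token (case-insensitive; multi-word
    relations match as normalized token subsequences), the E-noun-phrase is
    the earliest annotated span starting within ``window`` tokens after the
    relation; its concepts are all annotations nested inside the widest such
    span. The leading NP is resolved according to the pattern row's NP form.
    Instances are ordered by relation position; no matches yield an empty list.
    """
    if isinstance(patterns, FacetConfig):
        patterns = patterns.patterns
    toks = token_spans(description)
    norm = [policy.normalize_token(t) for _, _, t in toks]
    if not toks:
        return []
    # token index of each annotation's start character
    starts = {s: i for i, (s, _, _) in enumerate(toks)}
    ann_by_token: dict[int, list[SemanticAnnotation]] = {}
    for a in annotations:
        i = starts.get(a.start)
        if i is not None:
            ann_by_token.setdefault(i, []).append(a)

    instances: list[FacetInstance] = []
    seen: set[tuple[str, str, str, frozenset[str], int]] = set()
    for pattern in patterns:
        for relation in pattern.relations:
            rel_tokens = policy.tokenize(relation)
            if not rel_tokens:
                continue
            for i in range(len(norm) - len(rel_tokens) + 1):
                if norm[i : i + len(rel_tokens)] != rel_tokens:
                    continue
                rel_end = i + len(rel_tokens)
                np_text = _resolve_np(pattern, toks, norm, i, policy)
                if np_text is None:
                    continue  # keyword row whose NP requirement failed
                e_span = _find_e_span(annotations, toks, rel_end, window)
                if e_span is None:
                    continue
                concepts = frozenset(
                    a.concept_id
                    for a in annotations
                    if e_span[0] <= a.start and a.end <= e_span[1]
                )
                key = (pattern.facet, np_text, relation, concepts, toks[i][0])
                if key not in seen:
                    seen.add(key)
                    instances.append(
                        FacetInstance(
                            facet=pattern.facet,
                            np=np_text,
                            relation=description[toks[i][0] : toks[rel_end - 1][1]],
                            concepts=concepts,
                            start=toks[i][0],
                        )
                    )
    instances.sort(key=lambda inst: (inst.start, inst.facet))
    return instances


def _resolve_np(pattern: FacetPattern, toks, norm, rel_start: int, policy: TokenPolicy) -> str | None:
    """Leading NP of a pattern occurrence; None means the row does not fire."""
    if pattern.np_kind == "none":
        return ""
    if rel_start > 0 and norm[rel_start - 1] in PRONOUNS:
        if pattern.np_kind == "entity":
            return toks[rel_start - 1][2]
        return None  # keyword rows never accept a pronoun
    phrase, picked = _preceding_phrase(toks, norm, rel_start)
    if pattern.np_kind == "keyword":
        # the NP keyword ("input"/"output"...) must be the phrase head
        if picked and re.fullmatch(pattern.np_regex, norm[picked[-1]], re.IGNORECASE):
            return phrase
        return None
    return phrase  # entity form: record whatever subject precedes, may be ""


def _find_e_span(annotations, toks, rel_end: int, window: int) -> tuple[int, int] | None:
    """Widest annotated span starting at the earliest annotated token within
    ``window`` tokens after the relation."""
    if rel_end >= len(toks):
        return None
    window_char_start = toks[rel_end][0]
    limit = min(rel_end + window, len(toks)) - 1
    window_char_end = toks[limit][1] if limit >= rel_end else window_char_start
    candidates = [a for a in annotations if window_char_start <= a.start <= window_char_end]
    if not candidates:
        return None
    first = min(a.start for a in candidates)
    widest = max(a.end for a in candidates if a.start == first)
    # widen to cover annotations nested beyond the first's end but inside it
    return (first, widest)


def extract_by_semantic_type(
    annotations: list[SemanticAnnotation],
    repository: Repository,
    type_map: dict[str, frozenset[str]] | FacetConfig | None = None,
) -> list[FacetInstance]:
    """Facet instances from annotation semantic types (no pattern, empty NP/R).

    Defaults: species from {Bacterium, Virus, Mammal, Species}, disease from
    {Disease}. Every annotation whose concept carries a mapped type yields one
    instance for that facet.
    """
    if type_map is None:
        type_map = load_patterns().type_map
    elif isinstance(type_map, FacetConfig):
        type_map = type_map.type_map
    for facet, types in type_map.items():
        if not isinstance(facet, str) or not types:
            raise ConfigurationError(f"bad semantic-type map entry for facet {facet!r}")
    instances: list[FacetInstance] = []
    for a in annotations:
        concept = repository[a.concept_id]
        for facet, types in type_map.items():
            if concept.semantic_types & types:
                instances.append(
                    FacetInstance(facet=facet, np="", relation="", concepts=frozenset({a.concept_id}), start=a.start)
                )
    instances.sort(key=lambda inst: (inst.start, inst.facet))
    return instances


def facet_vectors(
    instances: list[FacetInstance],
    lexicon: Lexicon,
    background: BackgroundModel,
) -> dict[str, SemanticVector]:
    """Per-facet tf·idf vectors over the union of instance concept sets.

    tf(c) = number of instances of the facet mentioning c; facets with no
    instances are absent from the map.
    """
    counts: dict[str, dict[str, int]] = {}
    for inst in instances:
        per = counts.setdefault(inst.facet, {})
        for cid in inst.concepts:
            per[cid] = per.get(cid, 0) + 1
    return {
        facet: SemanticVector(
            {cid: n * idf(lexicon.variants_of(cid), background, lexicon.policy) for cid, n in per.items()}
        )
        for facet, per in counts.items()
        if per
    }
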