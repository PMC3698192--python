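"""Concept repository, background word-probability model, and lexicon.

The repository is a loose integration of one or more knowledge resources:
an inventory of concepts, each with a non-empty set of lexical variants
``lex(C)``, a set of semantic types, and ``is_a`` taxonomy parents forming a
DAG. Concept ids are opaque strings (e.g. ``UMLS:C1514562``, ``EDAM_1234``).

The background model supplies word probabilities P(w | Background) used to
measure the information content of a string::

    info(S) = -sum_{w in S} log P(w | Background)

computed in natural log over the *bag* of words of S (multiplicity counts).
Unseen words receive a strictly positive out-of-vocabulary floor so info is
always finite.
"""

from __future__ import annotations

import csv
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from .errors import RepositoryError, UnknownConceptError
from .tokens import DEFAULT_POLICY, TokenPolicy


@dataclass(frozen=True)
class Concept:
    """A node of the knowledge repository."""

    id: str
    lex: frozenset[str]
    semantic_types: frozenset[str] = frozenset()
    parents: frozenset[str] = frozenset()
    source: str = ""

    def __post_init__(self) -> None:
        if not self.lex:
            raise RepositoryError(f"concept {self.id!r} has an empty lexical-variant set")
        if self.id in self.parents:
            raise RepositoryError(f"concept {self.id!r} is its own is_a parent")


class BackgroundModel:
    """Word probabilities with an explicit out-of-vocabulary floor.

    Parameters
    ----------
    probabilities:
        Map word -> probability; every value must lie in (0, 1].
    oov_probability:
        Strictly positive probability assigned to unseen words.
    """

    def __init__(self, probabilities: dict[str, float], oov_probability: float):
        for word, p in probabilities.items():
            if not (0.0 < p <= 1.0):
                raise RepositoryError(f"background probability for {word!r} is {p}, not in (0, 1]")
        if oov_probability <= 0:
            raise RepositoryError(f"oov_probability must be > 0, got {oov_probability}")
        self.probabilities = dict(probabilities)
        self.oov_probability = float(oov_probability)

    @classmethod
    def from_counts(cls, counts: dict[str, int], oov_probability: float | None = None) -> "BackgroundModel":
        """Build from raw corpus counts.

        The default OOV floor is ``1 / (2 * total token count)`` — half the
        mass of a word that occurred once.
        """
        total = sum(counts.values())
        if total <= 0:
            raise RepositoryError("background counts sum to zero")
        for word, c in counts.items():
            if c <= 0:
                raise RepositoryError(f"background count for {word!r} is {c}, must be positive")
        probs = {w: c / total for w, c in counts.items()}
        if oov_probability is None:
            oov_probability = 1.0 / (2.0 * total)
        return cls(probs, oov_probability)

    def probability(self, word: str) -> float:
        return self.probabilities.get(word, self.oov_probability)

    def __contains__(self, word: str) -> bool:
        return word in self.probabilities


def info(tokens, background: BackgroundModel) -> float:
    """Information content of a bag of words: ``-sum_w log P(w | Background)``.

    ``tokens`` may be any iterable of normalized tokens or a Counter bag;
    multiplicity counts. The empty bag has zero information. Natural log.
    """
    if isinstance(tokens, Counter):
        items = tokens.items()
    else:
        items = Counter(tokens).items()
    return -sum(n * math.log(background.probability(w)) for w, n in items)


class Repository:
    """Validated concept inventory with is_a closure queries."""

    def __init__(self, concepts: dict[str, Concept]):
        self.concepts = dict(concepts)
        self._children: dict[str, set[str]] = defaultdict(set)
        for c in self.concepts.values():
            for p in c.parents:
                if p not in self.concepts:
                    raise RepositoryError(f"concept {c.id!r} has unknown parent {p!r}")
                self._children[p].add(c.id)
        cycle = self._find_cycle()
        if cycle:
            raise RepositoryError("is_a taxonomy contains a cycle: " + " -> ".join(cycle))

    def _find_cycle(self) -> list[str] | None:
        WHITE, GREY, BLACK = 0, 1, 2
        color = dict.fromkeys(self.concepts, WHITE)
        stack_path: list[str] = []

        def dfs(node: str) -> list[str] | None:
            color[node] = GREY
            stack_path.append(node)
            for parent in self.concepts[node].parents:
                if color[parent] == GREY:
                    i = stack_path.index(parent)
                    return stack_path[i:] + [parent]
                if color[parent] == WHITE:
                    found = dfs(parent)
                    if found:
                        return found
            color[node] = BLACK
            stack_path.pop()
            return None

        for cid in self.concepts:
            if color[cid] == WHITE:
                found = dfs(cid)
                if found:
                    return found
        return None

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def __getitem__(self, concept_id: str) -> Concept:
        try:
            return self.concepts[concept_id]
        except KeyError:
            raise UnknownConceptError(concept_id) from None

    def ancestors(self, concept_id: str) -> set[str]:
        """Transitive is_a closure upward, excluding the concept itself."""
        self[concept_id]
        seen: set[str] = set()
        frontier = list(self.concepts[concept_id].parents)
        while frontier:
            node = frontier.pop()
            if node in seen:
                continue
            seen.add(node)
            frontier.extend(self.concepts[node].parents)
        return seen

    def descendants(self, concept_id: str) -> set[str]:
        """Transitive is_a closure downward, excluding the concept itself."""
        self[concept_id]
        seen: set[str] = set()
        frontier = list(self._children.get(concept_id, ()))
        while frontier:
            node = frontier.pop()
            if node in seen:
                continue
            seen.add(node)
            frontier.extend(self._children.get(node, ()))
        return seen


class Lexicon:
    """Normalized-token-bag index over every (concept, variant) pair.

    One entry per distinct normalized bag; each entry records the set of
    (concept id, original variant string) pairs it came from, so a surface
    form shared by two concepts yields both on lookup.
    """

    def __init__(self, policy: TokenPolicy = DEFAULT_POLICY):
        self.policy = policy
        self.entries: dict[tuple[str, ...], set[tuple[str, str]]] = defaultdict(set)
        self._variants_by_concept: dict[str, frozenset[str]] = {}
        self._token_index: dict[str, set[str]] = defaultdict(set)

    def add(self, concept_id: str, variant: str) -> None:
        key = self.policy.bag_key(variant)
        if not key:
            return  # variant normalizes to nothing; nothing to index
        self.entries[key].add((concept_id, variant))
        for token in set(key):
            self._token_index[token].add(concept_id)

    def lookup(self, text: str) -> set[tuple[str, str]]:
        """Exact bag-of-words lookup of a surface string."""
        return set(self.entries.get(self.policy.bag_key(text), ()))

    def variants_of(self, concept_id: str) -> frozenset[str]:
        return self._variants_by_concept[concept_id]

    def candidates(self, tokens) -> set[str]:
        """Concept ids whose variants share at least one token with the bag."""
        out: set[str] = set()
        for token in set(tokens):
            out |= self._token_index.get(token, set())
        return out

    def __len__(self) -> int:
        return len(self.entries)


def build_lexicon(repository: Repository, policy: TokenPolicy = DEFAULT_POLICY) -> Lexicon:
    """Index every lexical variant of every concept by its normalized bag."""
    lex = Lexicon(policy)
    for concept in repository.concepts.values():
        lex._variants_by_concept[concept.id] = concept.lex
        for variant in concept.lex:
            lex.add(concept.id, variant)
    return lex


def _read_tsv(path: Path) -> list[list[str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        return [row for row in csv.reader(fh, delimiter="\t") if row and row[0].strip()]


def load_repository(
    concepts_path: str | Path,
    taxonomy_path: str | Path,
    background_path: str | Path,
    policy: TokenPolicy = DEFAULT_POLICY,
) -> tuple[Repository, BackgroundModel]:
    """Load concepts, is_a taxonomy and background counts from TSV files.

    File dialects (no headers):

    * concepts: ``id <TAB> variant <TAB> semantic_type(;-separated) <TAB> source``,
      one row per (id, variant); rows with the same id merge their variants.
    * taxonomy: ``child_id <TAB> parent_id``.
    * background: ``word <TAB> count``; probabilities and the OOV floor are
      derived from counts at load time.
    """
    variants: dict[str, set[str]] = defaultdict(set)
    types: dict[str, set[str]] = defaultdict(set)
    sources: dict[str, str] = {}
    for row in _read_tsv(Path(concepts_path)):
        cid = row[0].strip()
        variant = row[1].strip() if len(row) > 1 else ""
        if variant:
            variants[cid].add(variant)
        if len(row) > 2 and row[2].strip():
            types[cid] |= {t.strip() for t in row[2].split(";") if t.strip()}
        if len(row) > 3 and row[3].strip():
            sources[cid] = row[3].strip()

    parents: dict[str, set[str]] = defaultdict(set)
    for row in _read_tsv(Path(taxonomy_path)):
        if len(row) < 2:
            raise RepositoryError(f"taxonomy row needs child and parent: {row!r}")
        child, parent = row[0].strip(), row[1].strip()
        if child == parent:
            raise RepositoryError(f"taxonomy self-loop: {child!r} is_a {parent!r}")
        parents[child].add(parent)

    concepts: dict[str, Concept] = {}
    for cid in variants:
        if not variants[cid]:
            raise RepositoryError(f"concept {cid!r} has an empty lexical-variant set")
        concepts[cid] = Concept(
            id=cid,
            lex=frozenset(variants[cid]),
            semantic_types=frozenset(types.get(cid, ())),
            parents=frozenset(parents.get(cid, ())),
            source=sources.get(cid, ""),
        )
    for child in parents:
        if child not in concepts:
            raise RepositoryError(f"taxonomy references unknown concept {child!r}")

    counts: dict[str, int] = {}
    for row in _read_tsv(Path(background_path)):
        if len(row) < 2:
            raise RepositoryError(f"background row needs word and count: {row!r}")
        try:
            counts[row[0].strip()] = int(row[1])
        except ValueError:
            raise RepositoryError(f"background count not an integer: {row!r}") from None

    background = BackgroundModel.from_counts(counts)
    return Repository(concepts), background
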