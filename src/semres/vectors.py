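"""Sparse concept-weighted semantic vectors (tf·idf over annotations)."""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping


class SemanticVector:
    """Sparse map concept id -> non-negative weight; zero weights are dropped."""

    __slots__ = ("weights",)

    def __init__(self, weights: Mapping[str, float] | None = None):
        self.weights: dict[str, float] = {c: float(w) for c, w in (weights or {}).items() if w > 0.0}

    def __bool__(self) -> bool:
        return bool(self.weights)

    def __len__(self) -> int:
        return len(self.weights)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.weights

    def __getitem__(self, concept_id: str) -> float:
        return self.weights[concept_id]

    def __eq__(self, other) -> bool:
        return isinstance(other, SemanticVector) and self.weights == other.weights

    def __repr__(self) -> str:
        inner = ", ".join(f"{c}: {w:.4g}" for c, w in sorted(self.weights.items()))
        return f"SemanticVector({{{inner}}})"

    @property
    def concepts(self) -> set[str]:
        return set(self.weights)

    def restrict(self, keep: Iterable[str]) -> "SemanticVector":
        keep = set(keep)
        return SemanticVector({c: w for c, w in self.weights.items() if c in keep})

    def merge(self, other: "SemanticVector") -> "SemanticVector":
        """Union of supports; weights of shared concepts add."""
        out = dict(self.weights)
        for c, w in other.weights.items():
            out[c] = out.get(c, 0.0) + w
        return SemanticVector(out)

    def to_dict(self) -> dict[str, float]:
        return dict(sorted(self.weights.items()))


def cosine(a: SemanticVector, b: SemanticVector) -> float:
    """Cosine similarity of two sparse vectors; 0.0 if either is empty."""
    if not a or not b:
        return 0.0
    dot = sum(w * b.weights[c] for c, w in a.weights.items() if c in b.weights)
    na = math.sqrt(sum(w * w for w in a.weights.values()))
    nb = math.sqrt(sum(w * w for w in b.weights.values()))
    return dot / (na * nb)
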