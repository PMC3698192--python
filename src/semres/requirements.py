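"""Goal/task requirements model: loading, normalization, I/O propagation and
annotation refinement.

A user's information need is a goal plus an ordered list of tasks, each with a
free-text description, optional explicit facet values, and dependencies on
other tasks (a DAG). Normalization annotates every task description, turning
it into a tf·idf semantic vector plus per-facet vectors; explicit facet values
(either free text or concept ids) override what the extractor found in the
description. Facet values a task lacks can then be filled in from its
neighbours: a task inherits its input from the outputs of the tasks it depends
on, and its output from the inputs of the tasks that depend on it.

Refinement lets a user prune wrongly annotated concepts or swap a concept for
a narrower/broader one in the taxonomy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

from .annotate import DEFAULT_THRESHOLD, annotate, idf, to_vector
from .errors import RefinementError, RepositoryError, UnknownConceptError
from .facets import FacetConfig, extract_by_pattern, extract_by_semantic_type, facet_vectors, load_patterns
from .repository import BackgroundModel, Lexicon, Repository
from .vectors import SemanticVector


@dataclass(frozen=True)
class Task:
    """One step of the requirements model."""

    id: str
    description: str
    explicit_facets: dict[str, object] = field(default_factory=dict)
    depends_on: frozenset[str] = frozenset()
    vector: SemanticVector | None = None
    facet_vectors: dict[str, SemanticVector] = field(default_factory=dict)
    #: provenance of each facet vector: "explicit", "extracted" or "propagated"
    facet_origin: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class RequirementsModel:
    """A goal plus its ordered tasks; dependency closure must be acyclic."""

    goal: str
    tasks: tuple[Task, ...]

    def __post_init__(self) -> None:
        ids = [t.id for t in self.tasks]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise RepositoryError(f"duplicate task ids: {dupes}")
        known = set(ids)
        for t in self.tasks:
            unknown = t.depends_on - known
            if unknown:
                raise RepositoryError(f"task {t.id!r} depends on unknown tasks {sorted(unknown)}")
        cycle = _find_cycle({t.id: t.depends_on for t in self.tasks})
        if cycle:
            raise RepositoryError("task dependencies contain a cycle: " + " -> ".join(cycle))

    def task(self, task_id: str) -> Task:
        for t in self.tasks:
            if t.id == task_id:
                return t
        raise KeyError(task_id)

    def dependents_of(self, task_id: str) -> set[str]:
        return {t.id for t in self.tasks if task_id in t.depends_on}


def _find_cycle(deps: dict[str, frozenset[str]]) -> list[str] | None:
    WHITE, GREY, BLACK = 0, 1, 2
    color = dict.fromkeys(deps, WHITE)
    path: list[str] = []

    def dfs(node: str) -> list[str] | None:
        color[node] = GREY
        path.append(node)
        for nxt in deps[node]:
            if color[nxt] == GREY:
                i = path.index(nxt)
                return path[i:] + [nxt]
            if color[nxt] == WHITE:
                found = dfs(nxt)
                if found:
                    return found
        color[node] = BLACK
        path.pop()
        return None

    for node in deps:
        if color[node] == WHITE:
            found = dfs(node)
            if found:
                return found
    return None


def load_requirements(path: str | Path) -> RequirementsModel:
    """Load a requirements model from JSON.

    Schema: ``{goal, tasks: [{id, description, facets: {facet: text-or-id-list},
    depends_on: [...]}]}``. Duplicate ids and dependency cycles are structural
    errors.
    """
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    tasks = []
    for t in raw.get("tasks", []):
        tasks.append(
            Task(
                id=str(t["id"]),
                description=str(t.get("description", "")),
                explicit_facets=dict(t.get("facets") or {}),
                depends_on=frozenset(str(d) for d in t.get("depends_on") or []),
            )
        )
    return RequirementsModel(goal=str(raw.get("goal", "")), tasks=tuple(tasks))


def _explicit_vector(value, repository: Repository, lexicon: Lexicon, background: BackgroundModel, threshold: float) -> SemanticVector:
    """Vector for an explicit facet value: a concept-id list is taken literally
    (tf = 1 each); free text is annotated like any description."""
    if isinstance(value, (list, tuple, set)):
        weights = {}
        for cid in value:
            if cid not in repository:
                raise UnknownConceptError(cid)
            weights[cid] = idf(repository[cid], background, lexicon.policy)
        return SemanticVector(weights)
    anns = annotate(str(value), lexicon, background, threshold)
    return to_vector(anns, lexicon, background)


def normalize_model(
    model: RequirementsModel,
    repository: Repository,
    lexicon: Lexicon,
    background: BackgroundModel,
    patterns: FacetConfig | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> RequirementsModel:
    """Annotate every task and build its semantic and facet vectors.

    Facet values are merged with priority explicit > text-extracted; propagated
    values are added later by :func:`propagate_io` and never override either.
    Pure function: the input model is not mutated.
    """
    if patterns is None:
        patterns = load_patterns()
    new_tasks = []
    for task in model.tasks:
        anns = annotate(task.description, lexicon, background, threshold)
        vector = to_vector(anns, lexicon, background)
        if not vector:
            warnings.warn(f"task {task.id!r} produced no annotations; empty vector")
        instances = extract_by_pattern(task.description, anns, patterns)
        instances += extract_by_semantic_type(anns, repository, patterns)
        fvecs = facet_vectors(instances, lexicon, background)
        origin = {f: "extracted" for f in fvecs}
        for facet, value in task.explicit_facets.items():
            vec = _explicit_vector(value, repository, lexicon, background, threshold)
            if vec:
                fvecs[facet] = vec
                origin[facet] = "explicit"
        new_tasks.append(replace(task, vector=vector, facet_vectors=fvecs, facet_origin=origin))
    return RequirementsModel(goal=model.goal, tasks=tuple(new_tasks))


def propagate_io(model: RequirementsModel) -> RequirementsModel:
    """Fill missing input/output facets from dependency structure.

    A task with no input facet inherits the union of its dependencies' output
    vectors; a task with no output facet inherits the union of its dependents'
    input vectors. Each pass reads only the state the pass started from
    (single hop); passes repeat until nothing changes, so the call returns the
    fixpoint and a second call is the identity. Explicit and extracted values
    are never overwritten, and a vector filled by propagation never seeds a
    further vector within the same pass.
    """
    fvecs_by_id = {t.id: dict(t.facet_vectors) for t in model.tasks}
    origin_by_id = {t.id: dict(t.facet_origin) for t in model.tasks}
    dependents = {t.id: sorted(model.dependents_of(t.id)) for t in model.tasks}
    for _ in range(2 * len(model.tasks) + 1):
        snapshot = {tid: dict(v) for tid, v in fvecs_by_id.items()}
        changed = False
        for task in model.tasks:
            fvecs = fvecs_by_id[task.id]
            if "input" not in fvecs:
                union = SemanticVector()
                for dep in sorted(task.depends_on):
                    out = snapshot[dep].get("output")
                    if out:
                        union = union.merge(out)
                if union:
                    fvecs["input"] = union
                    origin_by_id[task.id]["input"] = "propagated"
                    changed = True
            if "output" not in fvecs:
                union = SemanticVector()
                for dep_id in dependents[task.id]:
                    inp = snapshot[dep_id].get("input")
                    if inp:
                        union = union.merge(inp)
                if union:
                    fvecs["output"] = union
                    origin_by_id[task.id]["output"] = "propagated"
                    changed = True
        if not changed:
            break
    new_tasks = [
        replace(t, facet_vectors=fvecs_by_id[t.id], facet_origin=origin_by_id[t.id])
        for t in model.tasks
    ]
    return RequirementsModel(goal=model.goal, tasks=tuple(new_tasks))


def refine_select(task: Task, keep) -> Task:
    """Restrict the task vector to ``keep``; weights of kept concepts unchanged."""
    keep = set(keep)
    if task.vector is None:
        raise RefinementError(f"task {task.id!r} is not normalized")
    offenders = keep - task.vector.concepts
    if offenders:
        raise RefinementError(f"concepts not in task vector: {sorted(offenders)}")
    return replace(task, vector=task.vector.restrict(keep))


def _refine_swap(
    task: Task,
    concept_id: str,
    replacement_id: str,
    repository: Repository,
    lexicon: Lexicon,
    background: BackgroundModel,
    allowed: set[str],
    direction: str,
) -> Task:
    if task.vector is None or concept_id not in task.vector:
        raise RefinementError(f"concept {concept_id!r} not in task vector")
    if replacement_id not in allowed:
        raise RefinementError(
            f"{replacement_id!r} is not a {direction} of {concept_id!r}"
        )
    old_idf = idf(repository[concept_id], background, lexicon.policy)
    tf = task.vector[concept_id] / old_idf
    new_idf = idf(repository[replacement_id], background, lexicon.policy)
    weights = dict(task.vector.weights)
    del weights[concept_id]
    weights[replacement_id] = weights.get(replacement_id, 0.0) + tf * new_idf
    return replace(task, vector=SemanticVector(weights))


def refine_specialize(
    task: Task, concept_id: str, replacement_id: str,
    repository: Repository, lexicon: Lexicon, background: BackgroundModel,
) -> Task:
    """Swap a concept for one of its descendants; tf carries over, idf is
    recomputed for the replacement."""
    return _refine_swap(task, concept_id, replacement_id, repository, lexicon,
                        background, repository.descendants(concept_id), "descendant")


def refine_generalize(
    task: Task, concept_id: str, replacement_id: str,
    repository: Repository, lexicon: Lexicon, background: BackgroundModel,
) -> Task:
    """Swap a concept for one of its ancestors; tf carries over, idf is
    recomputed for the replacement."""
    return _refine_swap(task, concept_id, replacement_id, repository, lexicon,
                        background, repository.ancestors(concept_id), "ancestor")
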