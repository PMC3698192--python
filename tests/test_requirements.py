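"""Requirements model: loading, normalization, I/O propagation, refinement."""

import json

import pytest

from semres.annotate import annotate, idf, to_vector
from semres.errors import RefinementError, RepositoryError
from semres.repository import BackgroundModel, Concept, Repository, build_lexicon
from semres.requirements import (
    RequirementsModel,
    Task,
    load_requirements,
    normalize_model,
    propagate_io,
    refine_generalize,
    refine_select,
    refine_specialize,
)
from semres.vectors import SemanticVector


@pytest.fixture(scope="module")
def kr():
    repo = Repository({
        "SEQ": Concept("SEQ", frozenset({"sequence", "sequences"})),
        "PSEQ": Concept("PSEQ", frozenset({"protein sequence", "protein sequences"}),
                        parents=frozenset({"SEQ"})),
        "ALN": Concept("ALN", frozenset({"sequence alignment"})),
        "TREE": Concept("TREE", frozenset({"phylogenetic tree", "phylogenetic trees"})),
        "DOM": Concept("DOM", frozenset({"functional domain", "functional domains"})),
    })
    words = "sequence protein alignment phylogenetic tree functional domain align build search similar given analyze".split()
    bg = BackgroundModel.from_counts({w: 80 for w in words})
    return repo, bg, build_lexicon(repo)


def write_model(tmp_path, payload):
    p = tmp_path / "req.json"
    p.write_text(json.dumps(payload))
    return p


CASE_STUDY = {
    "goal": "specific genes in different organisms to be compared",
    "tasks": [
        {"id": "t1", "description": "search similar sequences given a protein sequence"},
        {"id": "t2", "description": "predict the gene structure", "depends_on": ["t1"]},
        {"id": "t3", "description": "align protein sequences", "depends_on": ["t2"],
         "facets": {"output": "sequence alignment"}},
        {"id": "t4", "description": "build a phylogenetic tree", "depends_on": ["t3"]},
        {"id": "t5", "description": "analyze the functional domain given a protein sequence",
         "depends_on": ["t4"]},
    ],
}


class TestLoad:
    def test_five_task_chain_loads(self, tmp_path):
        model = load_requirements(write_model(tmp_path, CASE_STUDY))
        assert len(model.tasks) == 5
        assert model.task("t4").depends_on == frozenset({"t3"})

    def test_single_task_no_deps(self, tmp_path):
        model = load_requirements(write_model(tmp_path, {"goal": "g", "tasks": [
            {"id": "only", "description": "align protein sequences"}]}))
        assert len(model.tasks) == 1

    def test_cycle_rejected(self, tmp_path):
        bad = {"goal": "g", "tasks": [
            {"id": "a", "description": "x", "depends_on": ["b"]},
            {"id": "b", "description": "y", "depends_on": ["a"]}]}
        with pytest.raises(RepositoryError, match="cycle"):
            load_requirements(write_model(tmp_path, bad))

    def test_duplicate_ids_rejected(self, tmp_path):
        bad = {"goal": "g", "tasks": [
            {"id": "a", "description": "x"}, {"id": "a", "description": "y"}]}
        with pytest.raises(RepositoryError, match="duplicate"):
            load_requirements(write_model(tmp_path, bad))


class TestNormalize:
    def test_matching_task_gets_vector(self, kr):
        repo, bg, lex = kr
        model = RequirementsModel("g", (Task("t", "align protein sequences"),))
        norm = normalize_model(model, repo, lex, bg)
        assert norm.task("t").vector

    def test_unmatched_task_empty_vector_with_warning(self, kr):
        repo, bg, lex = kr
        model = RequirementsModel("g", (Task("t", "metabolic pathway curation"),))
        with pytest.warns(UserWarning, match="no annotations"):
            norm = normalize_model(model, repo, lex, bg)
        assert not norm.task("t").vector

    def test_each_task_vector_equals_per_stage_pipeline(self, kr, tmp_path):
        repo, bg, lex = kr
        model = load_requirements(write_model(tmp_path, CASE_STUDY))
        norm = normalize_model(model, repo, lex, bg)
        for task in model.tasks:
            expected = to_vector(annotate(task.description, lex, bg), lex, bg)
            assert norm.task(task.id).vector == expected

    def test_explicit_facet_overrides_extracted(self, kr, tmp_path):
        repo, bg, lex = kr
        model = load_requirements(write_model(tmp_path, CASE_STUDY))
        norm = normalize_model(model, repo, lex, bg)
        t3 = norm.task("t3")
        assert t3.facet_origin["output"] == "explicit"
        # full phrase maps to the alignment concept; the embedded head noun
        # legitimately adds its general concept
        assert "ALN" in t3.facet_vectors["output"].concepts
        assert t3.facet_vectors["output"].concepts <= {"ALN", "SEQ"}

    def test_explicit_concept_id_list(self, kr):
        repo, bg, lex = kr
        model = RequirementsModel("g", (Task("t", "align protein sequences",
                                             explicit_facets={"input": ["PSEQ"]}),))
        norm = normalize_model(model, repo, lex, bg)
        vec = norm.task("t").facet_vectors["input"]
        assert vec.concepts == {"PSEQ"}
        assert vec["PSEQ"] == pytest.approx(idf(repo["PSEQ"], bg))

    def test_pure_function_of_inputs(self, kr, tmp_path):
        repo, bg, lex = kr
        model = load_requirements(write_model(tmp_path, CASE_STUDY))
        a = normalize_model(model, repo, lex, bg)
        b = normalize_model(model, repo, lex, bg)
        assert [t.vector for t in a.tasks] == [t.vector for t in b.tasks]
        assert [t.facet_vectors for t in a.tasks] == [t.facet_vectors for t in b.tasks]


class TestPropagateIO:
    def test_dependent_task_inherits_output_as_input(self, kr, tmp_path):
        """build-phylogenetic-tree inherits the sequence-alignment output of
        align-protein-sequences."""
        repo, bg, lex = kr
        model = normalize_model(load_requirements(write_model(tmp_path, CASE_STUDY)), repo, lex, bg)
        t4_before = model.task("t4")
        assert "input" not in t4_before.facet_vectors
        after = propagate_io(model)
        t4 = after.task("t4")
        assert t4.facet_origin["input"] == "propagated"
        assert "ALN" in t4.facet_vectors["input"].concepts
        assert t4.facet_vectors["input"] == after.task("t3").facet_vectors["output"]

    def test_explicit_value_never_overwritten(self, kr):
        repo, bg, lex = kr
        model = RequirementsModel("g", (
            Task("a", "align protein sequences", explicit_facets={"output": "sequence alignment"}),
            Task("b", "build a phylogenetic tree", explicit_facets={"input": ["TREE"]},
                 depends_on=frozenset({"a"})),
        ))
        after = propagate_io(normalize_model(model, repo, lex, bg))
        assert after.task("b").facet_vectors["input"].concepts == {"TREE"}
        assert after.task("b").facet_origin["input"] == "explicit"

    def test_chain_fills_exactly_second_task_input(self, kr):
        """Hand trace: chain a<-b<-c<-d with only a's output set; only b's
        input can be derived (inputs do not become outputs)."""
        repo, bg, lex = kr
        out = SemanticVector({"ALN": 1.0})
        tasks = (
            Task("a", "", vector=SemanticVector(), facet_vectors={"output": out}),
            Task("b", "", vector=SemanticVector(), facet_vectors={}, depends_on=frozenset({"a"})),
            Task("c", "", vector=SemanticVector(), facet_vectors={}, depends_on=frozenset({"b"})),
            Task("d", "", vector=SemanticVector(), facet_vectors={}, depends_on=frozenset({"c"})),
        )
        after = propagate_io(RequirementsModel("g", tasks))
        assert after.task("b").facet_vectors["input"] == out
        assert "input" not in after.task("c").facet_vectors
        assert "input" not in after.task("d").facet_vectors
        # a gains an output-from-dependent? b had no input before the call
        assert after.task("a").facet_vectors["output"] == out

    def test_multiple_dependencies_union(self, kr):
        tasks = (
            Task("a", "", facet_vectors={"output": SemanticVector({"ALN": 1.0})}),
            Task("b", "", facet_vectors={"output": SemanticVector({"TREE": 2.0})}),
            Task("c", "", facet_vectors={}, depends_on=frozenset({"a", "b"})),
        )
        after = propagate_io(RequirementsModel("g", tasks))
        assert after.task("c").facet_vectors["input"].concepts == {"ALN", "TREE"}

    def test_idempotent(self, kr, tmp_path):
        repo, bg, lex = kr
        model = normalize_model(load_requirements(write_model(tmp_path, CASE_STUDY)), repo, lex, bg)
        once = propagate_io(model)
        twice = propagate_io(once)
        for t1, t2 in zip(once.tasks, twice.tasks):
            assert t1.facet_vectors == t2.facet_vectors

    def test_idempotent_with_output_backfill(self):
        """Even when an output filled by propagation later enables an input
        fill, the fixpoint is reached within one call."""
        tasks = (
            Task("d", "", facet_vectors={}),
            Task("x", "", facet_vectors={}, depends_on=frozenset({"d"})),
            Task("y", "", facet_vectors={"input": SemanticVector({"SEQ": 1.0})},
                 depends_on=frozenset({"d"})),
        )
        once = propagate_io(RequirementsModel("g", tasks))
        twice = propagate_io(once)
        assert once.task("x").facet_vectors == twice.task("x").facet_vectors
        assert "input" in once.task("x").facet_vectors


class TestRefinement:
    def make_task(self, kr):
        repo, bg, lex = kr
        anns = annotate("align protein sequence and build phylogenetic tree", lex, bg)
        return Task("t", "", vector=to_vector(anns, lex, bg))

    def test_keep_all_is_identity(self, kr):
        task = self.make_task(kr)
        assert refine_select(task, task.vector.concepts).vector == task.vector

    def test_keep_none_empties(self, kr):
        task = self.make_task(kr)
        assert not refine_select(task, set()).vector

    def test_subset_matches_filter_oracle(self, kr):
        task = self.make_task(kr)
        keep = set(sorted(task.vector.concepts)[:2])
        refined = refine_select(task, keep)
        assert refined.vector.weights == {c: w for c, w in task.vector.weights.items() if c in keep}

    def test_unknown_keep_rejected(self, kr):
        task = self.make_task(kr)
        with pytest.raises(RefinementError, match="XXX"):
            refine_select(task, {"XXX"})

    def test_specialize_to_child(self, kr):
        repo, bg, lex = kr
        task = Task("t", "", vector=SemanticVector({"SEQ": idf(repo["SEQ"], bg)}))
        out = refine_specialize(task, "SEQ", "PSEQ", repo, lex, bg)
        assert "SEQ" not in out.vector
        assert out.vector["PSEQ"] == pytest.approx(idf(repo["PSEQ"], bg))

    def test_generalize_root_fails(self, kr):
        repo, bg, lex = kr
        task = Task("t", "", vector=SemanticVector({"SEQ": 1.0}))
        with pytest.raises(RefinementError):
            refine_generalize(task, "SEQ", "PSEQ", repo, lex, bg)

    def test_specialize_requires_descendant(self, kr):
        repo, bg, lex = kr
        task = Task("t", "", vector=SemanticVector({"ALN": 1.0}))
        with pytest.raises(RefinementError):
            refine_specialize(task, "ALN", "TREE", repo, lex, bg)

    def test_untouched_weights_unchanged(self, kr):
        repo, bg, lex = kr
        task = Task("t", "", vector=SemanticVector({
            "SEQ": idf(repo["SEQ"], bg), "TREE": 3.0}))
        out = refine_specialize(task, "SEQ", "PSEQ", repo, lex, bg)
        assert out.vector["TREE"] == 3.0

    def test_specialize_in_random_dag_respects_closure(self, small_pipeline):
        repo, bg = small_pipeline["repo"], small_pipeline["background"]
        lex = small_pipeline["lexicon"]
        cids = sorted(repo.concepts)
        for cid in cids:
            task = Task("t", "", vector=SemanticVector({cid: idf(repo[cid], bg)}))
            for other in cids:
                if other == cid:
                    continue
                if other in repo.descendants(cid):
                    refined = refine_specialize(task, cid, other, repo, lex, bg)
                    assert refined.vector.concepts == {other}
                else:
                    with pytest.raises(RefinementError):
                        refine_specialize(task, cid, other, repo, lex, bg)
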