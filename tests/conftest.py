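import pytest
from hypothesis import HealthCheck, settings

from semres.repository import BackgroundModel, Concept, Repository
from semres.synthetic import FixtureSpec, generate_corpus, generate_kr

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_repo():
    """Three-concept is_a chain: root 'sequence' <- 'protein sequence' <- 'lrrk2 protein sequence'."""
    return Repository({
        "A": Concept("A", frozenset({"sequence"}), frozenset({"Data"})),
        "B": Concept("B", frozenset({"protein sequence", "peptide sequence"}),
                     frozenset({"Protein"}), parents=frozenset({"A"})),
        "C": Concept("C", frozenset({"lrrk2 protein sequence"}),
                     frozenset({"Protein"}), parents=frozenset({"B"})),
    })


@pytest.fixture(scope="session")
def tiny_bg():
    words = "sequence protein peptide lrrk2 gene tree phylogenetic align alignment domain".split()
    counts = {w: 50 * (i + 1) for i, w in enumerate(words)}
    return BackgroundModel.from_counts(counts)


@pytest.fixture(scope="session")
def small_spec():
    return FixtureSpec(seed=7, n_concepts=20, n_resources=12, n_queries=8,
                       n_topics=2, taxonomy_depth=3, branching=3)


@pytest.fixture(scope="session")
def small_kr(small_spec):
    return generate_kr(small_spec)


@pytest.fixture(scope="session")
def small_corpus(small_spec, small_kr):
    return generate_corpus(small_spec, small_kr)


@pytest.fixture(scope="session")
def small_pipeline(small_spec, small_kr, small_corpus, tmp_path_factory):
    """Loaded repository + lexicon + normalized corpus for the small fixture."""
    from semres.facets import load_patterns
    from semres.ranking import normalize_corpus
    from semres.repository import build_lexicon, load_repository
    from semres.synthetic import write_kr

    outdir = tmp_path_factory.mktemp("kr")
    paths = write_kr(small_kr, outdir)
    repo, background = load_repository(paths["concepts"], paths["taxonomy"], paths["background"])
    lexicon = build_lexicon(repo)
    patterns = load_patterns()
    corpus = normalize_corpus(list(small_corpus.resources), lexicon, background, repo, patterns)
    return {
        "repo": repo, "background": background, "lexicon": lexicon,
        "patterns": patterns, "corpus": corpus,
    }
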