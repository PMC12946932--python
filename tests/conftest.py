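import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import phqscreen as pq
from phqscreen.synthetic import GeneratorConfig, generate_posts, posts_as_pairs

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ontology():
    return pq.default_ontology()


@pytest.fixture(scope="session")
def embedder():
    return pq.get_embedder("reference")


@pytest.fixture(scope="session")
def stopwords():
    return pq.load_stopwords()


@pytest.fixture(scope="session")
def snomed_table(tmp_path_factory):
    path = tmp_path_factory.mktemp("snomed") / "descriptions.tsv"
    pq.generate_snomed_fixture(path)
    return pq.load_snomed(path)


@pytest.fixture(scope="session")
def trained_model(ontology, embedder):
    """Classifier trained on a 500-post synthetic corpus (default conditions)."""
    posts = generate_posts(GeneratorConfig(n_posts=500, seed=100), ontology)
    return pq.train(posts_as_pairs(posts), embedder, pq.Hyperparams(seed=0))


@pytest.fixture(scope="session")
def single_label_splits(ontology):
    """Balanced single-item train/test corpora with guaranteed cue planting."""
    train = generate_posts(
        GeneratorConfig(n_posts=500, seed=11, min_items_per_post=1,
                        max_items_per_post=1, cue_rate=1.0),
        ontology,
    )
    test = generate_posts(
        GeneratorConfig(n_posts=100, seed=12, min_items_per_post=1,
                        max_items_per_post=1, cue_rate=1.0),
        ontology,
    )
    return train, test
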