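import pytest

from cglkit import benchmarks
from cglkit.embeddings import EmbedderSpec
from cglkit.simulate import (FamilySpec, embed_records, generate_family,
                             penalty_records)


@pytest.fixture(scope="session")
def small_family():
    """A small 3-class planted-signal dataset for fast model tests."""
    fix = generate_family(FamilySpec(n_sequences=120, seed=11))
    records = list(fix.records)
    labels = list(fix.labels)
    pr, pl = penalty_records(fix, n_parents=1)
    records += pr
    labels += pl
    embeddings = embed_records(records, EmbedderSpec(dim=32, seed=11))
    return records, labels, embeddings, fix


@pytest.fixture(scope="session")
def planted_dataset():
    """The full-size planted-signal study conditions: n = 600 natural
    sequences (contextual-pair label rule), catalytic-site knockouts as the
    no-activity group, D = 64 synthetic embeddings."""
    return benchmarks.planted_dataset()


@pytest.fixture(scope="session")
def planted_cv(planted_dataset):
    """5-fold cross-validated transformer on the planted-signal dataset
    (shared across the acceptance tests because training is the slow step)."""
    _, labels, embeddings, _ = planted_dataset
    return benchmarks.reference_cv(embeddings, labels)
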