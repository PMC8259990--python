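import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from condlm import synthetic as SY
from condlm import (build_condition_index, build_document_track, build_vocab,
                    filter_records, sample_corpus)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def two_topic_grammar():
    """Two disjoint-topic grammar used across corpus/model tests."""
    return SY.default_grammar(n_words=30, n_topics=2, mixing=1.0, seed=5)


@pytest.fixture(scope="session")
def small_corpus(two_topic_grammar):
    """60 filtered annotated records from the two-topic grammar."""
    return list(filter_records(sample_corpus(two_topic_grammar, 60, rng=7)))


@pytest.fixture(scope="session")
def prepared(two_topic_grammar, small_corpus):
    """(records, condition index, vocab, document tracks) for model tests."""
    recs = small_corpus
    idx = build_condition_index(recs, min_count=2, cutoff_year=2020)
    vocab = build_vocab([r.text for r in recs], size=100, seed=13)
    tracks = [build_document_track(r, vocab, idx) for r in recs]
    return recs, idx, vocab, tracks


@pytest.fixture
def rng():
    return np.random.default_rng(0)
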