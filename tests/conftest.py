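"""Shared fixtures: small synthetic bundles reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from quotedtext.synthetic import (
    NoteConfig,
    RegistryConfig,
    generate_notes,
    generate_registry,
    generate_topic_corpus,
)


@pytest.fixture(scope="session")
def small_registry():
    return generate_registry(RegistryConfig(n_patients=300, seed=11))


@pytest.fixture(scope="session")
def clean_bundle(small_registry):
    """Notes + gold with no adversarial hazards: extraction must be perfect."""
    notes, gold = generate_notes(small_registry, NoteConfig(seed=12))
    return notes, gold


@pytest.fixture(scope="session")
def adversarial_bundle():
    """The packaged adversarial fixture: fixed seed, hazard rates on."""
    registry = generate_registry(RegistryConfig(n_patients=800, seed=21))
    config = NoteConfig(
        seed=22,
        adversarial_rates={
            "apostrophe": 0.2,
            "html": 0.05,
            "blank": 0.05,
            "unbalanced": 0.03,
        },
    )
    notes, gold = generate_notes(registry, config)
    return notes, gold


@pytest.fixture(scope="session")
def topic_corpus():
    corpus, topic_map = generate_topic_corpus(NoteConfig(seed=31), 3000)
    return corpus, topic_map


@pytest.fixture(scope="session")
def topic_vectors(topic_corpus):
    from quotedtext.embeddings import train_cbow

    corpus, topic_map = topic_corpus
    table = train_cbow(corpus, dimension=50, window=5, min_count=5, epochs=3, seed=32)
    return table, topic_map


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def brute_force_mean_silhouette(matrix, labels):
    """O(n^2) mean silhouette straight from the definition; the independent
    oracle used against the production implementation."""
    X = np.asarray(matrix, float)
    labels = np.asarray(labels)
    n = len(X)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    vals = []
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            vals.append(0.0)
            continue
        a = D[i][own].sum() / (own.sum() - 1)
        b = min(
            D[i][labels == lab].mean() for lab in np.unique(labels) if lab != labels[i]
        )
        denom = max(a, b)
        vals.append(0.0 if denom == 0 else (b - a) / denom)
    return float(np.mean(vals))
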