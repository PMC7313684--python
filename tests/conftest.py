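"""Shared fixtures: small synthetic datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import myogest as mg
from myogest.features import feature_matrix


@pytest.fixture(scope="session")
def small_dataset() -> list[mg.EmgRecording]:
    """Six participants, four reps per gesture: 96 labeled recordings."""
    return mg.generate_dataset(6, 4, seed=7)


@pytest.fixture(scope="session")
def small_features(small_dataset) -> tuple[np.ndarray, np.ndarray]:
    procs = [mg.preprocess(r) for r in small_dataset]
    return feature_matrix(procs)


@pytest.fixture(scope="session")
def separable_toy() -> tuple[np.ndarray, np.ndarray]:
    """Four tight, well-separated 2-D clusters, one per gesture."""
    rng = np.random.default_rng(42)
    centers = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], dtype=float)
    X = np.vstack([c + 0.1 * rng.standard_normal((12, 2)) for c in centers])
    y = np.repeat(np.arange(4), 12)
    return X, y


@pytest.fixture(scope="session")
def streaming_model() -> tuple[mg.TrainedClassifier, list[mg.EmgRecording]]:
    """SVM trained on one participant's early reps; later reps held out for
    streaming replay (the online-use scenario: the model knows the user)."""
    recs = mg.generate_dataset(1, 8, seed=11)
    counts: dict[int, int] = {}
    train_recs, replay = [], []
    for r in recs:
        counts[int(r.label)] = counts.get(int(r.label), 0) + 1
        (train_recs if counts[int(r.label)] <= 5 else replay).append(r)
    X, y = mg.windowed_training_set(train_recs)
    model = mg.train(mg.ClassifierSpec(kind="svm", seed=0), X, y)
    return model, replay
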