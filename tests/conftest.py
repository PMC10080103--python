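import numpy as np
import pytest

from afe.data import SplitDataset
from afe.models import ClassifierSpec


class StubClassifier:
    """Deterministic classifier stub keyed by the first feature column.

    ``mapping[value]`` gives the posterior for rows whose first feature
    equals ``value``; unmatched rows get ``default``. Lets tests pin
    posteriors exactly without fitting anything.
    """

    def __init__(self, mapping=None, default=(0.5, 0.5), n_features=1, class_labels=(0, 1)):
        self.mapping = {float(k): np.asarray(v, dtype=float) for k, v in (mapping or {}).items()}
        self.default = np.asarray(default, dtype=float)
        self.n_features = n_features
        self.class_labels = np.asarray(class_labels)

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        return np.vstack([self.mapping.get(float(row[0]), self.default) for row in X])

    def predict(self, X):
        idx = np.argmax(self.predict_proba(X), axis=1)
        return self.class_labels[idx]


def make_split_dataset(n=10, n_fo=3, d_o=1, d_u=2, labels=None, seed=0):
    """Small SplitDataset whose observed feature 0 equals the row index,
    so stub classifiers can address examples individually."""
    rng = np.random.default_rng(seed)
    observed = np.column_stack(
        [np.arange(n, dtype=float)] + [rng.normal(size=n) for _ in range(d_o - 1)]
    )
    hidden = rng.normal(size=(n, d_u))
    if labels is None:
        labels = rng.integers(0, 2, size=n)
        labels[:2] = [0, 1]  # both classes present
    e_o = np.arange(n_fo)
    e_u = np.arange(n_fo, n)
    elic = np.full((n, d_u), np.nan)
    elic[e_o] = hidden[e_o]
    return SplitDataset(observed, elic, np.asarray(labels), e_o, e_u), hidden


@pytest.fixture
def stub_factory():
    return StubClassifier


@pytest.fixture
def small_dataset():
    return make_split_dataset()


@pytest.fixture
def fast_gb():
    """Small gradient-boosting spec to keep loop tests quick."""
    return ClassifierSpec(family="gradient_boosting", params={"n_estimators": 20, "max_depth": 2})


def random_distributions(rng, k, size):
    """Strictly positive random probability vectors (Dirichlet(1))."""
    return rng.dirichlet(np.ones(k), size=size)
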