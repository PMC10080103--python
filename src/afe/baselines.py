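"""Comparison strategies sharing the elicitation loop.

Three baselines stand against divergence-based selection, all plugging
into the same acquisition/retraining mechanics:

* ``rnd`` — uniform random batches from E_u;
* ``us_obs`` — uncertainty sampling: highest posterior entropy under the
  cheap-feature model M_u;
* ``us_all`` — uncertainty sampling on the full feature set, with each
  E_u row's missing elicitable features mode-imputed from the current
  E_o before scoring under M_o.

Random draws use a stream derived from (run seed, iteration) so baseline
randomness never perturbs the classifier seeds.
"""

from __future__ import annotations

import numpy as np

from .data import SplitDataset
from .divergences import as_probability_vector
from .elicitation import (
    AFEConfig,
    DivergenceSelection,
    EmptyPoolError,
    ModelPair,
    get_top_n,
)
from .models import ProbabilisticClassifier

__all__ = [
    "entropy",
    "select_random",
    "select_uncertain_observed",
    "select_uncertain_imputed",
    "mode_impute",
    "RandomSelection",
    "UncertaintyObserved",
    "UncertaintyImputed",
    "get_strategy",
    "STRATEGY_NAMES",
]

STRATEGY_NAMES = ("afe", "rnd", "us_obs", "us_all")


def entropy(p) -> float:
    """Shannon entropy -sum p log p in nats, with the 0 log 0 = 0 convention."""
    p = as_probability_vector(p)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def select_random(e_u, n: int, rng_seed) -> list[int]:
    """Uniform sample of min(n, |E_u|) indices without replacement."""
    e_u = np.asarray(e_u, dtype=int)
    if e_u.size == 0:
        raise EmptyPoolError("E_u is empty")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    return [int(i) for i in rng.choice(e_u, size=min(n, e_u.size), replace=False)]


def select_uncertain_observed(
    dataset: SplitDataset, m_u: ProbabilisticClassifier, n: int
) -> list[int]:
    """Top-n of E_u by entropy of M_u's posterior (observed features only)."""
    if dataset.e_u.size == 0:
        raise EmptyPoolError("E_u is empty")
    probs = m_u.predict_proba(dataset.observed[dataset.e_u])
    scores = {int(i): entropy(p) for i, p in zip(dataset.e_u, probs)}
    return get_top_n(scores, n)


def mode_impute(dataset: SplitDataset, *, sig_digits: int = 6) -> np.ndarray:
    """Per-column mode of E_o's elicitable values; ties go to the smallest.

    A mode is only well defined for discrete values, so continuous
    columns are first rounded to ``sig_digits`` significant digits.
    """
    if dataset.e_o.size == 0:
        raise EmptyPoolError("E_o is empty")
    block = dataset.elicitable[dataset.e_o]
    out = np.empty(dataset.d_u)
    for j in range(dataset.d_u):
        col = block[:, j]
        with np.errstate(divide="ignore", invalid="ignore"):
            mags = np.where(col == 0, 1.0, 10.0 ** np.floor(np.log10(np.abs(col))))
        rounded = np.round(col / mags, sig_digits - 1) * mags
        values, counts = np.unique(rounded, return_counts=True)
        out[j] = values[counts == counts.max()].min()
    return out


def select_uncertain_imputed(
    dataset: SplitDataset,
    m_o: ProbabilisticClassifier,
    imputed: np.ndarray,
    n: int,
) -> list[int]:
    """Top-n of E_u by entropy of M_o's posterior on [observed_i, imputed]."""
    if dataset.e_u.size == 0:
        raise EmptyPoolError("E_u is empty")
    X = np.hstack(
        [dataset.observed[dataset.e_u], np.tile(imputed, (dataset.e_u.size, 1))]
    )
    probs = m_o.predict_proba(X)
    scores = {int(i): entropy(p) for i, p in zip(dataset.e_u, probs)}
    return get_top_n(scores, n)


class RandomSelection:
    """RND baseline: seeded uniform batches."""

    name = "rnd"

    def select(self, dataset, model_pair: ModelPair, n, config: AFEConfig, iteration):
        seed = [int(config.seed) & 0x7FFFFFFF, 1000 + iteration]
        return select_random(dataset.e_u, n, seed), None


class UncertaintyObserved:
    """USObs baseline: entropy under the observed-features model."""

    name = "us_obs"

    def select(self, dataset, model_pair: ModelPair, n, config, iteration):
        return select_uncertain_observed(dataset, model_pair.m_u, n), None


class UncertaintyImputed:
    """USAll baseline: entropy under M_o with mode-imputed elicitable features.

    The imputation vector is recomputed each iteration from the current
    E_o; the scoring model is the loop's M_o, not a separate refit on
    imputed data.
    """

    name = "us_all"

    def select(self, dataset, model_pair: ModelPair, n, config, iteration):
        imputed = mode_impute(dataset)
        return select_uncertain_imputed(dataset, model_pair.m_o, imputed, n), None


_STRATEGIES = {
    "afe": DivergenceSelection,
    "rnd": RandomSelection,
    "us_obs": UncertaintyObserved,
    "us_all": UncertaintyImputed,
}


def get_strategy(name: str):
    try:
        return _STRATEGIES[name]()
    except KeyError:
        raise ValueError(
            f"unknown strategy {name!r}; expected one of {STRATEGY_NAMES}"
        ) from None
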