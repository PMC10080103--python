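"""The active feature elicitation loop.

Given a cohort split into a fully observed pool ``E_o`` and a partially
observed pool ``E_u`` (labels known for all), the loop repeatedly

1. scores every i in E_u by the *mean divergence* of the cheap-feature
   model's posterior at i from the full-feature model's posteriors over
   E_o:  MD_i = (1/|E_o|) * sum_j Div( P_Mu(Y|x_o^i) || P_Mo(Y|x_o^j, x_u^j) ),
2. selects the top-n most divergent examples,
3. queries the feature oracle for their elicitable features and moves
   them into E_o,
4. retrains the full-feature model M_o on the grown E_o (the
   cheap-feature model M_u is trained once, up front, on everyone's
   observed features and never refit),
5. stops when the change in M_o's train mean log-likelihood falls below
   a tolerance, or the batch budget / pool is exhausted.

The divergence direction is fixed: the partially observed example's
posterior is the first argument. With asymmetric divergences (KL,
chi-square) swapping the arguments changes the selection, so the order
is part of the method, not a convention.

API shape: :class:`ActiveFeatureElicitation` is the model object (data +
configuration); ``fit()`` runs the loop and returns
:class:`ElicitationResults` carrying the final classifier, the
per-iteration trace and a ``summary()``. :func:`run_afe` is the
equivalent one-call functional entry point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from . import evaluation
from .data import (
    ArrayFeatureOracle,
    FeatureOracle,
    PoolMembershipError,
    SplitDataset,
    TestSet,
)
from .divergences import DivergenceSpec, get_divergence, pairwise_divergence_matrix
from .models import (
    ClassifierSpec,
    ProbabilisticClassifier,
    mean_log_likelihood,
    train_full_model,
    train_observed_model,
)

__all__ = [
    "AFEConfig",
    "ModelPair",
    "ElicitationTrace",
    "IterationRecord",
    "ActiveFeatureElicitation",
    "ElicitationResults",
    "run_afe",
    "pairwise_divergence",
    "mean_divergence",
    "score_unobserved",
    "get_top_n",
    "acquire",
    "update_batch_size",
    "has_converged",
    "EmptyPoolError",
]


class EmptyPoolError(ValueError):
    """An operation needed a non-empty E_o or E_u."""


@dataclass(frozen=True)
class ModelPair:
    """The two classifiers of the loop: frozen M_u and current M_o."""

    m_u: ProbabilisticClassifier  # observed features, all examples; never refit
    m_o: ProbabilisticClassifier  # full features, current E_o; refit each iteration


@dataclass(frozen=True)
class AFEConfig:
    """Loop configuration.

    ``schedule='fixed'`` keeps the batch size constant (the protocol of
    repeated 5-example batches); ``'literal'`` applies the shrinking
    update n <- n/(n+delta), under which the loop terminates as soon as
    n drops below 1. ``budget`` caps the total number of examples
    acquired (each acquisition elicits all d_u features). ``epsilon`` is
    the convergence tolerance on the change in M_o's train mean
    log-likelihood between successive iterations (nats per example);
    ``None`` disables the likelihood stop — appropriate for classifiers
    expressive enough to saturate their training likelihood immediately,
    where only the batch budget and pool exhaustion are meaningful.
    """

    batch_size: int = 5
    delta: float = 1.0
    epsilon: float | None = 1e-3
    schedule: str = "fixed"
    max_iterations: int = 100
    budget: int | None = None
    divergence: DivergenceSpec = field(default_factory=DivergenceSpec)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    strategy: str = "afe"
    positive_class: object | None = None  # metrics target; None -> minority class
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("epsilon must be positive (or None to disable)")
        if self.schedule not in ("fixed", "literal"):
            raise ValueError("schedule must be 'fixed' or 'literal'")
        if self.budget is not None and self.budget < self.batch_size:
            raise ValueError("budget must be at least one batch")


@dataclass(frozen=True)
class IterationRecord:
    iteration: int
    selected: tuple[int, ...]
    n_observed: int
    n_unobserved: int
    train_ll: float
    recall: float
    f1: float
    gmean: float
    scores: dict[int, float] | None = None  # divergence snapshot over E_u


@dataclass
class ElicitationTrace:
    """Per-iteration log of the acquisition loop."""

    records: list[IterationRecord] = field(default_factory=list)

    def append(self, record: IterationRecord) -> None:
        if self.records:
            prev = self.records[-1]
            if record.n_observed <= prev.n_observed:
                raise ValueError("|E_o| must grow strictly between iterations")
            seen = {i for r in self.records for i in r.selected}
            if seen & set(record.selected):
                raise ValueError("an example was selected twice across iterations")
        self.records.append(record)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def train_lls(self) -> list[float]:
        return [r.train_ll for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": [r.iteration for r in self.records],
                "selected_indices": [
                    ";".join(str(i) for i in r.selected) for r in self.records
                ],
                "n_observed": [r.n_observed for r in self.records],
                "train_ll": [r.train_ll for r in self.records],
                "recall": [r.recall for r in self.records],
                "f1": [r.f1 for r in self.records],
                "gmean": [r.gmean for r in self.records],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# scoring primitives


def pairwise_divergence(
    i: int,
    j: int,
    dataset: SplitDataset,
    model_pair: ModelPair,
    spec: DivergenceSpec,
) -> float:
    """D_ij = Div(M_u posterior at i in E_u || M_o posterior at j in E_o)."""
    if i not in dataset.e_u:
        raise PoolMembershipError(f"index {i} is not in E_u")
    if j not in dataset.e_o:
        raise PoolMembershipError(f"index {j} is not in E_o")
    p = model_pair.m_u.predict_proba(dataset.observed[[i]])[0]
    q = model_pair.m_o.predict_proba(dataset.full_features([j]))[0]
    return get_divergence(spec.name)(p, q, clamp_eps=spec.clamp_eps)


def mean_divergence(
    i: int,
    dataset: SplitDataset,
    model_pair: ModelPair,
    spec: DivergenceSpec,
) -> float:
    """MD_i: mean of D_ij over all j currently in E_o."""
    if dataset.e_o.size == 0:
        raise EmptyPoolError("E_o is empty")
    return float(
        np.mean([pairwise_divergence(i, j, dataset, model_pair, spec) for j in dataset.e_o])
    )


def score_unobserved(
    dataset: SplitDataset, model_pair: ModelPair, spec: DivergenceSpec
) -> dict[int, float]:
    """Mean-divergence score for every example still in E_u.

    Posteriors are computed once per example (one batched predict per
    model), then the |E_u| x |E_o| divergence grid is evaluated in a
    single vectorised pass.
    """
    if dataset.e_u.size == 0:
        raise EmptyPoolError("E_u is empty")
    if dataset.e_o.size == 0:
        raise EmptyPoolError("E_o is empty")
    P = model_pair.m_u.predict_proba(dataset.observed[dataset.e_u])
    Q = model_pair.m_o.predict_proba(dataset.full_features(dataset.e_o))
    grid = pairwise_divergence_matrix(P, Q, spec)
    scores = grid.mean(axis=1)
    if not np.all(np.isfinite(scores)):
        raise FloatingPointError(f"non-finite {spec.name} divergence scores")
    return {int(i): float(s) for i, s in zip(dataset.e_u, scores)}


def get_top_n(scores: Mapping[int, float], n: int) -> list[int]:
    """Indices of the min(n, |scores|) largest scores.

    Ordered by non-increasing score; exact ties broken by ascending
    example index so selection is deterministic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not scores:
        raise EmptyPoolError("no scores to select from")
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [i for i, _ in ranked[: min(n, len(ranked))]]


def acquire(dataset: SplitDataset, indices: Sequence[int], oracle: FeatureOracle) -> SplitDataset:
    """Query the oracle for ``indices`` and move them from E_u to E_o."""
    idx = np.asarray(list(indices), dtype=int)
    if idx.size == 0:
        return dataset
    values = oracle.query_many(idx)
    return dataset.with_acquired(idx, values)


def update_batch_size(n: float, delta: float, schedule: str) -> float:
    """Next batch size: unchanged under 'fixed'; n/(n+delta) under 'literal'."""
    if schedule == "fixed":
        return n
    if schedule == "literal":
        return n / (n + delta)
    raise ValueError("schedule must be 'fixed' or 'literal'")


def has_converged(trace: ElicitationTrace, epsilon: float | None) -> bool:
    """True when the pool is exhausted or the train LL has stabilised.

    The likelihood criterion compares the last two recorded train mean
    log-likelihoods; with fewer than two records it cannot fire, and
    ``epsilon=None`` disables it entirely.
    """
    if len(trace) == 0:
        return False
    if trace.records[-1].n_unobserved == 0:
        return True
    if epsilon is None or len(trace) < 2:
        return False
    lls = trace.train_lls
    return abs(lls[-1] - lls[-2]) < epsilon


# ---------------------------------------------------------------------------
# strategy contract


class SelectionStrategy(Protocol):
    """Pluggable batch selector over the current E_u."""

    name: str

    def select(
        self,
        dataset: SplitDataset,
        model_pair: ModelPair,
        n: int,
        config: AFEConfig,
        iteration: int,
    ) -> tuple[list[int], dict[int, float] | None]:
        """Return (selected indices, optional score snapshot)."""
        ...  # pragma: no cover


class DivergenceSelection:
    """The AFE selector: top-n by mean divergence from the observed pool."""

    name = "afe"

    def select(self, dataset, model_pair, n, config, iteration):
        scores = score_unobserved(dataset, model_pair, config.divergence)
        return get_top_n(scores, n), scores


def _resolve_strategy(name_or_strategy) -> SelectionStrategy:
    if hasattr(name_or_strategy, "select"):
        return name_or_strategy
    if name_or_strategy == "afe":
        return DivergenceSelection()
    from .baselines import get_strategy  # deferred: baselines imports this module

    return get_strategy(name_or_strategy)


# ---------------------------------------------------------------------------
# model / results objects


class ActiveFeatureElicitation:
    """Model object: a cohort, an oracle, and an acquisition configuration.

    Parameters
    ----------
    dataset
        The training cohort with its E_o / E_u split.
    oracle
        Source answering feature queries for E_u rows.
    config
        Loop settings (batch size, divergence, classifier, stopping rule).
    test_set
        Optional held-out examples with full features; per-iteration
        recall/F1/gmean are evaluated here when given.
    strategy
        Selector name (``afe``, ``rnd``, ``us_obs``, ``us_all``) or a
        custom object; overrides ``config.strategy``.
    """

    def __init__(
        self,
        dataset: SplitDataset,
        oracle: FeatureOracle,
        config: AFEConfig | None = None,
        test_set: TestSet | None = None,
        strategy: str | SelectionStrategy | None = None,
    ):
        self.dataset = dataset
        self.oracle = oracle
        self.config = config or AFEConfig()
        self.test_set = test_set
        self.strategy = _resolve_strategy(
            strategy if strategy is not None else self.config.strategy
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        *,
        label_col: str,
        observed_cols: Sequence[str],
        elicitable_cols: Sequence[str],
        initial_fo: Sequence[int],
        config: AFEConfig | None = None,
        test_set: TestSet | None = None,
    ) -> "ActiveFeatureElicitation":
        """Build from a complete cohort frame; hidden elicitable rows back the oracle."""
        X_o = df[list(observed_cols)].to_numpy(dtype=float)
        X_u = df[list(elicitable_cols)].to_numpy(dtype=float)
        y = df[label_col].to_numpy()
        fo = np.asarray(initial_fo, dtype=int)
        po = np.setdiff1d(np.arange(len(df)), fo)
        masked = np.full_like(X_u, np.nan)
        masked[fo] = X_u[fo]
        dataset = SplitDataset(X_o, masked, y, fo, po)
        return cls(dataset, ArrayFeatureOracle(X_u), config=config, test_set=test_set)

    def _positive_class(self):
        if self.config.positive_class is not None:
            return self.config.positive_class
        labels, counts = np.unique(self.dataset.labels, return_counts=True)
        return labels[np.argmin(counts)]  # rare class is the clinical target

    def _test_metrics(self, m_o: ProbabilisticClassifier) -> tuple[float, float, float]:
        if self.test_set is None or len(self.test_set) == 0:
            return (float("nan"),) * 3
        pred = m_o.predict(self.test_set.full)
        counts = evaluation.confusion(pred, self.test_set.labels, self._positive_class())
        return evaluation.metrics(counts)

    def fit(self) -> "ElicitationResults":
        """Run the acquisition loop and return the results object."""
        cfg = self.config
        dataset = self.dataset
        m_u = train_observed_model(dataset, cfg.classifier, seed=cfg.seed)
        m_o = train_full_model(dataset, cfg.classifier, seed=cfg.seed)
        trace = ElicitationTrace()
        n = float(cfg.batch_size)
        acquired_total = 0
        t = 0
        while t < cfg.max_iterations and n >= 1 and dataset.e_u.size > 0:
            if cfg.budget is not None and acquired_total >= cfg.budget:
                break
            batch = int(n)
            batch = min(batch, dataset.e_u.size)
            if cfg.budget is not None:
                batch = min(batch, cfg.budget - acquired_total)
            pair = ModelPair(m_u=m_u, m_o=m_o)
            selected, scores = self.strategy.select(dataset, pair, batch, cfg, t)
            dataset = acquire(dataset, selected, self.oracle)
            acquired_total += len(selected)
            m_o = train_full_model(dataset, cfg.classifier, seed=cfg.seed)
            ll = mean_log_likelihood(
                m_o, dataset.full_features(dataset.e_o), dataset.labels[dataset.e_o]
            )
            recall, f1, gmean = self._test_metrics(m_o)
            trace.append(
                IterationRecord(
                    iteration=t,
                    selected=tuple(int(i) for i in selected),
                    n_observed=int(dataset.e_o.size),
                    n_unobserved=int(dataset.e_u.size),
                    train_ll=ll,
                    recall=recall,
                    f1=f1,
                    gmean=gmean,
                    scores=scores,
                )
            )
            if has_converged(trace, cfg.epsilon):
                break
            n = update_batch_size(n, cfg.delta, cfg.schedule)
            t += 1
        final_model = train_full_model(dataset, cfg.classifier, seed=cfg.seed)
        return ElicitationResults(
            model=self,
            final_dataset=dataset,
            final_model=final_model,
            observed_model=m_u,
            trace=trace,
        )


@dataclass
class ElicitationResults:
    """Outcome of one elicitation run.

    Carries the terminal cohort state, the final full-feature classifier
    (trained on the terminal E_o), the frozen observed-features model and
    the per-iteration trace; ``summary()`` renders the run as text.
    """

    model: ActiveFeatureElicitation
    final_dataset: SplitDataset
    final_model: ProbabilisticClassifier
    observed_model: ProbabilisticClassifier
    trace: ElicitationTrace

    @property
    def n_iterations(self) -> int:
        return len(self.trace)

    @property
    def n_acquired(self) -> int:
        return int(self.final_dataset.e_o.size - self.model.dataset.e_o.size)

    def final_metrics(self) -> tuple[float, float, float]:
        return self.model._test_metrics(self.final_model)

    def summary(self) -> str:
        cfg = self.model.config
        recall, f1, gmean = self.final_metrics()
        lines = [
            "Active Feature Elicitation Results",
            "=" * 44,
            f"{'strategy':<24}{self.model.strategy.name}",
            f"{'classifier':<24}{cfg.classifier.family}",
            f"{'divergence':<24}{cfg.divergence.name}",
            f"{'batch size':<24}{cfg.batch_size}",
            f"{'iterations run':<24}{self.n_iterations}",
            f"{'examples acquired':<24}{self.n_acquired}",
            f"{'|E_o| initial -> final':<24}"
            f"{self.model.dataset.e_o.size} -> {self.final_dataset.e_o.size}",
            f"{'final train LL/ex':<24}"
            + (f"{self.trace.train_lls[-1]:.4f}" if len(self.trace) else "n/a"),
            f"{'test recall':<24}{recall:.4f}",
            f"{'test F1':<24}{f1:.4f}",
            f"{'test gmean':<24}{gmean:.4f}",
        ]
        return "\n".join(lines)


def run_afe(
    dataset: SplitDataset,
    oracle: FeatureOracle,
    config: AFEConfig,
    test_set: TestSet | None = None,
    strategy: str | SelectionStrategy | None = None,
) -> tuple[ProbabilisticClassifier, ElicitationTrace]:
    """Functional entry point: run the loop, return (final model, trace)."""
    results = ActiveFeatureElicitation(
        dataset, oracle, config=config, test_set=test_set, strategy=strategy
    ).fit()
    return results.final_model, results.trace
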