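"""Cohort containers, the feature oracle, and data sources.

The elicitation setting splits a cohort's columns into *observed*
features (cheap: demographics, a single screening score) available for
everyone, and *elicitable* features (labs, imaging, questionnaires)
known only for a small fully observed pool ``E_o``; labels are known for
all rows. :class:`SplitDataset` holds that state, a
:class:`FeatureOracle` answers acquisition queries for rows still in the
partially observed pool ``E_u``, and two sources build the pair:

* :func:`generate` — a seeded class-conditional Gaussian cohort that
  emulates the study shape (class-imbalanced labels, a handful of weakly
  informative observed features, strongly informative elicitable
  features, a tiny initial ``E_o``, a large ``E_u``, a held-out test set
  with full features);
* :func:`load_csv` — a loader for tabular cohorts such as the
  PIMA-style 4 observed / 4 elicitable diabetes table, where the hidden
  elicitable columns of ``E_u`` rows back the oracle.

The Gaussian generator is deliberately simple: class-conditional means
shifted by a configurable effect size (in units of the noise SD) make
Bayes-optimal posteriors available in closed form for stub-model tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SplitDataset",
    "TestSet",
    "FeatureOracle",
    "ArrayFeatureOracle",
    "SyntheticSpec",
    "CohortConfig",
    "generate",
    "load_csv",
    "write_cohort_csv",
    "PoolMembershipError",
    "SchemaError",
    "IntegrityError",
]


class PoolMembershipError(ValueError):
    """An index was used against the wrong pool (E_o vs E_u)."""


class SchemaError(ValueError):
    """A declared column is missing from the CSV."""


class IntegrityError(ValueError):
    """Missing values where the contract requires complete data."""


@dataclass(frozen=True)
class TestSet:
    """Held-out examples with the complete feature set available."""

    observed: np.ndarray
    elicitable: np.ndarray
    labels: np.ndarray

    @property
    def full(self) -> np.ndarray:
        return np.hstack([self.observed, self.elicitable])

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class SplitDataset:
    """Training cohort with observed/elicitable feature split.

    ``elicitable`` rows are NaN-masked outside ``e_o``. ``e_o`` and
    ``e_u`` are disjoint sorted integer index arrays partitioning
    ``range(n)``.
    """

    observed: np.ndarray  # (N, d_o)
    elicitable: np.ndarray  # (N, d_u); NaN outside e_o
    labels: np.ndarray  # (N,)
    e_o: np.ndarray  # sorted indices, fully observed
    e_u: np.ndarray  # sorted indices, partially observed

    def __post_init__(self) -> None:
        object.__setattr__(self, "e_o", np.sort(np.asarray(self.e_o, dtype=int)))
        object.__setattr__(self, "e_u", np.sort(np.asarray(self.e_u, dtype=int)))
        self.validate()

    def validate(self) -> None:
        n = self.observed.shape[0]
        if self.elicitable.shape[0] != n or self.labels.shape[0] != n:
            raise IntegrityError("observed/elicitable/labels row counts differ")
        both = np.concatenate([self.e_o, self.e_u])
        if np.intersect1d(self.e_o, self.e_u).size:
            raise IntegrityError("E_o and E_u overlap")
        if not np.array_equal(np.sort(both), np.arange(n)):
            raise IntegrityError("E_o and E_u do not partition the row set")
        if self.e_o.size and np.isnan(self.elicitable[self.e_o]).any():
            raise IntegrityError("E_o rows have missing elicitable values")
        if self.e_u.size and not np.isnan(self.elicitable[self.e_u]).all():
            raise IntegrityError("E_u rows carry elicitable values they should not")

    @property
    def n(self) -> int:
        return self.observed.shape[0]

    @property
    def d_o(self) -> int:
        return self.observed.shape[1]

    @property
    def d_u(self) -> int:
        return self.elicitable.shape[1]

    def full_features(self, indices) -> np.ndarray:
        idx = np.asarray(indices, dtype=int)
        return np.hstack([self.observed[idx], self.elicitable[idx]])

    def with_acquired(self, indices, values: np.ndarray) -> "SplitDataset":
        """Return a copy with ``indices`` moved E_u -> E_o, elicitable rows filled."""
        idx = np.asarray(indices, dtype=int)
        if idx.size and not np.isin(idx, self.e_u).all():
            raise PoolMembershipError("acquired indices must currently lie in E_u")
        if np.unique(idx).size != idx.size:
            raise PoolMembershipError("duplicate indices in acquisition batch")
        elic = self.elicitable.copy()
        elic[idx] = values
        return replace(
            self,
            elicitable=elic,
            e_o=np.concatenate([self.e_o, idx]),
            e_u=np.setdiff1d(self.e_u, idx),
        )


class FeatureOracle:
    """Source of elicitable feature vectors; query(i) is idempotent."""

    def query(self, i: int) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def query_many(self, indices) -> np.ndarray:
        return np.vstack([self.query(int(i)) for i in indices])


class ArrayFeatureOracle(FeatureOracle):
    """Oracle backed by a hidden ground-truth elicitable matrix."""

    def __init__(self, hidden: np.ndarray):
        self._hidden = np.asarray(hidden, dtype=float)

    def query(self, i: int) -> np.ndarray:
        row = self._hidden[i]
        if np.isnan(row).any():
            raise IntegrityError(f"oracle has no elicitable values for row {i}")
        return row.copy()


@dataclass(frozen=True)
class SyntheticSpec:
    """Generating parameters for a synthetic partially observed cohort.

    Effect sizes are class-mean shifts in units of the feature noise SD;
    the defaults describe the regime of interest — a rare positive class
    (a quarter of subjects), observed features that are only weakly
    informative (0.3 SD shift) and elicitable features that carry most of
    the signal (2 SD shift), a PIMA-like 4 + 4 column split, ten initially
    fully observed subjects, and a 20% held-out test set.
    """

    n_examples: int = 500
    positive_rate: float = 0.25
    d_o: int = 4
    d_u: int = 4
    effect_obs: float = 0.3
    effect_elic: float = 2.0
    noise_sd: float = 1.0
    n_initial_fo: int = 10
    test_fraction: float = 0.2
    seed: int = 0
    test_seed: int | None = None  # defaults to seed: same spec, same test set
    stratify_initial: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.positive_rate < 1.0):
            raise ValueError("positive_rate must lie in (0, 1)")
        if self.d_o < 1 or self.d_u < 1:
            raise ValueError("d_o and d_u must be >= 1")
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must lie in (0, 1)")
        n_train = int(round(self.n_examples * (1.0 - self.test_fraction)))
        if not (0 < self.n_initial_fo < n_train):
            raise ValueError("n_initial_fo must be positive and smaller than the train pool")


def _stratified_indices(labels: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Sample k row positions containing every class present, where possible."""
    classes, counts = np.unique(labels, return_counts=True)
    if k < classes.size:
        # cannot cover all classes; fall back to a plain draw
        return rng.choice(len(labels), size=k, replace=False)
    take = np.maximum(1, np.floor(k * counts / counts.sum()).astype(int))
    while take.sum() > k:
        take[np.argmax(take)] -= 1
    while take.sum() < k:
        take[np.argmax(counts - take)] += 1
    picked = []
    for cls, t in zip(classes, take):
        pool = np.flatnonzero(labels == cls)
        picked.append(rng.choice(pool, size=min(t, pool.size), replace=False))
    return np.sort(np.concatenate(picked))


def generate(
    spec: SyntheticSpec, init_seed: int | None = None
) -> tuple[SplitDataset, ArrayFeatureOracle, TestSet]:
    """Draw a cohort, split off a fixed test set, and mask the E_u rows.

    The cohort (labels, features) and the test split depend only on
    ``spec.seed`` / ``spec.test_seed``, so repeated runs share one fixed
    test set; ``init_seed`` controls only which train rows start fully
    observed, the per-run source of sampling variation.
    """
    rng = np.random.default_rng(spec.seed)
    y = (rng.random(spec.n_examples) < spec.positive_rate).astype(int)
    shift_o = spec.effect_obs * spec.noise_sd
    shift_u = spec.effect_elic * spec.noise_sd
    X_o = rng.normal(0.0, spec.noise_sd, size=(spec.n_examples, spec.d_o)) + shift_o * y[:, None]
    X_u = rng.normal(0.0, spec.noise_sd, size=(spec.n_examples, spec.d_u)) + shift_u * y[:, None]

    test_seed = spec.seed if spec.test_seed is None else spec.test_seed
    n_test = int(round(spec.n_examples * spec.test_fraction))
    test_rng = np.random.default_rng(test_seed)
    test_idx = _stratified_indices(y, n_test, test_rng)
    train_idx = np.setdiff1d(np.arange(spec.n_examples), test_idx)

    test = TestSet(X_o[test_idx], X_u[test_idx], y[test_idx])

    y_tr, Xo_tr, Xu_tr = y[train_idx], X_o[train_idx], X_u[train_idx]
    init_rng = np.random.default_rng(spec.seed + 1 if init_seed is None else init_seed)
    if spec.stratify_initial:
        fo = _stratified_indices(y_tr, spec.n_initial_fo, init_rng)
    else:
        fo = np.sort(init_rng.choice(len(y_tr), size=spec.n_initial_fo, replace=False))
    po = np.setdiff1d(np.arange(len(y_tr)), fo)

    masked = np.full_like(Xu_tr, np.nan)
    masked[fo] = Xu_tr[fo]
    dataset = SplitDataset(Xo_tr, masked, y_tr, fo, po)
    oracle = ArrayFeatureOracle(Xu_tr)
    return dataset, oracle, test


@dataclass(frozen=True)
class CohortConfig:
    """Column roles and split settings for a cohort CSV."""

    label_col: str
    observed_cols: Sequence[str]
    elicitable_cols: Sequence[str]
    n_initial_fo: int = 10
    fully_observed_col: str | None = None  # 0/1 indicator overrides n_initial_fo
    initial_fo_indices: Sequence[int] | None = None
    test_fraction: float = 0.2
    split_seed: int = 0
    stratify_initial: bool = True

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "CohortConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in cfg.items() if k in known})


def load_csv(
    path, config: CohortConfig, init_seed: int | None = None
) -> tuple[SplitDataset, ArrayFeatureOracle, TestSet]:
    """Load a cohort CSV and split it into (train SplitDataset, oracle, test).

    The CSV must carry complete observed columns and labels; its
    elicitable columns serve two roles — known values for the initial
    E_o rows, and the hidden ground truth behind the oracle for E_u
    rows. The test split is fixed by ``config.split_seed``; ``init_seed``
    varies only the initial E_o draw.
    """
    df = pd.read_csv(path)
    wanted = [config.label_col, *config.observed_cols, *config.elicitable_cols]
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise SchemaError(f"columns missing from {path}: {missing}")
    if df[[config.label_col, *config.observed_cols]].isna().any().any():
        raise IntegrityError("missing values in label or observed columns")
    if df[list(config.elicitable_cols)].isna().any().any():
        raise IntegrityError("elicitable columns must be complete to back the oracle")

    y = df[config.label_col].to_numpy()
    X_o = df[list(config.observed_cols)].to_numpy(dtype=float)
    X_u = df[list(config.elicitable_cols)].to_numpy(dtype=float)
    n = len(df)

    test_rng = np.random.default_rng(config.split_seed)
    n_test = int(round(n * config.test_fraction))
    test_idx = _stratified_indices(y, n_test, test_rng) if n_test else np.array([], dtype=int)
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    test = TestSet(X_o[test_idx], X_u[test_idx], y[test_idx])

    y_tr, Xo_tr, Xu_tr = y[train_idx], X_o[train_idx], X_u[train_idx]
    if config.fully_observed_col is not None:
        if config.fully_observed_col not in df.columns:
            raise SchemaError(f"indicator column {config.fully_observed_col!r} missing")
        fo = np.flatnonzero(df[config.fully_observed_col].to_numpy()[train_idx] == 1)
    elif config.initial_fo_indices is not None:
        fo = np.asarray(config.initial_fo_indices, dtype=int)
    else:
        init_rng = np.random.default_rng(
            config.split_seed + 1 if init_seed is None else init_seed
        )
        if config.stratify_initial:
            fo = _stratified_indices(y_tr, config.n_initial_fo, init_rng)
        else:
            fo = np.sort(init_rng.choice(len(y_tr), size=config.n_initial_fo, replace=False))
    po = np.setdiff1d(np.arange(len(y_tr)), fo)

    masked = np.full_like(Xu_tr, np.nan)
    masked[fo] = Xu_tr[fo]
    dataset = SplitDataset(Xo_tr, masked, y_tr, fo, po)
    return dataset, ArrayFeatureOracle(Xu_tr), test


def write_cohort_csv(spec: SyntheticSpec, out_path) -> Path:
    """Materialise a synthetic cohort as CSV plus a sidecar parameter JSON.

    Columns: ``obs_1..obs_{d_o}``, ``elic_1..elic_{d_u}``, ``label``. The
    sidecar records the generating parameters and seed so the cohort can
    be reproduced or reloaded with :func:`load_csv`.
    """
    out_path = Path(out_path)
    rng = np.random.default_rng(spec.seed)
    y = (rng.random(spec.n_examples) < spec.positive_rate).astype(int)
    X_o = rng.normal(0.0, spec.noise_sd, size=(spec.n_examples, spec.d_o)) \
        + spec.effect_obs * spec.noise_sd * y[:, None]
    X_u = rng.normal(0.0, spec.noise_sd, size=(spec.n_examples, spec.d_u)) \
        + spec.effect_elic * spec.noise_sd * y[:, None]
    cols = {f"obs_{j + 1}": X_o[:, j] for j in range(spec.d_o)}
    cols.update({f"elic_{j + 1}": X_u[:, j] for j in range(spec.d_u)})
    cols["label"] = y
    pd.DataFrame(cols).to_csv(out_path, index=False)
    sidecar = out_path.with_suffix(out_path.suffix + ".json")
    sidecar.write_text(json.dumps(spec.__dict__, indent=2, default=str))
    return out_path
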