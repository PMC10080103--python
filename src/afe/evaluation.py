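"""Metrics, multi-run aggregation, rank comparison, and the experiment harness.

Class imbalance drives every choice here: the metrics are recall
(clinical sensitivity), F1, and the geometric mean of sensitivity and
specificity; all three return 0 under the 0/0 degenerate cases, a
deliberately conservative convention applied uniformly to every
strategy. Method comparison uses average ranks with a 3% relative tie
band: methods within 3% of the running group leader's value share the
group's best rank.

:func:`run_experiment` executes a (strategy x classifier x divergence)
grid of seeded elicitation runs against one fixed test set and writes
per-run trace CSVs, a summary table, and a rank table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .divergences import DivergenceSpec
from .models import ClassifierSpec

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "confusion",
    "metrics",
    "RunSummary",
    "aggregate_runs",
    "average_rank",
    "ExperimentConfig",
    "run_experiment",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(predicted, true, positive_class) -> ConfusionCounts:
    """Confusion counts with respect to the declared positive class."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError("predicted and true label vectors differ in length")
    pos_pred = predicted == positive_class
    pos_true = true == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos_pred & pos_true)),
        fp=int(np.sum(pos_pred & ~pos_true)),
        tn=int(np.sum(~pos_pred & ~pos_true)),
        fn=int(np.sum(~pos_pred & pos_true)),
    )


def metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(recall, F1, gmean) from confusion counts; 0/0 cases return 0.

    recall = TP/(TP+FN); F1 = 2*prec*rec/(prec+rec);
    gmean = sqrt(sensitivity * specificity).
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    )
    specificity = tn / (tn + fp) if (tn + fp) else 0.0
    gmean = float(np.sqrt(recall * specificity))
    return float(recall), float(f1), float(gmean)


@dataclass
class RunSummary:
    """Per-iteration mean +/- sample SD of each metric across seeded runs."""

    strategy: str
    classifier: str
    divergence: str
    n_runs: int
    table: pd.DataFrame  # iteration x {metric}_mean / {metric}_sd

    def final_mean(self, metric: str) -> float:
        return float(self.table[f"{metric}_mean"].iloc[-1])


_METRICS = ("recall", "f1", "gmean")


def aggregate_runs(
    traces: Sequence, *, strategy: str = "", classifier: str = "", divergence: str = ""
) -> RunSummary:
    """Aggregate elicitation traces over runs.

    Traces of unequal length are truncated to the common prefix (with a
    warning); the mean and sample standard deviation (ddof=1, zero for a
    single run) are reported per iteration and metric.
    """
    if not traces:
        raise ValueError("no traces to aggregate")
    lengths = [len(t) for t in traces]
    t_min = min(lengths)
    if len(set(lengths)) > 1:
        logger.warning(
            "traces have unequal lengths %s; aggregating the common prefix of %d",
            lengths,
            t_min,
        )
    rows = {}
    rows["iteration"] = np.arange(t_min)
    for m in _METRICS + ("train_ll",):
        vals = np.array(
            [[getattr(t.records[i], m) for i in range(t_min)] for t in traces]
        )
        rows[f"{m}_mean"] = vals.mean(axis=0)
        rows[f"{m}_sd"] = vals.std(axis=0, ddof=1) if len(traces) > 1 else np.zeros(t_min)
    return RunSummary(
        strategy=strategy,
        classifier=classifier,
        divergence=divergence,
        n_runs=len(traces),
        table=pd.DataFrame(rows),
    )


def average_rank(
    performance: Mapping[str, Mapping[str, float]], tolerance: float = 0.03
) -> dict[str, float]:
    """Mean rank of each method across datasets, with a relative tie band.

    ``performance[method][dataset]`` is a higher-is-better metric value.
    Per dataset, methods are sorted best-first; a method joins the
    current tie group when its value is within ``tolerance`` (relative
    to the group leader's value) of the leader, and every member of a
    group shares the group's best (minimum) rank. ``tolerance=0``
    reduces to standard competition ranking. Lower mean rank is better.
    """
    methods = sorted(performance)
    datasets = None
    for m in methods:
        ds = set(performance[m])
        if datasets is None:
            datasets = ds
        elif ds != datasets:
            raise ValueError("methods report inconsistent dataset sets")
    assert datasets is not None
    totals = {m: 0.0 for m in methods}
    for d in sorted(datasets):
        ordered = sorted(methods, key=lambda m: (-performance[m][d], m))
        leader_val = None
        group_rank = 1
        for pos, m in enumerate(ordered, start=1):
            v = performance[m][d]
            tied = (
                leader_val is not None
                and (
                    (leader_val > 0 and (leader_val - v) <= tolerance * leader_val)
                    or (leader_val <= 0 and v == leader_val)
                )
            )
            if not tied:
                leader_val = v
                group_rank = pos
            totals[m] += group_rank
    return {m: totals[m] / len(datasets) for m in methods}


# ---------------------------------------------------------------------------
# experiment harness


@dataclass
class ExperimentConfig:
    """Grid of elicitation runs against one cohort and one fixed test set.

    ``data`` is either a :class:`afe.data.SyntheticSpec` or a
    ``(csv_path, CohortConfig)`` pair. Runs differ only in which train
    rows start fully observed (and in any strategy randomness); the
    cohort and test split are fixed by the data seed.
    """

    data: object
    strategies: Sequence[str] = ("afe", "rnd", "us_obs", "us_all")
    classifiers: Sequence[str | ClassifierSpec] = ("gradient_boosting",)
    divergences: Sequence[str] = ("kl",)
    batch_size: int = 5
    delta: float = 1.0
    # expressive learners saturate train likelihood almost at once, which
    # would stop every run after two batches; the grid runs its full
    # iteration budget instead
    epsilon: float | None = None
    schedule: str = "fixed"
    max_iterations: int = 10
    budget: int | None = None
    n_runs: int = 10
    base_seed: int = 0
    out_dir: str | Path = "afe_results"
    rank_metric: str = "recall"
    make_plots: bool = False


def _classifier_spec(c) -> ClassifierSpec:
    return c if isinstance(c, ClassifierSpec) else ClassifierSpec(family=c)


def _load_data(config: ExperimentConfig, init_seed: int):
    from . import data as data_mod

    if isinstance(config.data, data_mod.SyntheticSpec):
        return data_mod.generate(config.data, init_seed=init_seed)
    path, cohort_cfg = config.data
    return data_mod.load_csv(path, cohort_cfg, init_seed=init_seed)


def run_experiment(config: ExperimentConfig) -> dict[tuple[str, str, str], RunSummary]:
    """Execute the full grid; write traces, ``summary.csv`` and ``ranks.csv``.

    Every (strategy, classifier, divergence) combination is run
    ``n_runs`` times with run seeds ``base_seed + r``; all combinations
    in run r share the same initial E_o and the same classifier seed, so
    strategies differ only in which examples they choose.
    """
    from .elicitation import AFEConfig, ActiveFeatureElicitation

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summaries: dict[tuple[str, str, str], RunSummary] = {}
    for cls in config.classifiers:
        cls_spec = _classifier_spec(cls)
        for div_name in config.divergences:
            div_spec = DivergenceSpec(name=div_name)
            for strat in config.strategies:
                traces = []
                for r in range(config.n_runs):
                    run_seed = int(config.base_seed) + r
                    dataset, oracle, test = _load_data(config, init_seed=run_seed)
                    afe_cfg = AFEConfig(
                        batch_size=config.batch_size,
                        delta=config.delta,
                        epsilon=config.epsilon,
                        schedule=config.schedule,
                        max_iterations=config.max_iterations,
                        budget=config.budget,
                        divergence=div_spec,
                        classifier=cls_spec,
                        strategy=strat,
                        seed=run_seed,
                    )
                    res = ActiveFeatureElicitation(
                        dataset, oracle, config=afe_cfg, test_set=test
                    ).fit()
                    traces.append(res.trace)
                    res.trace.to_csv(
                        out_dir
                        / f"trace_{strat}_{cls_spec.family}_{div_name}_run{r}.csv"
                    )
                key = (strat, cls_spec.family, div_name)
                summaries[key] = aggregate_runs(
                    traces,
                    strategy=strat,
                    classifier=cls_spec.family,
                    divergence=div_name,
                )

    frames = []
    for (strat, fam, div), summ in summaries.items():
        tbl = summ.table.copy()
        tbl.insert(0, "strategy", strat)
        tbl.insert(1, "classifier", fam)
        tbl.insert(2, "divergence", div)
        frames.append(tbl)
    summary_df = pd.concat(frames, ignore_index=True)
    summary_df.to_csv(out_dir / "summary.csv", index=False)

    rank_rows = []
    dataset_name = "cohort"
    for metric in _METRICS:
        perf = {
            f"{strat}_{fam}_{div}": {dataset_name: summ.final_mean(metric)}
            for (strat, fam, div), summ in summaries.items()
        }
        ranks = average_rank(perf)
        for method, rank in ranks.items():
            rank_rows.append({"method": method, "metric": metric, "mean_rank": rank})
    pd.DataFrame(rank_rows).to_csv(out_dir / "ranks.csv", index=False)

    if config.make_plots:
        _plot_summaries(summaries, out_dir)
    return summaries


def _plot_summaries(summaries, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for metric in _METRICS:
        fig, ax = plt.subplots(figsize=(6, 4))
        for (strat, fam, div), summ in summaries.items():
            tbl = summ.table
            ax.errorbar(
                tbl["iteration"],
                tbl[f"{metric}_mean"],
                yerr=tbl[f"{metric}_sd"],
                label=f"{strat}/{fam}/{div}",
                capsize=2,
            )
        ax.set_xlabel("iteration (batches acquired)")
        ax.set_ylabel(metric)
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out_dir / f"{metric}_vs_iteration.png", dpi=120)
        plt.close(fig)
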