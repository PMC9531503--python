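"""Benchmark metrics, training curves and cross-strategy comparisons.

The sample-efficiency of a strategy is read off its training curve: per-step
batch mean/max reward, validity and uniqueness against *cumulative molecules
sampled* (strategies with different batch sizes are only comparable on that
axis). Summary numbers are the area under a normalized training curve, the
optimization percentage relative to the prior's mean score, and the first
step (or sample) at which a threshold is crossed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import canonicalize
from .filters import DiversityFilter, DiversityFilterConfig
from .models import GenerationBatch, SmilesLM
from .rl import CurveRecord, RLConfig, RLRun, rl_run
from .scoring import ScoringTask

CURVE_COLUMNS = ["step", "n_sampled_cum", "mean_raw", "mean_reward",
                 "max_reward", "mean_filtered_reward", "validity",
                 "uniqueness", "wall_time_s"]


@dataclass
class TrainingCurve:
    """Ordered per-step log of an RL run."""

    records: list[CurveRecord]

    @classmethod
    def from_run(cls, run: RLRun) -> "TrainingCurve":
        return cls(records=list(run.records))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records], columns=CURVE_COLUMNS)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrainingCurve":
        df = pd.read_csv(path)
        ints = {"step", "n_sampled_cum"}
        return cls(records=[
            CurveRecord(**{k: int(row[k]) if k in ints else float(row[k])
                           for k in CURVE_COLUMNS})
            for _, row in df.iterrows()])

    def endpoint(self, name: str) -> np.ndarray:
        if not self.records or not hasattr(self.records[0], name):
            raise KeyError(f"unknown curve endpoint {name!r}")
        return np.array([getattr(r, name) for r in self.records], dtype=float)


def batch_metrics(batch: GenerationBatch | Sequence[str]) -> tuple[float, float]:
    """(validity, uniqueness): valid/total and distinct-canonical/valid.

    Uniqueness over an all-invalid batch is reported as 1.0 (vacuous).
    """
    smiles = batch.smiles if isinstance(batch, GenerationBatch) else list(batch)
    canon = [canonicalize(s) for s in smiles]
    valid = [c for c in canon if c is not None]
    validity = len(valid) / len(smiles) if smiles else 0.0
    uniqueness = len(set(valid)) / len(valid) if valid else 1.0
    return validity, uniqueness


def curve_auc(curve: TrainingCurve, endpoint: str = "mean_reward") -> float:
    """Trapezoidal area under an endpoint over the normalized step axis, so
    a constant endpoint c gives exactly c and runs of different lengths are
    comparable."""
    y = curve.endpoint(endpoint)
    if len(y) < 2:
        raise ValueError("need at least 2 records for an AUC")
    x = np.linspace(0.0, 1.0, len(y))
    return float(np.trapezoid(y, x))


def optimization_percent(batch_mean: float, prior_mean: float,
                         direction: str = "maximize") -> float:
    """100 * batch_mean / prior_mean on the raw scale.

    For minimize tasks whose scores are negative-better (docking-like), the
    same ratio applies: a mean twice as negative as the prior's reads 200%.
    """
    if prior_mean == 0:
        raise ValueError("prior mean of 0 cannot anchor an optimization percentage")
    return 100.0 * batch_mean / prior_mean


@dataclass
class ThresholdCrossing:
    """First mean / first single-sample crossing; None means never, with the
    run length as the reported lower bound ("> n_steps")."""

    mean_step: int | None
    sample_step: int | None
    n_steps: int

    def describe(self) -> tuple[str, str]:
        fmt = lambda v: f"> {self.n_steps}" if v is None else str(v)
        return fmt(self.mean_step), fmt(self.sample_step)


def steps_to_threshold(curve: TrainingCurve, threshold: float,
                       endpoint: str = "mean_reward",
                       max_endpoint: str = "max_reward") -> ThresholdCrossing:
    means = curve.endpoint(endpoint)
    maxima = curve.endpoint(max_endpoint)
    steps = curve.endpoint("step").astype(int)
    mean_idx = np.nonzero(means >= threshold)[0]
    samp_idx = np.nonzero(maxima >= threshold)[0]
    return ThresholdCrossing(
        mean_step=int(steps[mean_idx[0]]) if mean_idx.size else None,
        sample_step=int(steps[samp_idx[0]]) if samp_idx.size else None,
        n_steps=int(steps[-1]) if len(steps) else 0,
    )


@dataclass
class ComparisonReport:
    """Curves and threshold tables for several strategies on one task."""

    curves: dict[str, list[TrainingCurve]]           # strategy -> one per seed
    thresholds: list[float]
    steps_to_threshold: pd.DataFrame = field(default=None)
    samples_to_threshold: pd.DataFrame = field(default=None)
    fold_improvements: dict[float, float | None] = field(default_factory=dict)

    def samples_to_mean_threshold(self, strategy: str, seed_idx: int,
                                  threshold: float,
                                  batch_size: int) -> float:
        """Cumulative samples at the first mean crossing; inf if never."""
        crossing = steps_to_threshold(self.curves[strategy][seed_idx], threshold)
        if crossing.mean_step is None:
            return float("inf")
        return crossing.mean_step * batch_size


def compare_strategies(prior: SmilesLM, task_factory, dfilter_factory,
                       strategy_configs: dict[str, RLConfig],
                       seeds: Sequence[int],
                       thresholds: Sequence[float] = (0.5,),
                       stop_at_mean_reward: float | None = None,
                       ) -> ComparisonReport:
    """Run every (strategy, seed) cell and tabulate threshold crossings.

    ``task_factory`` and ``dfilter_factory`` are zero-argument callables so
    each run gets a fresh scorer state and an empty filter memory. All
    configs must agree on the per-run sample budget
    (n_steps * batch_size) so curves are comparable per molecule sampled.
    """
    budgets = {name: cfg.n_steps * cfg.batch_size
               for name, cfg in strategy_configs.items()}
    if len(set(budgets.values())) > 1:
        raise ValueError(f"sample budgets differ across strategies: {budgets}")

    curves: dict[str, list[TrainingCurve]] = {}
    for name, cfg in strategy_configs.items():
        curves[name] = []
        for seed in seeds:
            run_cfg = RLConfig(**{**vars(cfg), "seed": seed})
            run = rl_run(prior, task_factory(), dfilter_factory(), run_cfg,
                         stop_at_mean_reward=stop_at_mean_reward)
            curves[name].append(TrainingCurve.from_run(run))

    rows_steps, rows_samples = [], []
    for name, cfg in strategy_configs.items():
        for i, seed in enumerate(seeds):
            for thr in thresholds:
                crossing = steps_to_threshold(curves[name][i], thr)
                mean_s, samp_s = crossing.describe()
                rows_steps.append({"strategy": name, "seed": seed,
                                   "threshold": thr, "mean_step": mean_s,
                                   "sample_step": samp_s})
                samples = (None if crossing.mean_step is None
                           else crossing.mean_step * cfg.batch_size)
                rows_samples.append({"strategy": name, "seed": seed,
                                     "threshold": thr, "samples": samples})

    report = ComparisonReport(curves=curves, thresholds=list(thresholds),
                              steps_to_threshold=pd.DataFrame(rows_steps),
                              samples_to_threshold=pd.DataFrame(rows_samples))

    # fold improvement of the last-listed strategy over the first (candidate
    # vs baseline), by median samples-to-threshold across seeds
    names = list(strategy_configs)
    if len(names) >= 2:
        base, cand = names[0], names[-1]
        for thr in thresholds:
            df = report.samples_to_threshold
            b = df[(df.strategy == base) & (df.threshold == thr)]["samples"]
            c = df[(df.strategy == cand) & (df.threshold == thr)]["samples"]
            if b.isna().all() or c.isna().all():
                report.fold_improvements[thr] = None
            else:
                report.fold_improvements[thr] = float(
                    b.dropna().median() / c.dropna().median())
    return report


def plot_comparison(report: ComparisonReport, path: str | Path,
                    endpoint: str = "mean_reward") -> None:
    """One panel: endpoint vs cumulative molecules sampled, mean over seeds."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, curve_list in report.curves.items():
        for i, curve in enumerate(curve_list):
            x = curve.endpoint("n_sampled_cum")
            y = curve.endpoint(endpoint)
            ax.plot(x, y, alpha=0.6, label=name if i == 0 else None)
    ax.set_xlabel("molecules sampled")
    ax.set_ylabel(endpoint.replace("_", " "))
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
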