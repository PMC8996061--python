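"""Experiment orchestration: sampling-strategy and chunk-size comparisons.

Experiment 1 compares class-independent against class-dependent anchor
allocation at a fixed chunk size.  Experiment 2 sweeps the chunk size k over
a grid (default 512...16384) under the class-dependent strategy and tracks
training-set entropy and chunk composition alongside the segmentation
metrics.  Both experiments repeat training several times (training is
stochastic through anchor sampling) and report per-class means, Student-t
95% confidence intervals on the mean, and Wilcoxon signed-rank significance
between paired configurations.

Test clouds are always chunked with label-blind coverage chunking — at
deployment no labels exist — regardless of the training strategy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .baseline_segmenter import BaselineSegmenter, Segmenter, make_chunk_view
from .chunk_sampler import TrainingSet, build_training_set
from .class_stats import chunk_composition
from .cloud_io import LabeledPointCloud
from .coverage_merge import ChunkPrediction, cover_cloud, merge_predictions
from .evaluation import MetricReport, compare_paired, evaluate

DEFAULT_K_GRID = (512, 1024, 2048, 4096, 8192, 16384)


@dataclass
class ExperimentConfig:
    """Shared knobs of both experiments."""

    strategies: tuple[str, ...] = ("class_independent", "class_dependent")
    a: int = 100
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    k: int = 4096  # chunk size for experiment 1
    repetitions: int = 5
    seed: int = 0
    batch_size: int = 1  # coverage-chunking anchors per iteration

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if any(k < 1 for k in self.k_grid) or self.k < 1:
            raise ValueError("chunk sizes must be >= 1")


@dataclass
class RunResult:
    """One trained-and-evaluated configuration on one test cloud."""

    strategy: str
    k: int
    repetition: int
    cloud_id: str
    report: MetricReport
    training_entropy: float


def run_pipeline_once(
    train_clouds: Sequence[LabeledPointCloud],
    test_clouds: Sequence[LabeledPointCloud],
    strategy: str,
    a: int,
    k: int,
    seed: int,
    segmenter_factory: Callable[[], Segmenter] = BaselineSegmenter,
    batch_size: int = 1,
) -> tuple[TrainingSet, list[tuple[str, np.ndarray, MetricReport]]]:
    """Train once and evaluate on every test cloud (merged, full-cloud).

    Returns the training set and, per test cloud, ``(cloud_id, merged
    labels, metric report)``.
    """
    training = build_training_set(train_clouds, strategy, a=a, k=k, seed=seed)
    views = [
        make_chunk_view(cloud, chunk)
        for chunks, cloud in zip(training.chunk_sets, train_clouds)
        for chunk in chunks
    ]
    segmenter = segmenter_factory()
    segmenter.fit(views)

    results = []
    for i, cloud in enumerate(test_clouds):
        rng = np.random.default_rng(np.random.SeedSequence((seed, 1000 + i)))
        chunks = cover_cloud(cloud, k, rng=rng, batch_size=batch_size)
        predictions = [
            ChunkPrediction(
                member_indices=chunk.member_indices,
                predicted_labels=segmenter.predict(make_chunk_view(cloud, chunk)),
            )
            for chunk in chunks
        ]
        merged, _ = merge_predictions(
            cloud.n_points, predictions, rng=rng, n_classes=cloud.scheme.n_classes
        )
        results.append((cloud.cloud_id, merged, evaluate(cloud.labels, merged)))
    return training, results


def _mean_ci(values: np.ndarray, confidence: float = 0.95) -> tuple[float, float]:
    """Mean and half-width of the Student-t confidence interval on the mean."""
    values = values[~np.isnan(values)]
    if values.size == 0:
        return float("nan"), float("nan")
    mean = float(values.mean())
    if values.size < 2 or np.allclose(values, mean):
        return mean, 0.0
    half = sps.t.ppf((1 + confidence) / 2, values.size - 1) * sps.sem(values)
    return mean, float(half)


def _summarise(results: list[RunResult], group_key: str) -> pd.DataFrame:
    """Per-class (and micro/macro) mean +- 95% CI per strategy or k."""
    scheme = results[0].report.scheme
    rows = []
    for res in results:
        group = getattr(res, group_key)
        for c, name in enumerate(scheme.names):
            rows.append(
                {
                    "group": group,
                    "class": name,
                    "iou": res.report.iou[c],
                    "precision": res.report.precision[c],
                    "recall": res.report.recall[c],
                }
            )
        rows.append({"group": group, "class": "micro", "iou": res.report.iou_micro})
        rows.append({"group": group, "class": "macro", "iou": res.report.iou_macro})
    df = pd.DataFrame(rows)
    out = []
    for (group, cls), sub in df.groupby(["group", "class"], sort=False):
        mean, ci = _mean_ci(sub["iou"].to_numpy(dtype=float))
        row = {"group": group, "class": cls, "iou_mean": mean, "iou_ci95": ci}
        for metric in ("precision", "recall"):
            if metric in sub and not sub[metric].isna().all():
                m, c_ = _mean_ci(sub[metric].to_numpy(dtype=float))
                row[f"{metric}_mean"], row[f"{metric}_ci95"] = m, c_
        out.append(row)
    return pd.DataFrame(out)


@dataclass
class ExperimentReport:
    """Raw runs, a summary table and paired significance labels."""

    results: list[RunResult]
    summary: pd.DataFrame
    significance: dict[str, object] = field(default_factory=dict)
    extras: dict[str, object] = field(default_factory=dict)

    def save(self, out_dir: str | Path, config: ExperimentConfig) -> None:
        """Persist summary CSV plus a manifest sufficient to reproduce the run."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(out_dir / "summary.csv", index=False)
        manifest = {
            "package_version": __version__,
            "config": {
                "strategies": list(config.strategies),
                "a": config.a,
                "k": config.k,
                "k_grid": list(config.k_grid),
                "repetitions": config.repetitions,
                "seed": config.seed,
                "batch_size": config.batch_size,
            },
            "significance": {
                key: {"p_value": lab.p_value, "stars": lab.stars}
                for key, lab in self.significance.items()
            },
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def run_experiment_1(
    train_clouds: Sequence[LabeledPointCloud],
    test_clouds: Sequence[LabeledPointCloud],
    config: ExperimentConfig | None = None,
    segmenter_factory: Callable[[], Segmenter] = BaselineSegmenter,
) -> ExperimentReport:
    """Compare anchor-allocation strategies at fixed chunk size ``config.k``."""
    config = config or ExperimentConfig()
    results: list[RunResult] = []
    for strategy in config.strategies:
        for rep in range(config.repetitions):
            rep_seed = int(
                np.random.SeedSequence((config.seed, rep)).generate_state(1)[0]
                % (2**31)
            )
            training, evals = run_pipeline_once(
                train_clouds,
                test_clouds,
                strategy,
                config.a,
                config.k,
                rep_seed,
                segmenter_factory,
                config.batch_size,
            )
            for cloud_id, _, report in evals:
                results.append(
                    RunResult(
                        strategy=strategy,
                        k=config.k,
                        repetition=rep,
                        cloud_id=cloud_id,
                        report=report,
                        training_entropy=training.entropy_bits,
                    )
                )
    summary = _summarise(results, "strategy")

    significance = {}
    if len(config.strategies) == 2 and config.repetitions * len(test_clouds) >= 5:
        s0, s1 = config.strategies
        scheme = results[0].report.scheme
        for c, name in enumerate(scheme.names):
            a_scores = [r.report.iou[c] for r in results if r.strategy == s0]
            b_scores = [r.report.iou[c] for r in results if r.strategy == s1]
            significance[name] = compare_paired(a_scores, b_scores)
    return ExperimentReport(results=results, summary=summary, significance=significance)


def run_experiment_2(
    train_clouds: Sequence[LabeledPointCloud],
    test_clouds: Sequence[LabeledPointCloud],
    config: ExperimentConfig | None = None,
    segmenter_factory: Callable[[], Segmenter] = BaselineSegmenter,
    strategy: str = "class_dependent",
) -> ExperimentReport:
    """Sweep chunk size k under one strategy; track entropy and composition."""
    config = config or ExperimentConfig()
    results: list[RunResult] = []
    entropy_per_k: dict[int, float] = {}
    composition_per_k: dict[int, float] = {}
    for k in config.k_grid:
        for rep in range(config.repetitions):
            rep_seed = int(
                np.random.SeedSequence((config.seed, rep)).generate_state(1)[0]
                % (2**31)
            )
            training, evals = run_pipeline_once(
                train_clouds,
                test_clouds,
                strategy,
                config.a,
                k,
                rep_seed,
                segmenter_factory,
                config.batch_size,
            )
            if rep == 0:
                entropy_per_k[k] = training.entropy_bits
                cpc = [
                    chunk_composition(chunks, cloud).mean
                    for chunks, cloud in zip(training.chunk_sets, train_clouds)
                ]
                composition_per_k[k] = float(np.mean(cpc))
            for cloud_id, _, report in evals:
                results.append(
                    RunResult(
                        strategy=strategy,
                        k=k,
                        repetition=rep,
                        cloud_id=cloud_id,
                        report=report,
                        training_entropy=training.entropy_bits,
                    )
                )
    summary = _summarise(results, "k")
    return ExperimentReport(
        results=results,
        summary=summary,
        extras={
            "training_entropy_per_k": entropy_per_k,
            "mean_classes_per_chunk_per_k": composition_per_k,
        },
    )
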