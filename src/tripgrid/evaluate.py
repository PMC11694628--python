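"""Metrics, driver-grouped cross-validation, and factor sweeps.

Metrics are precision, recall, F1 (at a 0.5 threshold) and ROC AUC
(threshold-free). Cross-validation assigns *drivers*, not segments, to
folds: with a stride-1 sliding window, adjacent segments are near
duplicates, so segment-level splitting leaks test information into
training. A deliberately leaky segment-level mode exists behind
``group_by="segment"`` for comparison.

The factor sweep reruns cross-validation over a grid of (data size, layer
widths, depth) configurations for each of the three approaches (naive,
grid, combined), mirroring a study design that varies one factor at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import (
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from .datasets import SegmentDataset, GriddingConfig
from .models import (
    CombinedSpec,
    GridStreamSpec,
    NaiveStreamSpec,
    TrainingConfig,
    build_model,
    predict_proba,
    specs_for_experiment,
    train_model,
)

__all__ = [
    "MetricReport",
    "ExperimentConfig",
    "SingleClassError",
    "TABLE5_GRID",
    "f1_from_precision_recall",
    "compute_metrics",
    "assign_folds",
    "cross_validate",
    "run_factor_sweep",
    "plot_sweep",
]


class SingleClassError(ValueError):
    """AUC requested for a label vector containing a single class."""


@dataclass(frozen=True)
class MetricReport:
    precision: float
    recall: float
    f1: float
    auc: float
    n_segments: int
    fold_id: int = 0
    driver_auc: float = float("nan")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ExperimentConfig:
    """One row of the factor-sweep grid.

    ``data_fraction`` maps a calendar collection period onto a fraction of
    the simulated corpus (e.g. 4 months of a 2-year study -> 1/6).
    """

    name: str
    data_fraction: float
    node_config: tuple[int, ...]
    hidden_layers: int

    def __post_init__(self) -> None:
        if not 0.0 < self.data_fraction <= 1.0:
            raise ValueError("data_fraction must be in (0, 1]")


TABLE5_GRID: tuple[ExperimentConfig, ...] = (
    ExperimentConfig("exp1", 1 / 6, (64, 32, 16), 1),
    ExperimentConfig("exp2", 1 / 3, (96, 48, 24), 2),
    ExperimentConfig("exp3", 1 / 2, (128, 64, 32), 3),
    ExperimentConfig("exp4", 1.0, (128, 64, 32), 3),
)


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def compute_metrics(
    y_true: np.ndarray,
    y_score: np.ndarray,
    threshold: float = 0.5,
    fold_id: int = 0,
    driver_auc: float = float("nan"),
) -> MetricReport:
    """Precision/recall/F1 at the threshold plus threshold-free ROC AUC.

    ``y_score`` is the predicted probability of the abnormal class.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_score = np.asarray(y_score, dtype=float)
    if np.unique(y_true).size < 2:
        raise SingleClassError("AUC undefined: y_true contains a single class")
    y_pred = (y_score >= threshold).astype(int)
    return MetricReport(
        precision=float(precision_score(y_true, y_pred, zero_division=0)),
        recall=float(recall_score(y_true, y_pred, zero_division=0)),
        f1=float(f1_score(y_true, y_pred, zero_division=0)),
        auc=float(roc_auc_score(y_true, y_score)),
        n_segments=int(y_true.size),
        fold_id=fold_id,
        driver_auc=driver_auc,
    )


def assign_folds(
    ds: SegmentDataset, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Partition drivers into k folds, stratified by driver label.

    Returns, per fold, the array of held-out driver ids. Every driver
    appears in exactly one fold; both classes appear in every fold.
    """
    folds: list[list[str]] = [[] for _ in range(k)]
    for label in (0, 1):
        drivers = np.unique(ds.driver_ids[ds.y == label])
        if 0 < drivers.size < k:
            raise ValueError(
                f"need >= {k} drivers of class {label} for {k}-fold grouped CV, "
                f"have {drivers.size}"
            )
        for i, part in enumerate(np.array_split(rng.permutation(drivers), k)):
            folds[i].extend(part.tolist())
    return [np.asarray(f, dtype=object) for f in folds]


def _driver_level_auc(y, scores, driver_ids) -> float:
    df = pd.DataFrame({"d": driver_ids, "y": y, "s": scores})
    agg = df.groupby("d").agg(y=("y", "first"), s=("s", "mean"))
    if agg["y"].nunique() < 2:
        return float("nan")
    return float(roc_auc_score(agg["y"], agg["s"]))


def cross_validate(
    ds: SegmentDataset,
    model_kind: str = "combined",
    k: int = 5,
    seed: int = 0,
    naive_spec: NaiveStreamSpec | None = None,
    grid_spec: GridStreamSpec | None = None,
    combined_spec: CombinedSpec | None = None,
    training: TrainingConfig | None = None,
    augment_train: bool = True,
    group_by: str = "driver",
) -> tuple[list[MetricReport], dict]:
    """k-fold cross-validation of one approach on a segment dataset.

    With ``group_by="driver"`` (default) folds partition drivers so no
    driver contributes segments to both training and test. Rotation
    augmentation, when enabled, is applied to the training folds only.
    Returns per-fold reports (segment-level metrics plus a driver-level AUC
    from per-driver mean scores) and a mean/std summary.
    """
    if group_by not in ("driver", "segment"):
        raise ValueError("group_by must be 'driver' or 'segment'")
    rng = np.random.default_rng(seed)
    naive_spec = naive_spec or NaiveStreamSpec(input_dim=ds.x_naive.shape[1])
    grid_spec = grid_spec or GridStreamSpec(extent_g=ds.extent_g)
    training = training or TrainingConfig(seed=seed)

    if group_by == "driver":
        fold_members = assign_folds(ds, k, rng)
        test_masks = [np.isin(ds.driver_ids, f) for f in fold_members]
    else:  # leaky segment-level split, for leakage comparisons only
        perm = rng.permutation(len(ds))
        test_masks = [np.isin(np.arange(len(ds)), part) for part in np.array_split(perm, k)]

    reports: list[MetricReport] = []
    for fold_id, test_mask in enumerate(test_masks):
        train_ds = ds.subset(~test_mask)
        test_ds = ds.subset(test_mask)
        if augment_train:
            train_ds = train_ds.with_rotations()
        model = build_model(
            model_kind,
            seed=int(rng.integers(2**31)),
            naive_spec=naive_spec,
            grid_spec=grid_spec,
            combined_spec=combined_spec,
        )
        needs_grid = model_kind in ("grid", "combined")
        train_model(
            model,
            train_ds.x_naive if model_kind != "grid" else None,
            train_ds.grids() if needs_grid else None,
            train_ds.y,
            training,
        )
        scores = predict_proba(
            model,
            test_ds.x_naive if model_kind != "grid" else None,
            test_ds.grids() if needs_grid else None,
        )[:, 1]
        reports.append(
            compute_metrics(
                test_ds.y,
                scores,
                fold_id=fold_id,
                driver_auc=_driver_level_auc(test_ds.y, scores, test_ds.driver_ids),
            )
        )
    frame = pd.DataFrame([r.as_dict() for r in reports])
    summary = {}
    for m in ("precision", "recall", "f1", "auc", "driver_auc"):
        summary[f"{m}_mean"] = float(frame[m].mean())
        summary[f"{m}_std"] = float(frame[m].std(ddof=0))
    summary["n_segments"] = int(frame["n_segments"].sum())
    return reports, summary


def _prefix_fraction(ds: SegmentDataset, fraction: float) -> SegmentDataset:
    """Keep the first ``fraction`` of each driver's segments (in corpus
    order), emulating a shorter collection period."""
    if fraction >= 1.0:
        return ds
    keep = np.zeros(len(ds), dtype=bool)
    for d in ds.drivers:
        idx = np.flatnonzero(ds.driver_ids == d)
        keep[idx[: max(int(np.ceil(fraction * idx.size)), 1)]] = True
    return ds.subset(keep)


def run_factor_sweep(
    ds: SegmentDataset,
    grid: tuple[ExperimentConfig, ...] = TABLE5_GRID,
    approaches: tuple[str, ...] = ("naive", "grid", "combined"),
    k: int = 5,
    seed: int = 0,
    training: TrainingConfig | None = None,
    augment_train: bool = True,
) -> pd.DataFrame:
    """Cross-validate every approach under every experiment configuration.

    Returns one row per (experiment, approach) with the fold-mean metrics —
    the tables underlying metric-vs-factor comparison plots.
    """
    rows = []
    for cfg in grid:
        sub = _prefix_fraction(ds, cfg.data_fraction)
        naive_spec, grid_spec, combined_spec = specs_for_experiment(
            cfg.node_config,
            cfg.hidden_layers,
            input_dim=ds.x_naive.shape[1],
            extent_g=ds.extent_g,
        )
        for approach in approaches:
            _, summary = cross_validate(
                sub,
                model_kind=approach,
                k=k,
                seed=seed,
                naive_spec=naive_spec,
                grid_spec=grid_spec,
                combined_spec=combined_spec,
                training=training,
                augment_train=augment_train,
            )
            rows.append(
                {
                    "experiment": cfg.name,
                    "approach": approach,
                    "data_fraction": cfg.data_fraction,
                    "nodes": "/".join(map(str, cfg.node_config)),
                    "hidden_layers": cfg.hidden_layers,
                    "precision": summary["precision_mean"],
                    "recall": summary["recall_mean"],
                    "f1": summary["f1_mean"],
                    "auc": summary["auc_mean"],
                    "driver_auc": summary["driver_auc_mean"],
                    "n_segments": summary["n_segments"],
                }
            )
    return pd.DataFrame(rows)


def plot_sweep(
    table: pd.DataFrame, metric: str, x: str, path: str
) -> None:
    """Line plot of a sweep metric vs. a factor, one line per approach (SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for approach, sub in table.groupby("approach"):
        sub = sub.sort_values(x)
        ax.plot(sub[x], sub[metric], marker="o", label=approach)
    ax.set_xlabel(x)
    ax.set_ylabel(metric)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
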