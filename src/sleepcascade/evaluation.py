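"""Scoring: confusion matrices, holdout protocol, TOPSIS feature evaluation.

The holdout protocol mirrors the training study: repeat a stratified 90/10
split, rank features on the training part only, train the cascade (and the
flat five-class baseline for comparison), and score the held-out 10%; the
mean and standard deviation over repeats summarize generalization.

TOPSIS scores candidate nonlinear features on three criteria - computing
time (cost), average accuracy and N1 accuracy (benefits) - by min-max
normalizing each criterion, then ranking items by relative closeness
D- / (D+ + D-) to the ideal (1,1,1) and anti-ideal (0,0,0) points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedShuffleSplit

from .classifier import (
    CascadeConfig,
    predict_cascade,
    predict_single_ovo,
    train_cascade,
    train_single_ovo,
)
from .selection import miq_rank
from .signal_io import SleepStage

__all__ = [
    "ConfusionResult",
    "confusion_and_metrics",
    "HoldoutResult",
    "repeated_holdout",
    "TOPSISItem",
    "topsis_scores",
]

STAGE_ORDER = tuple(s.value for s in SleepStage.order())


@dataclass
class ConfusionResult:
    """Confusion matrix (rows = true stage, columns = predicted) + metrics.

    Precision/recall are NaN for stages with an empty column/row
    (undefined, reported as such).
    """

    matrix: pd.DataFrame
    accuracy: float
    precision: pd.Series
    recall: pd.Series


def confusion_and_metrics(
    true_labels, predicted_labels, stages: tuple[str, ...] = STAGE_ORDER
) -> ConfusionResult:
    """Confusion matrix with total accuracy and per-stage precision/recall."""
    y_true = np.asarray([getattr(l, "value", l) for l in true_labels], dtype=object)
    y_pred = np.asarray(
        [getattr(l, "value", l) for l in predicted_labels], dtype=object
    )
    if y_true.size != y_pred.size:
        raise ValueError("label arrays differ in length")
    bad = (set(y_true) | set(y_pred)) - set(stages)
    if bad:
        raise ValueError(f"labels outside the stage set: {sorted(bad)}")
    counts = _sk_confusion(y_true, y_pred, labels=list(stages))
    matrix = pd.DataFrame(counts, index=list(stages), columns=list(stages))
    total = counts.sum()
    accuracy = float(np.trace(counts) / total) if total else float("nan")
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, np.diag(counts) / np.where(col, col, 1), np.nan)
        recall = np.where(row > 0, np.diag(counts) / np.where(row, row, 1), np.nan)
    return ConfusionResult(
        matrix=matrix,
        accuracy=accuracy,
        precision=pd.Series(precision, index=list(stages)),
        recall=pd.Series(recall, index=list(stages)),
    )


@dataclass
class HoldoutResult:
    """Per-repeat and summary metrics of the repeated 90/10 holdout."""

    cascade_accuracy: np.ndarray
    cascade_n1_accuracy: np.ndarray
    single_accuracy: np.ndarray | None
    single_n1_accuracy: np.ndarray | None
    confusions: list[ConfusionResult]

    def summary(self) -> dict[str, float]:
        out = {
            "cascade_accuracy_mean": float(np.mean(self.cascade_accuracy)),
            "cascade_accuracy_sd": float(np.std(self.cascade_accuracy)),
            "cascade_n1_accuracy_mean": float(np.nanmean(self.cascade_n1_accuracy)),
            "cascade_n1_accuracy_sd": float(np.nanstd(self.cascade_n1_accuracy)),
        }
        if self.single_accuracy is not None:
            out["single_accuracy_mean"] = float(np.mean(self.single_accuracy))
            out["single_accuracy_sd"] = float(np.std(self.single_accuracy))
            out["single_n1_accuracy_mean"] = float(np.nanmean(self.single_n1_accuracy))
            out["single_n1_accuracy_sd"] = float(np.nanstd(self.single_n1_accuracy))
        return out


def repeated_holdout(
    feature_table: pd.DataFrame,
    labels,
    n_repeats: int = 5,
    test_fraction: float = 0.1,
    seed: int = 0,
    config: CascadeConfig | None = None,
    n_bins: int = 10,
    compare_single: bool = False,
    stratify: bool = True,
) -> HoldoutResult:
    """Repeat: split, rank on the training part, train, score the held-out part.

    N1 accuracy is the recall of stage N1 on the held-out epochs.  A repeat
    whose training split lacks a stage is aborted and logged (warning).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    y = np.asarray([getattr(l, "value", l) for l in labels], dtype=object)
    if stratify:
        splitter = StratifiedShuffleSplit(
            n_splits=n_repeats, test_size=test_fraction, random_state=seed
        )
        splits = splitter.split(np.zeros(len(y)), y)
    else:
        rng = np.random.default_rng(seed)
        n_test = max(1, int(round(test_fraction * len(y))))
        splits = []
        for _ in range(n_repeats):
            perm = rng.permutation(len(y))
            splits.append((perm[n_test:], perm[:n_test]))

    acc, n1_acc, s_acc, s_n1 = [], [], [], []
    confusions: list[ConfusionResult] = []
    base_cfg = config or CascadeConfig()
    for rep, (train_idx, test_idx) in enumerate(splits):
        y_train = y[train_idx]
        if set(STAGE_ORDER) - set(y_train):
            warnings.warn(f"repeat {rep}: a stage is absent from training; skipped")
            continue
        cfg = CascadeConfig(
            const=base_cfg.const,
            top_stage1=base_cfg.top_stage1,
            top_stage2=base_cfg.top_stage2,
            cv_folds=base_cfg.cv_folds,
            seed=seed + rep,
            const_grid=base_cfg.const_grid,
        )
        train_tab = feature_table.iloc[train_idx].reset_index(drop=True)
        test_tab = feature_table.iloc[test_idx].reset_index(drop=True)
        ranking = miq_rank(train_tab, y_train, n_bins=n_bins)
        model = train_cascade(train_tab, y_train, ranking, cfg)
        pred = predict_cascade(model, test_tab)
        result = confusion_and_metrics(y[test_idx], pred)
        confusions.append(result)
        acc.append(result.accuracy)
        n1_acc.append(float(result.recall["N1"]))
        if compare_single:
            params, svm = train_single_ovo(train_tab, y_train, ranking, cfg)
            pred_s = predict_single_ovo(params, svm, test_tab)
            res_s = confusion_and_metrics(y[test_idx], pred_s)
            s_acc.append(res_s.accuracy)
            s_n1.append(float(res_s.recall["N1"]))
    if not acc:
        raise ValueError("no repeat completed; check stage coverage")
    return HoldoutResult(
        cascade_accuracy=np.asarray(acc),
        cascade_n1_accuracy=np.asarray(n1_acc),
        single_accuracy=np.asarray(s_acc) if compare_single else None,
        single_n1_accuracy=np.asarray(s_n1) if compare_single else None,
        confusions=confusions,
    )


# ---------------------------------------------------------------------------
# TOPSIS
# ---------------------------------------------------------------------------


@dataclass
class TOPSISItem:
    """One scored candidate (e.g. a nonlinear feature)."""

    name: str
    time: float
    accuracy: float
    n1_accuracy: float
    v: tuple[float, float, float]
    d_plus: float
    d_minus: float
    score: float


def topsis_scores(
    items: list[tuple[str, float, float, float]],
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    sqrt_distances: bool = True,
) -> list[TOPSISItem]:
    """Score items given as (name, computing time, accuracy, N1 accuracy).

    Computing time is a cost criterion (smaller is better); the accuracies
    are benefits.  Each criterion is min-max normalized so the ideal point is
    (1,1,1) and the anti-ideal (0,0,0); a criterion with max == min carries
    no information and is dropped with a warning.  ``sqrt_distances=False``
    uses the squared-distance variant (no square root).
    """
    if len(items) < 2:
        raise ValueError("need at least 2 items to score")
    if any(w < 0 for w in weights):
        raise ValueError("weights must be non-negative")
    names = [it[0] for it in items]
    raw = np.asarray([[it[1], it[2], it[3]] for it in items], dtype=float)
    lo, hi = raw.min(axis=0), raw.max(axis=0)
    active = hi > lo
    if not np.all(active):
        warnings.warn("criterion with max == min dropped from TOPSIS scoring")
    v = np.zeros_like(raw)
    span = np.where(active, hi - lo, 1.0)
    v[:, 0] = (hi[0] - raw[:, 0]) / span[0]  # cost criterion
    v[:, 1] = (raw[:, 1] - lo[1]) / span[1]
    v[:, 2] = (raw[:, 2] - lo[2]) / span[2]
    v[:, ~active] = 0.0
    w = np.asarray(weights, dtype=float) * active
    d_plus = np.sum(w * (v - 1.0 * active) ** 2, axis=1)
    d_minus = np.sum(w * v**2, axis=1)
    if sqrt_distances:
        d_plus = np.sqrt(d_plus)
        d_minus = np.sqrt(d_minus)
    scores = d_minus / (d_plus + d_minus)
    return [
        TOPSISItem(
            name=names[j],
            time=raw[j, 0],
            accuracy=raw[j, 1],
            n1_accuracy=raw[j, 2],
            v=tuple(v[j]),
            d_plus=float(d_plus[j]),
            d_minus=float(d_minus[j]),
            score=float(scores[j]),
        )
        for j in range(len(items))
    ]
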