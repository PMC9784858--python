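"""The cascaded one-vs-one SVM sleep stager.

Stage I separates W / REM-LS / N3, where REM-LS merges the mutually
confusable stages R, N1 and N2.  Epochs routed to REM-LS go to stage II,
which resolves R / N1 / N2 and is trained on a rebalanced subset: every N1
epoch, an equal number of R epochs, and twice that number of N2 epochs.
Both stages are one-vs-one ensembles of binary SVMs with the quadratic
polynomial kernel (x.z)^2; the predicted class is the majority vote.

Features are standardized with training-set statistics (population std) and
each stage uses its own MIQ-ranked subset (top 32 for stage I, top 30 for
stage II by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .selection import DEFAULT_TOP_STAGE1, DEFAULT_TOP_STAGE2, MIQRanking, select_top
from .signal_io import SleepStage

__all__ = [
    "REM_LS",
    "STAGE1_CLASSES",
    "STAGE2_CLASSES",
    "StandardizationParams",
    "BinarySVM",
    "OvoSVM",
    "CascadeConfig",
    "CascadeModel",
    "standardize_fit",
    "standardize_apply",
    "quad_kernel",
    "train_binary_svm",
    "predict_binary",
    "train_ovo",
    "predict_ovo",
    "build_stage1_labels",
    "build_stage2_training_set",
    "train_cascade",
    "predict_cascade",
    "train_single_ovo",
    "save_model",
    "load_model",
]

#: The merged stage-I class containing R, N1 and N2.
REM_LS = "REM-LS"
STAGE1_CLASSES = ("W", REM_LS, "N3")
STAGE2_CLASSES = ("R", "N1", "N2")

MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


@dataclass
class StandardizationParams:
    """Per-feature training mean and (population) standard deviation."""

    means: pd.Series
    stds: pd.Series
    features: list[str]


def standardize_fit(training_table: pd.DataFrame) -> StandardizationParams:
    """Fit means/stds on the training table; zero-variance columns dropped."""
    if len(training_table) < 2:
        raise ValueError("need at least 2 rows to fit standardization")
    means = training_table.mean()
    stds = training_table.std(ddof=0)
    keep = stds[stds > 0].index.tolist()
    dropped = [c for c in training_table.columns if c not in keep]
    if dropped:
        warnings.warn(f"dropping zero-variance features: {dropped}")
    return StandardizationParams(
        means=means[keep], stds=stds[keep], features=keep
    )


def standardize_apply(
    params: StandardizationParams, table: pd.DataFrame
) -> pd.DataFrame:
    """Apply training-set standardization to (a superset of) its features."""
    missing = [c for c in params.features if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks features: {missing}")
    sub = table[params.features]
    return (sub - params.means) / params.stds


# ---------------------------------------------------------------------------
# Binary SVM with the quadratic polynomial kernel
# ---------------------------------------------------------------------------


def quad_kernel(x: np.ndarray, z: np.ndarray) -> float:
    """The quadratic polynomial kernel (x . z)^2."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape:
        raise ValueError("dimension mismatch")
    return float(np.dot(x, z) ** 2)


@dataclass
class BinarySVM:
    """A trained binary machine: dual solution plus the fitted backend.

    ``alpha`` are the Lagrange multipliers of the support vectors,
    ``sv_labels`` their +/-1 labels, ``bias`` the offset of Eq-style decision
    f(x) = sum_i alpha_i y_i (x_i . x)^2 + bias, and ``const`` the box bound.
    """

    support_vectors: np.ndarray
    alpha: np.ndarray
    sv_labels: np.ndarray
    bias: float
    const: float
    _svc: SVC = field(repr=False)


def train_binary_svm(
    rows: np.ndarray, labels: np.ndarray, const: float = 1.0
) -> BinarySVM:
    """Solve the soft-margin dual with the (x.z)^2 kernel.

    ``labels`` must contain both +1 and -1.  The quadratic program is solved
    by libsvm (SMO) to its KKT tolerance; multipliers, support vectors and
    bias are surfaced on the returned model.
    """
    x = np.asarray(rows, dtype=float)
    y = np.asarray(labels)
    if set(np.unique(y)) != {-1, 1}:
        raise ValueError("labels must contain both classes +1 and -1")
    svc = SVC(C=const, kernel="poly", degree=2, gamma=1.0, coef0=0.0, tol=1e-6)
    svc.fit(x, y)
    dual = svc.dual_coef_[0]  # alpha_i * y_i, positive class = +1
    return BinarySVM(
        support_vectors=svc.support_vectors_,
        alpha=np.abs(dual),
        sv_labels=np.sign(dual).astype(int),
        bias=float(svc.intercept_[0]),
        const=const,
        _svc=svc,
    )


def decision_binary(model: BinarySVM, x: np.ndarray) -> np.ndarray:
    """Decision value(s) sum_i alpha_i y_i (x_i . x)^2 + bias."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    k = (x @ model.support_vectors.T) ** 2
    return k @ (model.alpha * model.sv_labels) + model.bias


def predict_binary(model: BinarySVM, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels (+1 when the decision value is >= 0) and the values."""
    u = decision_binary(model, x)
    return np.where(u >= 0, 1, -1), u


# ---------------------------------------------------------------------------
# One-vs-one ensemble
# ---------------------------------------------------------------------------


@dataclass
class OvoSVM:
    """C(k,2) pairwise binary machines over an ordered class list.

    For the pair (a, b), ``a`` (earlier in ``classes``) is the +1 class.
    """

    classes: list[str]
    machines: dict[tuple[str, str], BinarySVM]
    features: list[str] | None = None


def train_ovo(
    rows: np.ndarray | pd.DataFrame,
    labels: np.ndarray,
    classes: list[str] | tuple[str, ...],
    const: float = 1.0,
) -> OvoSVM:
    """Train one binary machine per class pair."""
    x = np.asarray(rows, dtype=float)
    y = np.asarray(labels)
    features = list(rows.columns) if isinstance(rows, pd.DataFrame) else None
    classes = list(classes)
    present = set(np.unique(y))
    missing = [c for c in classes if c not in present]
    if missing:
        raise ValueError(f"classes missing from training data: {missing}")
    machines = {}
    for a, b in combinations(classes, 2):
        mask = (y == a) | (y == b)
        yy = np.where(y[mask] == a, 1, -1)
        machines[(a, b)] = train_binary_svm(x[mask], yy, const=const)
    return OvoSVM(classes=classes, machines=machines, features=features)


def predict_ovo(
    model: OvoSVM, x: np.ndarray | pd.DataFrame
) -> np.ndarray:
    """Majority vote over the pairwise machines.

    Vote ties are broken by the largest sum of absolute decision values over
    the machines involving each tied class, then by class-list order.
    """
    if isinstance(x, pd.DataFrame):
        x = x.to_numpy(dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[0]
    classes = model.classes
    votes = {c: np.zeros(n, dtype=int) for c in classes}
    strength = {c: np.zeros(n) for c in classes}
    for (a, b), machine in model.machines.items():
        pred, u = predict_binary(machine, x)
        votes[a] += pred == 1
        votes[b] += pred == -1
        strength[a] += np.abs(u)
        strength[b] += np.abs(u)
    out = np.empty(n, dtype=object)
    vote_mat = np.stack([votes[c] for c in classes], axis=1)
    str_mat = np.stack([strength[c] for c in classes], axis=1)
    for i in range(n):
        best_votes = vote_mat[i].max()
        tied = [j for j in range(len(classes)) if vote_mat[i, j] == best_votes]
        if len(tied) > 1:
            best_strength = max(str_mat[i, j] for j in tied)
            tied = [j for j in tied if str_mat[i, j] == best_strength]
        out[i] = classes[tied[0]]
    return out


# ---------------------------------------------------------------------------
# Cascade construction
# ---------------------------------------------------------------------------


def build_stage1_labels(labels: np.ndarray) -> np.ndarray:
    """Five-stage labels -> {W, REM-LS, N3}; R/N1/N2 merge into REM-LS."""
    y = np.asarray([getattr(l, "value", l) for l in labels], dtype=object)
    known = {s.value for s in SleepStage}
    bad = set(y) - known
    if bad:
        raise ValueError(f"unknown stage labels: {sorted(bad)}")
    return np.array(
        [l if l in ("W", "N3") else REM_LS for l in y], dtype=object
    )


def build_stage2_training_set(
    labels: np.ndarray, seed: int | np.random.Generator
) -> np.ndarray:
    """Row indices of the rebalanced stage-II training set.

    Keeps every N1 epoch, samples |N1| R epochs and 2|N1| N2 epochs without
    replacement.  When R or N2 are short, all available are taken (warning).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    y = np.asarray([getattr(l, "value", l) for l in labels], dtype=object)
    idx_n1 = np.flatnonzero(y == "N1")
    idx_r = np.flatnonzero(y == "R")
    idx_n2 = np.flatnonzero(y == "N2")
    if idx_n1.size == 0 or idx_r.size == 0 or idx_n2.size == 0:
        raise ValueError("stage-II set needs N1, R and N2 epochs")
    n1 = idx_n1.size
    take_r, take_n2 = n1, 2 * n1
    if idx_r.size < take_r:
        warnings.warn("fewer R epochs than N1; taking all R")
        take_r = idx_r.size
    if idx_n2.size < take_n2:
        warnings.warn("fewer N2 epochs than 2x N1; taking all N2")
        take_n2 = idx_n2.size
    sel_r = rng.choice(idx_r, size=take_r, replace=False)
    sel_n2 = rng.choice(idx_n2, size=take_n2, replace=False)
    return np.sort(np.concatenate([idx_n1, sel_r, sel_n2]))


@dataclass
class CascadeConfig:
    """Tunables of the cascade."""

    const: float = 1.0
    top_stage1: int = DEFAULT_TOP_STAGE1
    top_stage2: int = DEFAULT_TOP_STAGE2
    cv_folds: int = 10
    seed: int = 0
    const_grid: tuple[float, ...] | None = None  # optional stage-II C search


@dataclass
class CascadeModel:
    """A trained cascade: standardizer, feature subsets, two OvO stages."""

    standardizer: StandardizationParams
    stage1_features: list[str]
    stage2_features: list[str]
    svm1: OvoSVM
    svm2: OvoSVM
    config: CascadeConfig
    cv_scores: np.ndarray  # stage-II fold accuracies (diagnostic)


def _cv_accuracy(
    table: pd.DataFrame,
    labels: np.ndarray,
    classes: tuple[str, ...],
    const: float,
    folds: int,
    seed: int,
) -> np.ndarray:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    x = table.to_numpy(dtype=float)
    for train_idx, test_idx in skf.split(x, labels):
        model = train_ovo(x[train_idx], labels[train_idx], classes, const=const)
        pred = predict_ovo(model, x[test_idx])
        scores.append(float(np.mean(pred == labels[test_idx])))
    return np.asarray(scores)


def train_cascade(
    feature_table: pd.DataFrame,
    labels: np.ndarray,
    ranking: MIQRanking,
    config: CascadeConfig | None = None,
) -> CascadeModel:
    """Train both stages of the cascade on a training feature table.

    Stage I is trained on the full (imbalanced) training set with merged
    labels; stage II on the rebalanced R/N1/N2 subset, with a k-fold
    cross-validation diagnostic (and optional regularization-constant grid
    search) on that subset before the final refit.
    """
    config = config or CascadeConfig()
    y = np.asarray([getattr(l, "value", l) for l in labels], dtype=object)
    params = standardize_fit(feature_table)
    table_std = standardize_apply(params, feature_table)

    feats1 = [f for f in select_top(ranking, config.top_stage1) if f in params.features]
    feats2 = [f for f in select_top(ranking, config.top_stage2) if f in params.features]

    y1 = build_stage1_labels(y)
    svm1 = train_ovo(table_std[feats1], y1, STAGE1_CLASSES, const=config.const)

    idx2 = build_stage2_training_set(y, config.seed)
    table2 = table_std.iloc[idx2][feats2]
    y2 = y[idx2]

    const2 = config.const
    if config.const_grid:
        best = None
        for c in config.const_grid:
            acc = _cv_accuracy(
                table2, y2, STAGE2_CLASSES, c, config.cv_folds, config.seed
            ).mean()
            if best is None or acc > best[0]:
                best = (acc, c)
        const2 = best[1]
    cv_scores = _cv_accuracy(
        table2, y2, STAGE2_CLASSES, const2, config.cv_folds, config.seed
    )
    svm2 = train_ovo(table2, y2, STAGE2_CLASSES, const=const2)

    return CascadeModel(
        standardizer=params,
        stage1_features=feats1,
        stage2_features=feats2,
        svm1=svm1,
        svm2=svm2,
        config=config,
        cv_scores=cv_scores,
    )


def predict_cascade(model: CascadeModel, feature_table: pd.DataFrame) -> np.ndarray:
    """Predict five-class stages: stage I decides W/N3, stage II the rest."""
    table_std = standardize_apply(model.standardizer, feature_table)
    stage1 = predict_ovo(model.svm1, table_std[model.stage1_features])
    out = stage1.copy()
    route = stage1 == REM_LS
    if np.any(route):
        out[route] = predict_ovo(
            model.svm2, table_std.loc[route, model.stage2_features]
        )
    return out


def train_single_ovo(
    feature_table: pd.DataFrame,
    labels: np.ndarray,
    ranking: MIQRanking,
    config: CascadeConfig | None = None,
) -> tuple[StandardizationParams, OvoSVM]:
    """The flat five-class one-vs-one baseline on the stage-I feature subset."""
    config = config or CascadeConfig()
    y = np.asarray([getattr(l, "value", l) for l in labels], dtype=object)
    params = standardize_fit(feature_table)
    table_std = standardize_apply(params, feature_table)
    feats = [f for f in select_top(ranking, config.top_stage1) if f in params.features]
    classes = tuple(s.value for s in SleepStage.order())
    svm = train_ovo(table_std[feats], y, classes, const=config.const)
    svm.features = feats
    return params, svm


def predict_single_ovo(
    params: StandardizationParams, svm: OvoSVM, feature_table: pd.DataFrame
) -> np.ndarray:
    table_std = standardize_apply(params, feature_table)
    return predict_ovo(svm, table_std[svm.features])


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_model(model: CascadeModel, path: str | Path) -> None:
    """Write the trained cascade to a single format-versioned file."""
    joblib.dump({"format": "sleepcascade-model", "version": MODEL_FORMAT_VERSION,
                 "model": model}, path)


def load_model(path: str | Path) -> CascadeModel:
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != "sleepcascade-model":
        raise ValueError("not a sleepcascade model file")
    if payload.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version: {payload.get('version')}")
    return payload["model"]
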