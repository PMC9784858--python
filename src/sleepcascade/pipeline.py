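"""Orchestration: dataset -> features -> ranking -> cascade -> metrics.

Every artifact a run writes (feature CSV, ranking CSV, model file, predicted
hypnogram, metrics) lands in one output directory together with the exact
configuration and seed, so a run is reproducible from its own artifacts.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import CascadeConfig, predict_cascade, save_model, train_cascade
from .config import PipelineConfig
from .evaluation import confusion_and_metrics, repeated_holdout
from .features import FEATURE_NAMES, extract_feature_table
from .selection import miq_rank
from .signal_io import LabeledDataset

logger = logging.getLogger("sleepcascade")

__all__ = ["cascade_config", "compute_features", "run_pipeline", "read_feature_csv"]


def cascade_config(config: PipelineConfig) -> CascadeConfig:
    return CascadeConfig(
        const=config.const,
        top_stage1=config.top_stage1,
        top_stage2=config.top_stage2,
        cv_folds=config.cv_folds,
        seed=config.seed,
        const_grid=tuple(config.const_grid) if config.const_grid else None,
    )


def compute_features(dataset: LabeledDataset, config: PipelineConfig) -> pd.DataFrame:
    t0 = time.perf_counter()
    table = extract_feature_table(dataset, mse_tau=config.mse_tau)
    logger.info(
        "features: %d epochs x %d features in %.1f s",
        len(table), len(FEATURE_NAMES), time.perf_counter() - t0,
    )
    return table


def read_feature_csv(path: str | Path) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a feature CSV; returns (51-column table, stage labels)."""
    frame = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in frame.columns]
    if missing:
        raise ValueError(f"feature CSV lacks columns: {missing}")
    if "stage" not in frame.columns:
        raise ValueError("feature CSV lacks the 'stage' column")
    return frame[list(FEATURE_NAMES)], frame["stage"].to_numpy(dtype=object)


def run_pipeline(
    config: PipelineConfig, dataset: LabeledDataset, outdir: str | Path
) -> dict[str, Path]:
    """Run every stage on a labeled dataset and write all artifacts.

    Returns the artifact paths.  The holdout metrics cover the repeated
    90/10 protocol; the final model and predicted hypnogram use all epochs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "config": outdir / "config.yaml",
        "features": outdir / "features.csv",
        "ranking": outdir / "ranking.csv",
        "model": outdir / "model.joblib",
        "hypnogram": outdir / "hypnogram.csv",
        "metrics": outdir / "metrics.csv",
        "confusion": outdir / "confusion.csv",
    }
    config.to_yaml(paths["config"])

    table = compute_features(dataset, config)
    table.to_csv(paths["features"], index=False)
    features = table[list(FEATURE_NAMES)]
    labels = table["stage"].to_numpy(dtype=object)

    t0 = time.perf_counter()
    holdout = repeated_holdout(
        features,
        labels,
        n_repeats=config.n_repeats,
        test_fraction=config.test_fraction,
        seed=config.seed,
        config=cascade_config(config),
        n_bins=config.n_bins,
        compare_single=True,
        stratify=config.stratify,
    )
    logger.info("holdout evaluation in %.1f s", time.perf_counter() - t0)

    ranking = miq_rank(features, labels, n_bins=config.n_bins)
    ranking.write_csv(paths["ranking"])
    model = train_cascade(features, labels, ranking, cascade_config(config))
    save_model(model, paths["model"])

    predicted = predict_cascade(model, features)
    pd.DataFrame(
        {
            "epoch_index": np.arange(len(labels)),
            "true_stage": labels,
            "predicted_stage": predicted,
        }
    ).to_csv(paths["hypnogram"], index=False)

    summary = holdout.summary()
    summary["seed"] = config.seed
    pd.DataFrame([summary]).to_csv(paths["metrics"], index=False)

    confusion = confusion_and_metrics(labels, predicted)
    confusion.matrix.to_csv(paths["confusion"])
    logger.info(
        "holdout: cascade %.3f +/- %.3f (N1 %.3f), single %.3f (N1 %.3f)",
        summary["cascade_accuracy_mean"],
        summary["cascade_accuracy_sd"],
        summary["cascade_n1_accuracy_mean"],
        summary["single_accuracy_mean"],
        summary["single_n1_accuracy_mean"],
    )
    return paths
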