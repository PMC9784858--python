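"""MIQ (mutual-information quotient) feature ranking, mRMR style.

Each feature is scored once against the whole set: relevance is the mutual
information between the (quantile-discretized) feature and the stage label;
redundancy is the mean mutual information between the feature and every
other feature.  MIQ is their quotient and features are ranked by descending
MIQ.  The top-32 subset feeds stage I of the cascade and the top-30 subset
stage II by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score

__all__ = [
    "MIQRanking",
    "discretize",
    "mutual_information",
    "miq_rank",
    "select_top",
]

DEFAULT_BINS = 10
DEFAULT_TOP_STAGE1 = 32
DEFAULT_TOP_STAGE2 = 30


@dataclass
class MIQRanking:
    """Features ordered by descending MIQ, with diagnostics."""

    ranking: list[tuple[str, float]]
    n_bins: int
    relevance: dict[str, float]
    redundancy: dict[str, float]

    def names(self) -> list[str]:
        return [name for name, _ in self.ranking]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ranking) + 1),
                "feature": self.names(),
                "miq": [v for _, v in self.ranking],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, n_bins: int = DEFAULT_BINS) -> "MIQRanking":
        frame = pd.read_csv(path)
        ranking = list(zip(frame["feature"], frame["miq"].astype(float)))
        return cls(ranking=ranking, n_bins=n_bins, relevance={}, redundancy={})


def discretize(values: np.ndarray, n_bins: int = DEFAULT_BINS) -> np.ndarray:
    """Quantile-bin a continuous column into integer codes.

    Tied values share a bin, so a monotone transform of the column leaves the
    codes unchanged; at most ``n_bins`` distinct codes result.  A constant
    column yields a single code (with a warning).
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty column")
    if x.max() == x.min():
        warnings.warn("constant column discretized to a single code")
        return np.zeros(x.size, dtype=np.int64)
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="right").astype(np.int64)


def mutual_information(codes_x: np.ndarray, codes_y: np.ndarray) -> float:
    """Plug-in mutual information (nats) of two discrete code sequences."""
    x = np.asarray(codes_x)
    y = np.asarray(codes_y)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty input")
    if x.size != y.size:
        raise ValueError("length mismatch")
    return float(mutual_info_score(x, y))


def miq_rank(
    feature_table: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    n_bins: int = DEFAULT_BINS,
) -> MIQRanking:
    """Rank every feature column of ``feature_table`` by MIQ.

    MIQ(f_i) = I(f_i, g) / ((1/|F|) * sum_{j != i} I(f_i, f_j)).  Ties in MIQ
    are broken by the table's column order.  A feature whose redundancy
    denominator is zero (empirically independent of every other feature) is
    ranked by relevance alone, with a warning.
    """
    if feature_table.shape[1] < 2:
        raise ValueError("need at least 2 features to rank")
    names = list(feature_table.columns)
    y = np.asarray(labels)
    if y.size != len(feature_table):
        raise ValueError("labels length must match the table")
    codes = {
        name: discretize(feature_table[name].to_numpy(), n_bins) for name in names
    }
    n_features = len(names)
    relevance = {name: mutual_information(codes[name], y) for name in names}
    # pairwise MI is symmetric; compute the upper triangle once
    pair_mi = np.zeros((n_features, n_features))
    for i in range(n_features):
        for j in range(i + 1, n_features):
            mi = mutual_information(codes[names[i]], codes[names[j]])
            pair_mi[i, j] = pair_mi[j, i] = mi
    redundancy = {
        name: float(pair_mi[i].sum()) / n_features for i, name in enumerate(names)
    }
    scores = {}
    for name in names:
        if redundancy[name] <= 0:
            warnings.warn(
                f"feature {name!r} has zero redundancy; ranked by relevance alone"
            )
            scores[name] = np.inf if relevance[name] > 0 else 0.0
        else:
            scores[name] = relevance[name] / redundancy[name]
    order = sorted(range(n_features), key=lambda i: (-scores[names[i]], i))
    ranking = [(names[i], float(scores[names[i]])) for i in order]
    return MIQRanking(
        ranking=ranking, n_bins=n_bins, relevance=relevance, redundancy=redundancy
    )


def select_top(ranking: MIQRanking, k: int) -> list[str]:
    """The first ``k`` feature names of the ranking, in rank order."""
    names = ranking.names()
    if not 1 <= k <= len(names):
        raise ValueError(f"k must be in [1, {len(names)}]")
    return names[:k]
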