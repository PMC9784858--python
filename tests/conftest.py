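import numpy as np
import pytest

import sleepcascade as sc
from sleepcascade.features import FEATURE_NAMES


@pytest.fixture(scope="session")
def small_dataset():
    """A balanced 20-epoch-per-stage synthetic dataset."""
    counts = {s: 20 for s in sc.SleepStage.order()}
    return sc.synth_dataset(counts=counts, seed=101)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    """Feature table of the small dataset (computed once per session)."""
    return sc.extract_feature_table(small_dataset)


@pytest.fixture(scope="session")
def small_split(small_features):
    features = small_features[list(FEATURE_NAMES)]
    labels = small_features["stage"].to_numpy(dtype=object)
    return features, labels


@pytest.fixture(scope="session")
def trained_cascade(small_split):
    features, labels = small_split
    ranking = sc.miq_rank(features, labels)
    model = sc.train_cascade(features, labels, ranking, sc.CascadeConfig(seed=3))
    return model, ranking
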