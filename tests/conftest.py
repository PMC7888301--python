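import numpy as np
import pytest

from stratnorm import (
    extract_features,
    generate_dataset,
    generate_feature_table,
    mini_config,
)
from stratnorm.io import EEGDataset, TrialRecord


@pytest.fixture(scope="session")
def mini_table():
    """Mini synthetic feature table: planted emotion effect under dominant
    per-stratum affine nuisance (72 rows, 32 features)."""
    table, truth = generate_feature_table(mini_config(seed=11))
    return table, truth


@pytest.fixture(scope="session")
def null_table():
    """Mini table with no emotion signal at all."""
    table, _ = generate_feature_table(
        mini_config(seed=12, emotion_effect=0.0, affected_fraction=0.0)
    )
    return table


def make_tiny_dataset(
    n_participants=2,
    n_sessions=1,
    n_trials=3,
    n_channels=2,
    fs=128.0,
    n_samples=256,
    seed=0,
):
    """Small hand-rolled raw dataset of white-noise trials."""
    rng = np.random.default_rng(seed)
    trials = []
    for p in range(1, n_participants + 1):
        for s in range(1, n_sessions + 1):
            for t in range(1, n_trials + 1):
                trials.append(
                    TrialRecord(
                        participant=p,
                        session=s,
                        trial=t,
                        label=(t - 1) % 3,
                        signal=rng.standard_normal(
                            (n_channels, n_samples)
                        ).astype(np.float32),
                    )
                )
    return EEGDataset(fs=fs, n_channels=n_channels, trials=trials)


@pytest.fixture
def tiny_dataset():
    return make_tiny_dataset()


@pytest.fixture(scope="session")
def mini_raw_features():
    """Welch and multitaper feature tables extracted from one mini raw
    synthetic dataset (shared across tests; extraction is the slow part)."""
    d = generate_dataset(mini_config(seed=21))
    return extract_features(d, "welch"), extract_features(d, "multitaper")
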