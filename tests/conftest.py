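import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make the oracles importable

from ssvepkit import SimulationConfig, generate_dataset
from ssvepkit.preprocessing import (
    PreprocessingConfig,
    preprocess_trial,
    segment_features,
    sliding_windows,
)


@pytest.fixture(scope="session")
def preproc():
    return PreprocessingConfig()


@pytest.fixture(scope="session")
def static_dataset():
    """Small static-condition dataset at the default 0 dB SNR."""
    return generate_dataset(SimulationConfig(trials_per_class=6, seed=42))


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Effectively noise-free trials (background 60 dB below the response)."""
    return generate_dataset(SimulationConfig(trials_per_class=4, snr_db=60.0, seed=7))


def split_and_featurize(dataset, preproc, n_test_per_class=1, shift_ms=60.0):
    """Per-class chronological split -> (train, test) segment arrays.

    The last ``n_test_per_class`` trials of each class are held out, so both
    splits contain every class.  Returns time-domain arrays, feature arrays
    and label vectors for both splits.
    """
    by_class: dict[float, list[int]] = {}
    for i, t in enumerate(dataset):
        by_class.setdefault(t.label, []).append(i)
    train_idx, test_idx = [], []
    for idxs in by_class.values():
        train_idx += idxs[:-n_test_per_class]
        test_idx += idxs[-n_test_per_class:]

    def prep(indices):
        segs = []
        for i in sorted(indices):
            trial = preprocess_trial(dataset[i], preproc)
            segs += sliding_windows(trial, preproc.window_seconds, shift_ms)
        labels = np.array([dataset[s.parent_trial].label for s in segs])
        time = np.stack([s.samples for s in segs])
        feats = segment_features(segs, preproc)
        return time, feats, labels

    return prep(train_idx), prep(test_idx)


@pytest.fixture(scope="session")
def static_split(static_dataset, preproc):
    return split_and_featurize(static_dataset, preproc)


@pytest.fixture(scope="session")
def noiseless_split(noiseless_dataset, preproc):
    return split_and_featurize(noiseless_dataset, preproc)
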