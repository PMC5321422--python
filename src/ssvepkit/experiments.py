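"""Canonical synthetic-data experiments at desk scale.

These functions bundle the study conditions used for validation: fixed
generator settings, chronological splits, the per-architecture training
recipes, and problem sizes small enough to run on one CPU in minutes.
The scaled-down sizes (tens of trials, 60 ms training shift) keep every
experiment's statistical question intact — they shrink the number of
windows, not the window length, channel count or feature grid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import networks
from .data import TrialSet
from .decoders import (
    CCADecoder,
    CCAKNNDecoder,
    FrequencyDecoder,
    MSIDecoder,
    NetworkDecoder,
)
from .evaluation import run_cross_validation
from .preprocessing import (
    PreprocessingConfig,
    preprocess_trial,
    segment_features,
    sliding_windows,
)
from .simulate import SimulationConfig, generate_dataset

__all__ = [
    "make_decoders",
    "prepare_split",
    "decoder_accuracies",
    "snr_sweep",
    "ambulatory_comparison",
]

ALL_DECODERS = ("cca", "msi", "cca_knn", "cnn1", "cnn2", "nn")


def make_decoders(
    names=ALL_DECODERS,
    frequencies=(9.0, 11.0, 13.0, 15.0, 17.0),
    sampling_rate: float = 1000.0,
    n_bins: int = 120,
    n_channels: int = 8,
    seed: int = 0,
) -> dict[str, FrequencyDecoder]:
    """Instantiate decoders by name with the default per-architecture recipes."""
    out: dict[str, FrequencyDecoder] = {}
    for name in names:
        if name in ("cnn1", "cnn2", "nn"):
            spec = networks.NetworkSpec(
                name, n_fs=n_bins, n_ch=n_channels, n_classes=len(frequencies)
            )
            out[name] = NetworkDecoder(spec, networks.default_training_config(name, seed))
        elif name == "cca":
            out[name] = CCADecoder(frequencies, sampling_rate)
        elif name == "msi":
            out[name] = MSIDecoder(frequencies, sampling_rate)
        elif name == "cca_knn":
            out[name] = CCAKNNDecoder(frequencies, sampling_rate)
        else:
            raise ValueError(f"unknown decoder {name!r}")
    return out


def prepare_split(
    dataset: TrialSet,
    preproc: PreprocessingConfig | None = None,
    n_test_per_class: int = 1,
    shift_ms: float = 60.0,
):
    """Per-class chronological split into (train, test) segment bundles.

    The last ``n_test_per_class`` trials of every class are held out, so both
    sides contain all classes.  Each bundle is a dict with ``time``
    (B, T, n_ch), ``features`` (B, n_fs, n_ch) and ``labels``.
    """
    preproc = preproc or PreprocessingConfig()
    by_class: dict[float, list[int]] = {}
    for i, t in enumerate(dataset):
        by_class.setdefault(t.label, []).append(i)
    train_idx, test_idx = [], []
    for idxs in by_class.values():
        train_idx += idxs[:-n_test_per_class]
        test_idx += idxs[-n_test_per_class:]

    def bundle(indices):
        segs = []
        for i in sorted(indices):
            trial = preprocess_trial(dataset[i], preproc)
            segs += sliding_windows(trial, preproc.window_seconds, shift_ms)
        return {
            "time": np.stack([s.samples for s in segs]),
            "features": segment_features(segs, preproc),
            "labels": np.array([dataset[s.parent_trial].label for s in segs]),
        }

    return bundle(train_idx), bundle(test_idx)


def decoder_accuracies(
    decoders: dict[str, FrequencyDecoder], train: dict, test: dict
) -> dict[str, float]:
    """Fit (where applicable) and score every decoder, accuracy in percent."""
    out = {}
    for name, dec in decoders.items():
        Xtr = train[dec.input_kind]
        Xte = test[dec.input_kind]
        if dec.needs_training:
            dec.fit(Xtr, train["labels"])
        out[name] = dec.score(Xte, test["labels"])
    return out


def snr_sweep(
    snr_grid=(-25.0, -20.0, -15.0, -10.0),
    names=ALL_DECODERS,
    trials_per_class: int = 6,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy of every decoder across a broadband-SNR grid (static regime).

    Returns a tidy frame (decoder, snr_db, accuracy, n_test).  Used to check
    that decoding quality is non-decreasing in SNR up to sampling noise.
    """
    rows = []
    for snr in snr_grid:
        cfg = SimulationConfig(trials_per_class=trials_per_class, snr_db=snr, seed=seed)
        train, test = prepare_split(generate_dataset(cfg))
        accs = decoder_accuracies(make_decoders(names, seed=seed), train, test)
        for name, acc in accs.items():
            rows.append(
                dict(decoder=name, snr_db=snr, accuracy=acc, n_test=test["labels"].size)
            )
    return pd.DataFrame(rows)


def ambulatory_comparison(
    trials_per_class: int = 4,
    snr_db: float = -15.0,
    n_folds: int = 10,
    train_shifts_ms=(60, 30),
    seed: int = 0,
):
    """Chronological CV of CNN-1 vs CCA on artifact-injected trials.

    Mirrors the qualitative comparison between the learned and the
    training-free decoder in the ambulatory regime, at desk scale.
    """
    cfg = SimulationConfig(
        trials_per_class=trials_per_class,
        snr_db=snr_db,
        condition="ambulatory",
        seed=seed,
    )
    trials = generate_dataset(cfg)
    decs = make_decoders(("cnn1", "cca"), seed=seed)
    return run_cross_validation(
        trials, decs, n_folds=n_folds, train_shifts_ms=train_shifts_ms, seed=seed
    )
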