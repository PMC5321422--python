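"""Core data containers for multi-channel EEG recordings, trials and spectral features.

The containers mirror the stages of an SSVEP decoding pipeline: a continuous
:class:`Recording`, cue-aligned :class:`Trial` objects grouped in a
:class:`TrialSet`, sliding-window :class:`Segment` views, and the
:class:`FeatureMatrix` (normalized FFT magnitudes) consumed by the neural
network classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "Trial",
    "TrialSet",
    "Segment",
    "FeatureMatrix",
    "load_recording_csv",
]

#: Conditions a trial can be recorded under.
CONDITIONS = ("static", "ambulatory")


def _as_time_by_channel(samples) -> np.ndarray:
    arr = np.asarray(samples, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"samples must be 2-D (time x channel), got shape {arr.shape}")
    return arr


@dataclass
class Recording:
    """Continuous multi-channel EEG.

    Parameters
    ----------
    samples
        Array of shape ``(n_times, n_channels)``, in microvolts.
    sampling_rate
        Sampling frequency in Hz (1000 Hz in the target acquisition setup).
    channel_labels
        Ordered channel names; defaults to the 8 occipital/parieto-occipital
        sites used for SSVEP acquisition.
    """

    samples: np.ndarray
    sampling_rate: float = 1000.0
    channel_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.samples = _as_time_by_channel(self.samples)
        if not np.isfinite(self.sampling_rate) or self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if self.n_channels < 1:
            raise ValueError("recording needs at least one channel")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")
        if self.channel_labels is None:
            self.channel_labels = tuple(f"ch{i}" for i in range(self.n_channels))
        else:
            self.channel_labels = tuple(self.channel_labels)
            if len(self.channel_labels) != self.n_channels:
                raise ValueError(
                    f"{len(self.channel_labels)} labels for {self.n_channels} channels"
                )

    @property
    def n_times(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_times / self.sampling_rate

    def copy_with(self, samples: np.ndarray) -> "Recording":
        return Recording(samples, self.sampling_rate, self.channel_labels)


@dataclass
class Trial:
    """A single cue-aligned stimulation trial.

    ``label`` is the attended flicker frequency in Hz (one of the five
    stimulation frequencies, 9/11/13/15/17 Hz by default).
    """

    samples: np.ndarray
    label: float
    sampling_rate: float = 1000.0
    condition: str = "static"
    trial_id: int = 0

    def __post_init__(self) -> None:
        self.samples = _as_time_by_channel(self.samples)
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.label = float(self.label)

    @property
    def n_times(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_times / self.sampling_rate


@dataclass
class TrialSet:
    """Chronologically ordered collection of labelled trials.

    All trials share sampling rate, channel count and condition.  The
    chronological order of ``trials`` is meaningful: the evaluation module
    splits folds as contiguous blocks of this sequence.
    """

    trials: list[Trial]
    class_frequencies: tuple[float, ...]
    condition: str = "static"

    def __post_init__(self) -> None:
        self.class_frequencies = tuple(sorted(float(f) for f in self.class_frequencies))
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        for t in self.trials:
            if t.label not in self.class_frequencies:
                raise ValueError(f"trial label {t.label} not in {self.class_frequencies}")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, idx):
        return self.trials[idx]

    @property
    def labels(self) -> np.ndarray:
        return np.array([t.label for t in self.trials])

    @property
    def sampling_rate(self) -> float:
        return self.trials[0].sampling_rate

    def subset(self, indices) -> "TrialSet":
        return TrialSet([self.trials[i] for i in indices], self.class_frequencies, self.condition)

    # -- container I/O ------------------------------------------------------

    def save_npz(self, path: str | Path) -> None:
        """Write all trials to a single NPZ container."""
        samples = np.stack([t.samples for t in self.trials])
        np.savez(
            path,
            samples=samples,
            labels=self.labels,
            trial_ids=np.array([t.trial_id for t in self.trials]),
            sampling_rate=np.array(self.sampling_rate),
            condition=np.array(self.condition),
            class_frequencies=np.array(self.class_frequencies),
        )

    @classmethod
    def load_npz(cls, path: str | Path) -> "TrialSet":
        with np.load(path, allow_pickle=False) as z:
            condition = str(z["condition"])
            rate = float(z["sampling_rate"])
            trials = [
                Trial(s, lab, rate, condition, int(tid))
                for s, lab, tid in zip(z["samples"], z["labels"], z["trial_ids"])
            ]
            return cls(trials, tuple(z["class_frequencies"]), condition)


@dataclass
class Segment:
    """A 2 s sliding-window cut of a trial (``window_length x n_channels``)."""

    samples: np.ndarray
    sampling_rate: float
    parent_trial: int = 0
    offset: int = 0

    def __post_init__(self) -> None:
        self.samples = _as_time_by_channel(self.samples)
        if self.offset < 0:
            raise ValueError("offset must be non-negative")

    @property
    def n_times(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


@dataclass
class FeatureMatrix:
    """Per-channel FFT magnitude features on a fixed frequency grid.

    ``values`` has shape ``(n_fs, n_ch)`` — by default 120 frequency samples
    covering 5–35 Hz by 8 channels.  After :func:`~ssvepkit.preprocessing.
    normalize_features` all values lie in [0, 1].
    """

    values: np.ndarray
    bin_frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.values = _as_time_by_channel(self.values)
        self.bin_frequencies = np.asarray(self.bin_frequencies, dtype=np.float64)
        if self.bin_frequencies.shape != (self.values.shape[0],):
            raise ValueError("bin_frequencies must have one entry per feature row")
        if np.any(np.diff(self.bin_frequencies) <= 0):
            raise ValueError("bin_frequencies must be strictly increasing")

    @property
    def n_fs(self) -> int:
        return self.values.shape[0]

    @property
    def n_ch(self) -> int:
        return self.values.shape[1]

    @property
    def is_normalized(self) -> bool:
        return bool(np.all(self.values >= 0.0) and np.all(self.values <= 1.0))


def load_recording_csv(path: str | Path, sampling_rate: float) -> Recording:
    """Read a toy recording from CSV: one column per channel, one row per sample."""
    df = pd.read_csv(path)
    return Recording(df.to_numpy(dtype=np.float64), sampling_rate, tuple(df.columns))
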