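"""Chronological k-fold cross-validation and training-size sweeps.

Folds are contiguous blocks of trials in chronological order — the standard
EEG protocol that preserves non-stationarity and prevents temporal leakage.
Trials are segmented *after* the trial-level split, so no 2 s window ever
spans the train/test boundary.  The test segmentation is fixed (10 ms shift,
300 windows per 5 s trial); the training-set size is swept by varying the
training shift (60/30/20/15/12/10 ms -> 50...300 windows per trial).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import Trial, TrialSet
from .decoders import FrequencyDecoder
from .preprocessing import (
    PreprocessingConfig,
    preprocess_trial,
    segment_features,
    sliding_windows,
)

__all__ = [
    "FoldPlan",
    "make_fold_plan",
    "build_training_sets",
    "EvaluationReport",
    "run_cross_validation",
    "training_size_trend",
]


@dataclass
class FoldPlan:
    """Chronological fold assignment: fold i tests on the i-th block."""

    n_folds: int
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train_idx, test_idx)

    def __iter__(self):
        return iter(self.folds)


def make_fold_plan(n_trials: int, n_folds: int = 10) -> FoldPlan:
    """Split ``n_trials`` chronologically ordered trials into contiguous folds.

    Each fold's test set is one contiguous block (sizes differ by at most one
    when ``n_trials`` is not divisible); all other trials train.  The folds
    partition the trials exactly.
    """
    if isinstance(n_trials, TrialSet):
        n_trials = len(n_trials)
    if n_folds < 1 or n_folds > n_trials:
        raise ValueError(f"n_folds must be in [1, {n_trials}], got {n_folds}")
    blocks = np.array_split(np.arange(n_trials), n_folds)
    folds = []
    for b in blocks:
        test = np.asarray(b)
        train = np.setdiff1d(np.arange(n_trials), test)
        assert np.intersect1d(train, test).size == 0
        folds.append((train, test))
    return FoldPlan(n_folds, folds)


def build_training_sets(
    trials: list[Trial], window: float = 2.0, shifts_ms=(60, 30, 20, 15, 12, 10)
) -> dict[float, list]:
    """Segment training trials once per shift size.

    Returns ``{shift_ms: [Segment, ...]}``; with the windowing convention
    used here, 45 static training trials give 2,250 segments at 60 ms and
    13,500 at 10 ms (and 225 ambulatory trials give 11,250...67,500).
    """
    out = {}
    for shift in shifts_ms:
        segs = []
        for t in trials:
            segs.extend(sliding_windows(t, window, shift))
        out[float(shift)] = segs
    return out


@dataclass
class EvaluationReport:
    """Per-fold accuracies for every classifier x training size.

    ``per_fold`` columns: classifier, train_shift_ms, n_train_segments,
    fold, accuracy (percent).  ``summary()`` aggregates to mean +- std and
    the accuracy difference against a baseline classifier (the parenthesized
    deltas convention).
    """

    per_fold: pd.DataFrame
    config: dict = field(default_factory=dict)

    def summary(self, baseline: str = "cnn1") -> pd.DataFrame:
        grp = (
            self.per_fold.groupby(["classifier", "train_shift_ms", "n_train_segments"])[
                "accuracy"
            ]
            .agg(["mean", "std"])
            .reset_index()
        )
        if baseline in set(grp["classifier"]):
            base = grp[grp["classifier"] == baseline].set_index("train_shift_ms")["mean"]
            grp["delta_vs_baseline"] = grp.apply(
                lambda r: r["mean"] - base.get(r["train_shift_ms"], np.nan), axis=1
            )
        return grp

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.per_fold.to_csv(path.with_suffix(".csv"), index=False)
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "records": self.per_fold.to_dict(orient="records"),
                },
                fh,
                indent=2,
                default=float,
            )


def _segments_to_array(segments) -> np.ndarray:
    return np.stack([s.samples for s in segments])


def run_cross_validation(
    trials: TrialSet,
    decoders: dict[str, FrequencyDecoder],
    n_folds: int = 10,
    train_shifts_ms=(60, 30, 20, 15, 12, 10),
    test_shift_ms: float = 10.0,
    preproc: PreprocessingConfig | None = None,
    seed: int = 0,
) -> EvaluationReport:
    """Chronological cross-validation of all decoders over a shift sweep.

    For every fold: the test trials (seeded random presentation order, which
    affects only logging) are segmented at ``test_shift_ms``; training trials
    are segmented at each training shift.  Trainable decoders are re-fit per
    (fold, shift); CCA and MSI have no training phase and are evaluated once
    per fold, with the same accuracy recorded at every training size.
    """
    preproc = preproc or PreprocessingConfig()
    rng = np.random.default_rng(seed)
    filtered = [preprocess_trial(t, preproc) for t in trials]
    plan = make_fold_plan(len(filtered), n_folds)
    records = []
    for fold_id, (train_idx, test_idx) in enumerate(plan):
        assert np.intersect1d(train_idx, test_idx).size == 0, "train/test leakage"
        test_order = rng.permutation(test_idx)
        test_segs = []
        for i in test_order:
            test_segs.extend(sliding_windows(filtered[i], preproc.window_seconds, test_shift_ms))
        y_test = np.array([filtered[s.parent_trial].label for s in test_segs])
        test_time = _segments_to_array(test_segs)
        test_feat = segment_features(test_segs, preproc)

        train_sets = build_training_sets(
            [filtered[i] for i in train_idx], preproc.window_seconds, train_shifts_ms
        )
        static_scores: dict[str, float] = {}
        for name, dec in decoders.items():
            if not dec.needs_training and name not in static_scores:
                X_test = test_time if dec.input_kind == "time" else test_feat
                static_scores[name] = dec.score(X_test, y_test)
        for shift, segs in train_sets.items():
            y_train = np.array([filtered[s.parent_trial].label for s in segs])
            feat_cache: dict[str, np.ndarray] = {}
            for name, dec in decoders.items():
                if dec.needs_training:
                    if dec.input_kind == "time":
                        X_train = feat_cache.setdefault("time", _segments_to_array(segs))
                        X_test = test_time
                    else:
                        X_train = feat_cache.setdefault(
                            "features", segment_features(segs, preproc)
                        )
                        X_test = test_feat
                    try:
                        acc = dec.fit(X_train, y_train).score(X_test, y_test)
                    except Exception as exc:  # record the failure, keep going
                        records.append(
                            dict(
                                classifier=name,
                                train_shift_ms=shift,
                                n_train_segments=len(segs),
                                fold=fold_id,
                                accuracy=np.nan,
                                error=str(exc),
                            )
                        )
                        continue
                else:
                    acc = static_scores[name]
                records.append(
                    dict(
                        classifier=name,
                        train_shift_ms=shift,
                        n_train_segments=len(segs),
                        fold=fold_id,
                        accuracy=acc,
                    )
                )
    df = pd.DataFrame.from_records(records)
    cfg = dict(
        n_folds=n_folds,
        train_shifts_ms=list(train_shifts_ms),
        test_shift_ms=test_shift_ms,
        seed=seed,
        n_trials=len(trials),
        preprocessing=preproc.to_dict(),
    )
    return EvaluationReport(df, cfg)


def training_size_trend(report: EvaluationReport, baseline: str = "cnn1") -> pd.DataFrame:
    """Accuracy-vs-training-size series per classifier, plus baseline deltas.

    Requires at least two training sizes in the report.  For decoders with
    no training phase the series is constant by construction.
    """
    summary = report.summary(baseline)
    if summary["n_train_segments"].nunique() < 2:
        raise ValueError("need at least two training sizes for a trend")
    return summary.sort_values(["classifier", "n_train_segments"]).reset_index(drop=True)
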