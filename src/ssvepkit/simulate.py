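"""Synthetic SSVEP generator.

Produces labelled multi-channel EEG trials with the statistical structure the
decoders assume: a sinusoidal steady-state response at the attended flicker
frequency plus its second harmonic, projected over the channels with a fixed
occipital-like gain profile, embedded in spatially correlated 1/f background
noise at a requested broadband SNR.

Two regimes are emulated:

* ``static`` — signal + background noise only (standing still);
* ``ambulatory`` — additionally, a Poisson process of artifact events models
  walking-induced contamination: low-frequency high-amplitude bursts (head
  swing / cable sway proxy) and short broadband spikes (connector /
  impedance transients proxy).

The artifact statistics are stand-ins: the ambulatory recordings these mimic
are characterized only qualitatively (heavy low-frequency and broadband
transients), so burst/spike rates, durations and amplitudes here are
plausible defaults, not measured quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import Trial, TrialSet

__all__ = ["SimulationConfig", "generate_trial", "generate_dataset"]

#: Default per-channel gain profile (PO7, PO3, POz, PO4, PO8, O1, Oz, O2):
#: slightly stronger response over midline occipital sites.
DEFAULT_CHANNEL_GAINS = (0.8, 0.9, 1.0, 0.9, 0.8, 1.0, 1.1, 1.0)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic SSVEP study.

    Defaults reproduce the acquisition conditions of the emulated
    experiment: five stimulation frequencies 9/11/13/15/17 Hz, 8 channels
    at 1 kHz, 5 s trials, 10 trials per class in the static task (50 per
    class in the ambulatory task).
    """

    class_frequencies: tuple[float, ...] = (9.0, 11.0, 13.0, 15.0, 17.0)
    n_channels: int = 8
    sampling_rate: float = 1000.0
    trial_seconds: float = 5.0
    trials_per_class: int = 10
    fundamental_amplitude: float = 1.0
    harmonic_ratio: float = 0.5
    channel_gains: tuple[float, ...] = DEFAULT_CHANNEL_GAINS
    noise_exponent: float = 1.0
    spatial_correlation: float = 0.3
    snr_db: float = 0.0
    condition: str = "static"
    artifact_rate: float = 1.0
    artifact_amplitude_factor: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_frequencies = tuple(float(f) for f in self.class_frequencies)
        if len(set(self.class_frequencies)) != len(self.class_frequencies):
            raise ValueError("class frequencies must be distinct")
        nyq = self.sampling_rate / 2.0
        if any(not 0 < f < nyq for f in self.class_frequencies):
            raise ValueError(f"class frequencies must lie in (0, {nyq}) Hz")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if self.trials_per_class < 1:
            raise ValueError("trials_per_class must be >= 1")
        if self.condition not in ("static", "ambulatory"):
            raise ValueError("condition must be 'static' or 'ambulatory'")
        if len(self.channel_gains) != self.n_channels:
            if self.channel_gains == DEFAULT_CHANNEL_GAINS:
                # non-default channel count: fall back to uniform gains
                self.channel_gains = tuple(np.ones(self.n_channels))
            else:
                raise ValueError("channel_gains length must equal n_channels")

    @property
    def n_times(self) -> int:
        return int(round(self.trial_seconds * self.sampling_rate))

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _one_over_f_noise(rng: np.random.Generator, n: int, n_ch: int, alpha: float) -> np.ndarray:
    """Gaussian 1/f^alpha noise, unit RMS per channel, independent channels."""
    white = rng.standard_normal((n, n_ch))
    spec = np.fft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1]  # keep DC finite; it is removed by band-pass anyway
    spec *= freqs[:, None] ** (-alpha / 2.0)
    noise = np.fft.irfft(spec, n=n, axis=0)
    return noise / noise.std(axis=0, keepdims=True)


def _mix_spatially(noise: np.ndarray, correlation: float) -> np.ndarray:
    """Impose a uniform cross-channel correlation on independent noise."""
    n_ch = noise.shape[1]
    cov = np.full((n_ch, n_ch), correlation)
    np.fill_diagonal(cov, 1.0)
    return noise @ np.linalg.cholesky(cov).T


def _raised_cosine_burst(rng: np.random.Generator, rate: float) -> np.ndarray:
    """Low-frequency artifact burst: Hann envelope x sub-8 Hz sinusoid, 0.5-2 s."""
    dur = rng.uniform(0.5, 2.0)
    n = max(int(round(dur * rate)), 8)
    f = rng.uniform(0.5, 7.0)
    t = np.arange(n) / rate
    envelope = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / n))
    return envelope * np.sin(2.0 * np.pi * f * t + rng.uniform(0.0, 2.0 * np.pi))


def _broadband_spike(rng: np.random.Generator, rate: float) -> np.ndarray:
    """Short broadband transient: Hann-windowed white noise, 10-50 ms."""
    dur = rng.uniform(0.010, 0.050)
    n = max(int(round(dur * rate)), 4)
    envelope = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / n))
    return envelope * rng.standard_normal(n)


def _add_artifacts(samples: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator) -> None:
    """Superimpose a Poisson process of artifact events, in place."""
    n, n_ch = samples.shape
    background_rms = samples.std()
    n_events = rng.poisson(cfg.artifact_rate * cfg.trial_seconds)
    for _ in range(n_events):
        if rng.random() < 0.5:
            wave = _raised_cosine_burst(rng, cfg.sampling_rate)
        else:
            wave = _broadband_spike(rng, cfg.sampling_rate)
        amp = cfg.artifact_amplitude_factor * background_rms * rng.uniform(0.5, 1.5)
        onset = rng.integers(0, n)
        end = min(onset + wave.size, n)
        # common waveform with random per-channel coupling strength
        coupling = rng.uniform(0.3, 1.0, size=n_ch)
        samples[onset:end] += amp * wave[: end - onset, None] * coupling[None, :]


def generate_trial(cfg: SimulationConfig, label: float, seed: int) -> Trial:
    """Generate one 5 s trial for the given stimulation frequency.

    The SSVEP component is ``gain_c * [A sin(2*pi*f*t + phi1) +
    A*harmonic_ratio * sin(2*pi*2f*t + phi2)]`` with trial-random phases
    (cue-to-stimulus phase is uncontrolled in the emulated experiment).
    Background noise is scaled so that total signal RMS over total noise RMS
    matches ``snr_db``.  Bit-identical for identical ``(cfg, label, seed)``.
    """
    label = float(label)
    if label not in cfg.class_frequencies:
        raise ValueError(f"label {label} not in configured classes {cfg.class_frequencies}")
    rng = np.random.default_rng(seed)
    n = cfg.n_times
    t = np.arange(n) / cfg.sampling_rate
    gains = np.asarray(cfg.channel_gains)

    phi1, phi2 = rng.uniform(0.0, 2.0 * np.pi, size=2)
    wave = cfg.fundamental_amplitude * (
        np.sin(2.0 * np.pi * label * t + phi1)
        + cfg.harmonic_ratio * np.sin(2.0 * np.pi * 2.0 * label * t + phi2)
    )
    sig = wave[:, None] * gains[None, :]

    noise = _mix_spatially(_one_over_f_noise(rng, n, cfg.n_channels, cfg.noise_exponent),
                           cfg.spatial_correlation)
    sig_rms = np.sqrt(np.mean(sig**2))
    noise_rms = np.sqrt(np.mean(noise**2))
    if sig_rms > 0:
        noise *= sig_rms / (noise_rms * 10.0 ** (cfg.snr_db / 20.0))
    # with a zero-amplitude signal the trial is pure unit-RMS noise

    samples = sig + noise
    if cfg.condition == "ambulatory":
        _add_artifacts(samples, cfg, rng)
    return Trial(samples, label, cfg.sampling_rate, cfg.condition)


def generate_dataset(cfg: SimulationConfig) -> TrialSet:
    """Generate a full labelled dataset: ``trials_per_class`` trials per class.

    Trials appear in a seeded random chronological order (auditory cues were
    presented in random order in the emulated tasks); labels are exactly
    balanced.  Deterministic for a fixed config.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5EED]))
    labels = np.repeat(cfg.class_frequencies, cfg.trials_per_class)
    order = rng.permutation(labels.size)
    trial_seeds = rng.integers(0, 2**31, size=labels.size)
    trials = []
    for tid, idx in enumerate(order):
        trial = generate_trial(cfg, labels[idx], int(trial_seeds[tid]))
        trial.trial_id = tid
        trials.append(trial)
    return TrialSet(trials, cfg.class_frequencies, cfg.condition)
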