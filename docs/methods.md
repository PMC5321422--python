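# Methods

This note records the models implemented in `ssvepkit`, the parameter
choices that matter, and the places where the design was genuinely open.

## Preprocessing

Raw trials pass through a zero-phase front end before feature extraction:
a 2nd-order IIR notch at 60 Hz (Q = 30) and a 4th-order Butterworth
band-pass, 4–40 Hz, both applied forward–backward (`sosfiltfilt`) so they
introduce no group delay. These are conventional EEG defaults; both designs
and all edges are configurable (`PreprocessingConfig`). Recordings shorter
than the filters' padding headroom are rejected explicitly rather than
silently truncated.

**Windowing convention.** A trial of T samples is cut into 2 s windows with
shift s using `count = floor((T − W)/s)` — deliberately *without* the
customary `+1`. This is the convention under which a 5 s trial at 1 kHz
yields exactly 50/100/150/200/250/300 windows at 60/30/20/15/12/10 ms
shifts, and fold-level totals of 1,500 (static) and 7,500 (ambulatory) test
windows and 2,250–13,500 / 11,250–67,500 training windows. A trial exactly
one window long therefore yields zero windows; callers needing that window
should request it directly.

**Spectral features.** A 2 s window at 1 kHz natively gives 0.5 Hz
resolution — only 61 bins in 5–35 Hz, not the 120 the classifiers use. The
feature extractor therefore zero-pads each window to 0.25 Hz resolution
(n_fft = 4000) and keeps the 120 bins 5.00–34.75 Hz. This is the smallest
modification consistent with a 120-bin grid on that band; the pad factor
follows from the requested `(band, n_bins)` so other grids behave the same.
Features are magnitudes (|FFT|, not power), then min–max normalized to
[0, 1] **per channel** within each window, so no channel's amplitude scale
dominates; whole-matrix scope is available. A constant channel normalizes
to zeros, and normalization is idempotent.

## Network architectures and training

The three classifiers are implemented directly in numpy — forward pass and
backpropagation — so every gradient is checkable against central finite
differences (the suite verifies every parameter of reduced versions of all
three architectures to ≤ 1e-5 relative error).

* C1 applies one 1×N_ch kernel per map at every frequency position
  (a channel-combining, spatial filter): N_ch weights + 1 bias per map.
* C2 is a valid (no padding) convolution along frequency with kernel
  length 11, summing over all input maps: 120 → 110 units per map. As
  printed, the layer's weight indexing would give all eight output maps the
  same kernels, differing only by bias — making the maps nearly redundant.
  The default therefore gives each output map its own kernel bank
  (standard convolutional semantics); `c2_shared_kernel=True` selects the
  literal shared reading, and both are covered by the gradient checks.
* The output (and, in CNN-2, the 3-unit F3 bottleneck) layers are dense.
  All units, including outputs, are logistic sigmoids; predicted class =
  argmax over the 5 output units, exact ties resolving to the lowest class
  index.

**Initialization** is uniform on ±√(6/(N_in + N_out)) — the stated bound is
the uniform-initialization bound of the normalized scheme, and a normal
distribution cannot be supported "on an interval", so uniform is the
coherent reading. Conv layers use fan_in = in_maps × kernel, fan_out =
out_maps × kernel; dense layers use their fan-in/fan-out. Biases start at 0.

**Training** is plain gradient descent at rate 0.1 for at most 50
iterations, one iteration being a full pass over the training data, with an
early stop once the training error rate has improved by less than 0.5
percentage points over the trailing 10 iterations (so the earliest stop is
iteration 11). The loss is mean squared error between the sigmoid outputs
and one-hot targets by default, with sigmoid cross-entropy as an option;
"error rate" in the stopping rule is the training misclassification rate.

Two choices here were open and were settled empirically, once:

* **Update scheme.** The default is per-sample (online) stochastic descent,
  the scheme of the classic backpropagation literature. A single full-batch
  step per iteration is also available but cannot reduce the error within a
  50-step budget at rate 0.1, and mid-sized mini-batches converge only for
  some initializations; per-sample updates converged for every architecture,
  seed and SNR probed.
* **CNN-2 recipe.** The 3-unit bottleneck starts on a plateau in which the
  outputs match the class priors while the bottleneck weights carry no
  class information; with MSE the plateau regularly outlasts the 10-iteration
  stopping window. Per-sample updates with the cross-entropy loss traverse
  it within a few iterations, so `default_training_config("cnn2")` selects
  that recipe. The learning rate, iteration budget and stopping rule are
  identical for all architectures.

## Reference decoders

All three comparators score a window X (T × N_ch) against per-class
reference sets Y_f (T × 4): sin/cos at f and 2f, sampled at t = 1/S … T/S —
the fundamental-plus-second-harmonic composition characteristic of SSVEPs.
They operate on the same band-passed 2 s windows the networks see (before
FFT), and have no training phase except the KNN stage.

* **CCA** solves the symmetric generalized eigenproblem
  C_xy C_yy⁻¹ C_yx w = ρ² C_xx w on sample covariances of the centered
  sets; the largest ρ is the score and the detected class is its argmax
  over frequencies. A trace-scaled ridge (default 1e-8) keeps rank-deficient
  windows (e.g. a dead channel) solvable; with the ridge at 0 the
  implementation matches an independent QR-whitening + SVD oracle to ≤ 1e-8.
* **CCA-KNN** stores training windows' ρ-vectors verbatim and classifies by
  Euclidean k-nearest neighbours. k is chosen from {1, 3, 5, 7} by
  leave-one-out accuracy on the training set (plain training accuracy would
  always pick k = 1, since every stored point is its own nearest
  neighbour). Vote ties resolve to the nearest neighbour's label, then to
  the lowest class.
* **MSI** standardizes each column of X and Y, forms the joint correlation
  matrix C of [X, Y], whitens it with the block-diagonal transform built
  from the inverse square roots of the within-set blocks (R = U C Uᵀ), and
  computes S = 1 + Σ λ′ log λ′ / log d from eigenvalues normalized to unit
  sum. S is 0 for independent sets (R = I) and approaches 1 as the joint
  correlation degenerates to one direction; near-singular blocks get an
  eigenvalue floor. This block-whitening construction is the standard
  formulation of the S-estimator for two multivariate sets and is adopted
  here as the package's reading.

## Synthetic SSVEP generator

The generator emulates the acquisition conditions the decoders target:
five classes (9/11/13/15/17 Hz), 8 channels at 1 kHz, 5 s trials, 10 trials
per class in the static task and 50 per class in the ambulatory task.

Each trial is `gain ⊗ [A sin(2πft + φ₁) + rA sin(4πft + φ₂)] + noise`:

* harmonic ratio r = 0.5 — the second harmonic clearly present but weaker
  than the fundamental, as in occipital SSVEP spectra;
* per-channel gains follow a fixed occipital-like profile (midline sites
  slightly stronger); phases are randomized per trial, since cue-to-stimulus
  phase is uncontrolled in the emulated paradigm;
* background noise is 1/f^α Gaussian noise (α = 1), drawn independently per
  channel and mixed to a uniform cross-channel correlation of 0.3 —
  EEG-plausible values, as no noise model is given for the original
  recordings;
* `snr_db` fixes total signal RMS over total noise RMS; the default 0 dB
  makes the broadband amplitudes comparable while the *per-bin* spectral
  contrast remains strong, which is why all decoders are near-perfect there
  and differences appear only below roughly −10 dB.

The **ambulatory regime** adds a Poisson process (1 event/s) of two
artifact types: 0.5–2 s Hann-enveloped sub-8 Hz bursts (head-swing/cable
proxy) and 10–50 ms broadband spikes (connector/impedance proxy), at 5×
background RMS with random per-channel coupling. These statistics are
explicitly stand-ins — the contamination of real exoskeleton recordings is
characterized only qualitatively — so passing tests show robustness to
*this* artifact model, not to every real-world artifact. Other unmodelled
features of real EEG: inter-subject variability, non-stationary drifts,
alpha-band structure, and stimulus duty-cycle waveform shape (only its
harmonic consequence is modelled).

Determinism: a dataset is a pure function of its `SimulationConfig`
(including `seed`); per-trial seeds are spawned from the dataset seed, and
`generate_trial(cfg, label, seed)` is bit-reproducible under numpy's
Generator contract.

## Evaluation protocol

Folds are contiguous chronological blocks (sizes differing by at most one
when the trial count is not divisible); segmentation happens after the
trial-level split, and the train/test trial-id intersection is asserted
empty at runtime. Test trials are presented in a seeded random order, which
affects only logging. The test segmentation is fixed at the 10 ms shift;
training size is swept via the training shift. CCA and MSI are evaluated
once per fold and reported constant across training sizes, since they have
no training phase. Reports carry per-fold accuracies so any significance
test can be applied externally; for synthetic data, "subjects" are replaced
by independent generator replicates (seeds) and labelled as such.

## Problem sizes for the shipped experiments

The `experiments` module pins the desk-scale study conditions used by the
test suite and `scripts/acceptance.py`: 4–10 trials per class, the 60 ms
training shift (50 windows per trial), per-class chronological hold-outs,
and a −25…−10 dB grid for the SNR sweep — sizes chosen so each experiment
answers its statistical question in minutes on one CPU. Scaling down
reduces the number of windows only; window length, channel count, the
feature grid and all model topologies are the full-size ones.

## Known limitations

* The generator's artifact statistics are plausible stand-ins, not fitted
  to measured contamination; absolute accuracies on synthetic data are not
  comparable to accuracies on real recordings.
* CNN-2's trainability depends on escaping its bottleneck plateau before
  the early-stopping window closes; with MSE and large batches it can stop
  at chance. The shipped recipe avoids this, but the fragility is inherent
  to the 3-unit bottleneck + 0.5 pp/10-iteration rule combination.
* The CCA/MSI implementations assume 2 s windows long enough that sample
  covariances are well-conditioned after the trace ridge; very short
  windows may need a larger ridge.
* No artifact-removal preprocessing (ICA etc.) is applied, by design; the
  robustness question is posed to the classifiers directly.
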