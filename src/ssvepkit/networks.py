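"""From-scratch sigmoid networks for spectral SSVEP classification.

Three architectures operate on the 120 x 8 normalized FFT feature matrix:

* **CNN-1** — C1: 8 maps, each a shared 1 x N_ch channel-combining kernel
  applied at every frequency position; C2: valid convolution along frequency
  with an 11-tap kernel per (output map, input map) pair, 120 -> 110 units
  per map; L3: dense 8*110 -> 5 output units.
* **CNN-2** — identical C1/C2, then F3: a dense 3-unit bottleneck used to
  visualize the learned representation; L4: dense 3 -> 5.
* **NN** — plain feedforward net on the flattened 960-vector: 500 -> 100 -> 5.

Every unit uses the logistic sigmoid.  Training is plain gradient descent
with error backpropagation (no momentum, dropout or pooling), learning rate
0.1, at most 50 iterations with an early-stopping rule on the training error
rate.  All forward/backward arithmetic is written directly in numpy so the
gradients can be verified against finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "NetworkSpec",
    "TrainingConfig",
    "TrainedModel",
    "sigmoid",
    "init_weights",
    "forward",
    "loss_and_grads",
    "train",
    "predict",
    "predict_proba",
    "extract_activations",
    "n_parameters",
]

ARCHITECTURES = ("cnn1", "cnn2", "nn")


def sigmoid(s):
    """Logistic function 1 / (1 + exp(-s)); saturates without overflow."""
    s = np.asarray(s, dtype=np.float64)
    out = np.empty_like(s)
    pos = s >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-s[pos]))
    es = np.exp(s[~pos])
    out[~pos] = es / (1.0 + es)
    return out


@dataclass
class NetworkSpec:
    """Topology of one of the three architectures.

    ``c2_shared_kernel=True`` selects the literal reading of the C2 layer in
    which a single 11-tap kernel bank is shared by all output maps (they then
    differ only by bias); the default gives each output map its own kernels,
    the standard convolutional-layer semantics.
    """

    architecture: str = "cnn1"
    n_fs: int = 120
    n_ch: int = 8
    c1_maps: int = 8
    c2_kernel: int = 11
    f3_units: int = 3
    nn_hidden: tuple[int, ...] = (500, 100)
    n_classes: int = 5
    c2_shared_kernel: bool = False

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.architecture != "nn" and self.c2_units < 1:
            raise ValueError("c2 kernel longer than the feature axis")
        if self.architecture == "cnn2" and self.f3_units < 1:
            raise ValueError("cnn2 requires f3_units >= 1")

    @property
    def c2_units(self) -> int:
        """Length of each C2 map: valid convolution, n_fs - kernel + 1."""
        return self.n_fs - self.c2_kernel + 1

    @property
    def input_size(self) -> int:
        """Flattened input length for the plain NN (n_fs * n_ch)."""
        return self.n_fs * self.n_ch

    def layer_names(self) -> tuple[str, ...]:
        if self.architecture == "cnn1":
            return ("c1", "c2", "out")
        if self.architecture == "cnn2":
            return ("c1", "c2", "f3", "out")
        return tuple(f"h{i+1}" for i in range(len(self.nn_hidden))) + ("out",)


@dataclass
class TrainingConfig:
    """Gradient-descent hyperparameters.

    ``stop_threshold`` is an error-rate decrease in *fraction* units
    (0.005 = 0.5 percentage points): training stops once the training error
    rate has improved by less than that over the last ``stop_window``
    iterations.  One iteration is one pass over the training set; the
    default ``batch_size=1`` is classic per-sample (online) stochastic
    descent, the scheme of the original backpropagation literature.  Larger
    mini-batches or ``batch_size=None`` (one full-batch step per iteration)
    are available, but at learning rate 0.1 and at most 50 iterations the
    per-sample scheme is what makes the budget sufficient: a lone full-batch
    step per iteration cannot drive the error down in 50 steps, and
    mid-sized batches converge only for some initializations.
    """

    learning_rate: float = 0.1
    max_iterations: int = 50
    stop_window: int = 10
    stop_threshold: float = 0.005
    loss: str = "mse"  # or "cross_entropy"
    batch_size: int | None = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.loss not in ("mse", "cross_entropy"):
            raise ValueError("loss must be 'mse' or 'cross_entropy'")


def default_training_config(architecture: str, seed: int = 0) -> TrainingConfig:
    """Per-architecture training recipe at the standard learning rate.

    CNN-1 and the plain NN train reliably with the defaults (mean-squared
    error, per-sample updates).  The CNN-2 bottleneck (3 units between 880
    and 5) starts on a plateau where the outputs match the class priors;
    per-sample updates with the cross-entropy loss traverse that plateau
    within a few iterations, where MSE stalls past the early-stopping
    window.
    """
    if architecture == "cnn2":
        return TrainingConfig(loss="cross_entropy", batch_size=1, seed=seed)
    return TrainingConfig(seed=seed)


# ---------------------------------------------------------------------------
# weight construction


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    """Uniform on +-sqrt(6 / (fan_in + fan_out)) — the classic normalized
    initialization; the bound formula is the uniform-distribution bound."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_weights(spec: NetworkSpec, seed: int = 0) -> dict[str, np.ndarray]:
    """Initialize all weight tensors; biases start at zero."""
    rng = np.random.default_rng(seed)
    w: dict[str, np.ndarray] = {}
    if spec.architecture in ("cnn1", "cnn2"):
        w["c1_w"] = _glorot(rng, (spec.c1_maps, spec.n_ch), spec.n_ch, spec.c1_maps)
        w["c1_b"] = np.zeros(spec.c1_maps)
        k_out = 1 if spec.c2_shared_kernel else spec.c1_maps
        fan_in = spec.c1_maps * spec.c2_kernel
        fan_out = k_out * spec.c2_kernel
        w["c2_w"] = _glorot(rng, (k_out, spec.c1_maps, spec.c2_kernel), fan_in, fan_out)
        w["c2_b"] = np.zeros(spec.c1_maps)
        flat = spec.c1_maps * spec.c2_units
        if spec.architecture == "cnn2":
            w["f3_w"] = _glorot(rng, (spec.f3_units, flat), flat, spec.f3_units)
            w["f3_b"] = np.zeros(spec.f3_units)
            w["out_w"] = _glorot(rng, (spec.n_classes, spec.f3_units), spec.f3_units, spec.n_classes)
        else:
            w["out_w"] = _glorot(rng, (spec.n_classes, flat), flat, spec.n_classes)
        w["out_b"] = np.zeros(spec.n_classes)
    else:
        sizes = (spec.input_size,) + tuple(spec.nn_hidden) + (spec.n_classes,)
        for i in range(len(sizes) - 1):
            name = f"h{i+1}" if i < len(sizes) - 2 else "out"
            w[f"{name}_w"] = _glorot(rng, (sizes[i + 1], sizes[i]), sizes[i], sizes[i + 1])
            w[f"{name}_b"] = np.zeros(sizes[i + 1])
    return w


def n_parameters(spec: NetworkSpec) -> int:
    """Trainable parameter count implied by the topology."""
    if spec.architecture in ("cnn1", "cnn2"):
        c1 = spec.c1_maps * (spec.n_ch + 1)
        k_out = 1 if spec.c2_shared_kernel else spec.c1_maps
        c2 = k_out * spec.c1_maps * spec.c2_kernel + spec.c1_maps
        flat = spec.c1_maps * spec.c2_units
        if spec.architecture == "cnn1":
            return c1 + c2 + spec.n_classes * (flat + 1)
        return (
            c1 + c2
            + spec.f3_units * (flat + 1)
            + spec.n_classes * (spec.f3_units + 1)
        )
    total = 0
    sizes = (spec.input_size,) + tuple(spec.nn_hidden) + (spec.n_classes,)
    for i in range(len(sizes) - 1):
        total += sizes[i + 1] * (sizes[i] + 1)
    return total


# ---------------------------------------------------------------------------
# forward / backward


def _check_input(spec: NetworkSpec, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 2:
        X = X[None]
    if X.shape[1:] != (spec.n_fs, spec.n_ch):
        raise ValueError(
            f"input shape {X.shape[1:]} does not match spec ({spec.n_fs}, {spec.n_ch})"
        )
    return X


def _c2_kernels(spec: NetworkSpec, w: dict[str, np.ndarray]) -> np.ndarray:
    """C2 kernels as (out_maps, in_maps, kernel), broadcasting shared mode."""
    k = w["c2_w"]
    if spec.c2_shared_kernel:
        return np.broadcast_to(k, (spec.c1_maps,) + k.shape[1:])
    return k


def forward(spec: NetworkSpec, w: dict[str, np.ndarray], X: np.ndarray) -> dict[str, np.ndarray]:
    """Forward pass for a batch.

    Returns every layer's activations: keys ``c1`` (B, maps, n_fs), ``c2``
    (B, maps, c2_units), ``f3`` (cnn2 only), ``h1``/``h2`` (nn), and ``out``
    (B, n_classes); plus ``c1_win`` (the sliding-window view used by C2,
    kept for backpropagation).
    """
    X = _check_input(spec, X)
    acts: dict[str, np.ndarray] = {"input": X}
    if spec.architecture in ("cnn1", "cnn2"):
        z1 = np.einsum("bpj,kj->bkp", X, w["c1_w"]) + w["c1_b"][:, None]
        x1 = sigmoid(z1)
        x1w = sliding_window_view(x1, spec.c2_kernel, axis=2)  # (B, in, units, k)
        z2 = np.einsum("bipj,kij->bkp", x1w, _c2_kernels(spec, w)) + w["c2_b"][:, None]
        x2 = sigmoid(z2)
        flat = x2.reshape(X.shape[0], -1)
        acts.update(c1=x1, c1_win=x1w, c2=x2)
        if spec.architecture == "cnn2":
            xf = sigmoid(flat @ w["f3_w"].T + w["f3_b"])
            acts["f3"] = xf
            acts["out"] = sigmoid(xf @ w["out_w"].T + w["out_b"])
        else:
            acts["out"] = sigmoid(flat @ w["out_w"].T + w["out_b"])
    else:
        x = X.reshape(X.shape[0], -1)
        for name in spec.layer_names():
            x = sigmoid(x @ w[f"{name}_w"].T + w[f"{name}_b"])
            acts[name] = x
        acts["out"] = x
    return acts


def _output_delta(out: np.ndarray, targets: np.ndarray, loss: str) -> tuple[float, np.ndarray]:
    """Per-sample-averaged loss and dL/dz at the output layer."""
    b = out.shape[0]
    if loss == "mse":
        value = 0.5 * np.sum((out - targets) ** 2) / b
        delta = (out - targets) * out * (1.0 - out) / b
    else:  # cross_entropy with sigmoid outputs
        eps = 1e-12
        value = -np.sum(
            targets * np.log(out + eps) + (1.0 - targets) * np.log(1.0 - out + eps)
        ) / b
        delta = (out - targets) / b
    return float(value), delta


def loss_and_grads(
    spec: NetworkSpec,
    w: dict[str, np.ndarray],
    X: np.ndarray,
    targets: np.ndarray,
    loss: str = "mse",
) -> tuple[float, dict[str, np.ndarray], np.ndarray]:
    """Loss, gradient for every weight tensor, and the output activations.

    Backpropagation written layer by layer; gradients are exact derivatives
    of the batch-mean loss (verified elsewhere against central finite
    differences).
    """
    X = _check_input(spec, X)
    targets = np.asarray(targets, dtype=np.float64)
    acts = forward(spec, w, X)
    value, delta = _output_delta(acts["out"], targets, loss)
    g: dict[str, np.ndarray] = {}

    if spec.architecture in ("cnn1", "cnn2"):
        x2 = acts["c2"]
        flat = x2.reshape(X.shape[0], -1)
        if spec.architecture == "cnn2":
            xf = acts["f3"]
            g["out_w"] = delta.T @ xf
            g["out_b"] = delta.sum(axis=0)
            d_f = (delta @ w["out_w"]) * xf * (1.0 - xf)
            g["f3_w"] = d_f.T @ flat
            g["f3_b"] = d_f.sum(axis=0)
            d_flat = d_f @ w["f3_w"]
        else:
            g["out_w"] = delta.T @ flat
            g["out_b"] = delta.sum(axis=0)
            d_flat = delta @ w["out_w"]
        d2 = d_flat.reshape(x2.shape) * x2 * (1.0 - x2)  # (B, maps, units)

        x1w = acts["c1_win"]
        kernels = _c2_kernels(spec, w)
        full = np.einsum("bkp,bipj->kij", d2, x1w)
        g["c2_w"] = full.sum(axis=0, keepdims=True) if spec.c2_shared_kernel else full
        g["c2_b"] = d2.sum(axis=(0, 2))

        x1 = acts["c1"]
        d1 = np.zeros_like(x1)
        units = spec.c2_units
        for j in range(spec.c2_kernel):
            d1[:, :, j : j + units] += np.einsum("bkp,ki->bip", d2, kernels[:, :, j])
        d1 *= x1 * (1.0 - x1)
        g["c1_w"] = np.einsum("bkp,bpj->kj", d1, X)
        g["c1_b"] = d1.sum(axis=(0, 2))
    else:
        names = spec.layer_names()
        inputs = [X.reshape(X.shape[0], -1)] + [acts[n] for n in names[:-1]]
        d = delta
        for i in range(len(names) - 1, -1, -1):
            g[f"{names[i]}_w"] = d.T @ inputs[i]
            g[f"{names[i]}_b"] = d.sum(axis=0)
            if i > 0:
                d = (d @ w[f"{names[i]}_w"]) * inputs[i] * (1.0 - inputs[i])

    if not np.isfinite(value):
        raise FloatingPointError(f"non-finite training loss ({value}); aborting")
    return value, g, acts["out"]


# ---------------------------------------------------------------------------
# training / prediction


@dataclass
class TrainedModel:
    """A trained network: topology, weights, class labels, learning history."""

    spec: NetworkSpec
    weights: dict[str, np.ndarray]
    classes: np.ndarray
    history: np.ndarray  # per-iteration training error rate, fractions
    stopped_at: int
    config: TrainingConfig

    def save_npz(self, path: str | Path) -> None:
        meta = {
            "architecture": self.spec.architecture,
            "n_fs": self.spec.n_fs,
            "n_ch": self.spec.n_ch,
            "c1_maps": self.spec.c1_maps,
            "c2_kernel": self.spec.c2_kernel,
            "f3_units": self.spec.f3_units,
            "nn_hidden": np.array(self.spec.nn_hidden),
            "n_classes": self.spec.n_classes,
            "c2_shared_kernel": self.spec.c2_shared_kernel,
        }
        np.savez(
            path,
            classes=self.classes,
            history=self.history,
            stopped_at=self.stopped_at,
            **{f"meta_{k}": np.asarray(v) for k, v in meta.items()},
            **{f"w_{k}": v for k, v in self.weights.items()},
        )

    @classmethod
    def load_npz(cls, path: str | Path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as z:
            spec = NetworkSpec(
                architecture=str(z["meta_architecture"]),
                n_fs=int(z["meta_n_fs"]),
                n_ch=int(z["meta_n_ch"]),
                c1_maps=int(z["meta_c1_maps"]),
                c2_kernel=int(z["meta_c2_kernel"]),
                f3_units=int(z["meta_f3_units"]),
                nn_hidden=tuple(int(v) for v in z["meta_nn_hidden"]),
                n_classes=int(z["meta_n_classes"]),
                c2_shared_kernel=bool(z["meta_c2_shared_kernel"]),
            )
            weights = {k[2:]: z[k] for k in z.files if k.startswith("w_")}
            return cls(
                spec, weights, z["classes"], z["history"], int(z["stopped_at"]),
                TrainingConfig(),
            )


def _one_hot(y_idx: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((y_idx.size, n_classes))
    out[np.arange(y_idx.size), y_idx] = 1.0
    return out


def _error_rate(spec, w, X, y_idx, batch: int = 4096) -> float:
    wrong = 0
    for start in range(0, X.shape[0], batch):
        out = forward(spec, w, X[start : start + batch])["out"]
        wrong += int(np.sum(np.argmax(out, axis=1) != y_idx[start : start + batch]))
    return wrong / X.shape[0]


def train(
    spec: NetworkSpec,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainingConfig | None = None,
) -> TrainedModel:
    """Train by gradient descent with error backpropagation.

    ``y`` holds class labels (stimulation frequencies); classes are the
    sorted unique labels.  One "iteration" is one pass over the training set
    (a single full-batch update by default).  Training stops at
    ``max_iterations`` or once the training error rate has dropped by less
    than ``stop_threshold`` over the trailing ``stop_window`` iterations.
    """
    cfg = cfg or TrainingConfig()
    X = _check_input(spec, X)
    classes, y_idx = np.unique(np.asarray(y), return_inverse=True)
    if classes.size != spec.n_classes:
        raise ValueError(
            f"data has {classes.size} classes but the spec expects {spec.n_classes}"
        )
    counts = np.bincount(y_idx, minlength=spec.n_classes)
    if np.any(counts == 0):
        raise ValueError("every class needs at least one training example")
    targets = _one_hot(y_idx, spec.n_classes)

    w = init_weights(spec, cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    history: list[float] = []
    for _ in range(cfg.max_iterations):
        if cfg.batch_size is None:
            _, grads, _ = loss_and_grads(spec, w, X, targets, cfg.loss)
            for k in w:
                w[k] -= cfg.learning_rate * grads[k]
        else:
            order = rng.permutation(X.shape[0])
            for start in range(0, X.shape[0], cfg.batch_size):
                sel = order[start : start + cfg.batch_size]
                _, grads, _ = loss_and_grads(spec, w, X[sel], targets[sel], cfg.loss)
                for k in w:
                    w[k] -= cfg.learning_rate * grads[k]
        history.append(_error_rate(spec, w, X, y_idx))
        if (
            len(history) > cfg.stop_window
            and history[-1 - cfg.stop_window] - history[-1] < cfg.stop_threshold
        ):
            break
    return TrainedModel(spec, w, classes, np.array(history), len(history), cfg)


def predict_proba(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Output-layer activations for a batch (B, n_classes)."""
    return forward(model.spec, model.weights, X)["out"]


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Predicted class labels; ties resolve to the lowest class index."""
    out = predict_proba(model, X)
    return model.classes[np.argmax(out, axis=1)]


def extract_activations(model: TrainedModel, X: np.ndarray, layer: str) -> np.ndarray:
    """Activations of one layer (C1/C2 maps, F3 bottleneck, hidden, output).

    Raises for layers absent from the architecture (e.g. F3 on CNN-1), so
    downstream feature-inspection code fails loudly rather than silently.
    """
    valid = set(model.spec.layer_names()) | {"out"}
    if model.spec.architecture in ("cnn1", "cnn2"):
        valid |= {"c1", "c2"}
    if layer not in valid:
        raise ValueError(
            f"layer {layer!r} not available in architecture {model.spec.architecture!r} "
            f"(available: {sorted(valid)})"
        )
    return forward(model.spec, model.weights, X)[layer]
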