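"""Reference SSVEP decoders: CCA, CCA-KNN and the MSI S-estimator.

These classical methods score a 2 s multi-channel EEG window against a bank
of sinusoidal reference sets — for each candidate frequency f_i the four
series sin(2*pi*f_i*t), cos(2*pi*f_i*t), sin(2*pi*2f_i*t), cos(2*pi*2f_i*t)
sampled at t = 1/S ... T/S (fundamental + second harmonic, the
characteristic SSVEP composition).

* CCA: the detected class is the frequency whose reference set attains the
  largest maximal canonical correlation with the window.  No training phase.
* CCA-KNN: the vector of the five canonical correlations is a feature vector
  classified by k-nearest neighbours (Euclidean metric); k is selected from
  {1, 3, 5, 7} on the training data.
* MSI: the S-estimator — one minus the normalized entropy of the eigenvalues
  of the whitened joint correlation matrix of window and reference —
  measures synchronization; classify by argmax over frequencies.

All three share the decoder interface used by the evaluation module, as do
the network classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.neighbors import NearestNeighbors

from . import networks
from .data import Segment

__all__ = [
    "ReferenceSignalSet",
    "build_reference_signals",
    "cca_max_correlation",
    "classify_cca",
    "cca_feature_vector",
    "CCAKNN",
    "msi_index",
    "classify_msi",
    "FrequencyDecoder",
    "CCADecoder",
    "CCAKNNDecoder",
    "MSIDecoder",
    "NetworkDecoder",
]


@dataclass
class ReferenceSignalSet:
    """Sin/cos reference quadruples (fundamental + 2nd harmonic) per class."""

    frequencies: tuple[float, ...]
    n_samples: int
    sampling_rate: float
    signals: dict[float, np.ndarray]  # f -> (T, 4)

    def __getitem__(self, f: float) -> np.ndarray:
        return self.signals[float(f)]


def build_reference_signals(
    frequencies, n_samples: int, sampling_rate: float
) -> ReferenceSignalSet:
    """Construct the reference bank for a window of ``n_samples`` points.

    Raises if any second harmonic reaches the Nyquist frequency.
    """
    frequencies = tuple(float(f) for f in frequencies)
    nyq = sampling_rate / 2.0
    for f in frequencies:
        if 2.0 * f >= nyq:
            raise ValueError(f"second harmonic of {f} Hz at/above Nyquist ({nyq} Hz)")
    t = np.arange(1, n_samples + 1) / sampling_rate
    signals = {
        f: np.column_stack(
            [
                np.sin(2 * np.pi * f * t),
                np.cos(2 * np.pi * f * t),
                np.sin(2 * np.pi * 2 * f * t),
                np.cos(2 * np.pi * 2 * f * t),
            ]
        )
        for f in frequencies
    }
    return ReferenceSignalSet(frequencies, n_samples, sampling_rate, signals)


def _segment_array(X) -> np.ndarray:
    if isinstance(X, Segment):
        X = X.samples
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("expected a (time x channel) array")
    return X


def cca_max_correlation(X, Y, ridge: float = 1e-8) -> float:
    """Largest canonical correlation between data window X and reference Y.

    Solved as the symmetric generalized eigenproblem
    ``C_xy C_yy^-1 C_yx w = rho^2 C_xx w`` on sample covariances of the
    centered sets.  ``ridge`` scales a trace-proportional Tikhonov term
    added to C_xx and C_yy so rank-deficient (e.g. constant-channel) windows
    stay solvable; the result is clipped to [0, 1].
    """
    X = _segment_array(X)
    Y = _segment_array(Y)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of samples")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    n = X.shape[0] - 1
    cxx = Xc.T @ Xc / n
    cyy = Yc.T @ Yc / n
    cxy = Xc.T @ Yc / n
    cxx += ridge * (np.trace(cxx) / cxx.shape[0] + 1e-300) * np.eye(cxx.shape[0])
    cyy += ridge * (np.trace(cyy) / cyy.shape[0] + 1e-300) * np.eye(cyy.shape[0])
    m = cxy @ linalg.solve(cyy, cxy.T, assume_a="pos")
    eigvals = linalg.eigh(m, cxx, eigvals_only=True)
    return float(np.sqrt(np.clip(eigvals[-1], 0.0, 1.0)))


def cca_feature_vector(X, refs: ReferenceSignalSet, ridge: float = 1e-8) -> np.ndarray:
    """Canonical correlations against every class reference, in frequency order."""
    X = _segment_array(X)
    return np.array([cca_max_correlation(X, refs[f], ridge) for f in refs.frequencies])


def classify_cca(X, refs: ReferenceSignalSet, ridge: float = 1e-8):
    """Detected frequency = argmax over class canonical correlations.

    Returns ``(label, rho_vector)``; an exact tie resolves to the lowest
    class index (lowest frequency).
    """
    rho = cca_feature_vector(X, refs, ridge)
    return refs.frequencies[int(np.argmax(rho))], rho


class CCAKNN:
    """k-nearest-neighbour classifier on canonical-correlation vectors.

    Training stores the feature vectors and labels verbatim.  If several k
    are offered, the one with the best leave-one-out accuracy on the
    training set is kept (smallest k wins ties).  Vote ties resolve to the
    nearest neighbour's label, then to the lowest class index.
    """

    def __init__(self, ks=(1, 3, 5, 7)):
        self.ks = tuple(int(k) for k in ks)
        self.k_: int | None = None

    def fit(self, features: np.ndarray, labels) -> "CCAKNN":
        features = np.asarray(features, dtype=np.float64)
        labels = np.asarray(labels)
        if features.ndim != 2:
            raise ValueError("features must be 2-D (n_samples x n_features)")
        usable = [k for k in self.ks if k <= features.shape[0] - 1]
        if not usable:
            raise ValueError(
                f"no usable k in {self.ks} for {features.shape[0]} training samples"
            )
        self.features_ = features
        self.labels_ = labels
        self.classes_ = np.unique(labels)
        self._nn = NearestNeighbors(n_neighbors=min(max(usable) + 1, features.shape[0]))
        self._nn.fit(features)
        if len(usable) == 1:
            self.k_ = usable[0]
        else:
            # leave-one-out: neighbour 0 of a training point is itself
            _, idx = self._nn.kneighbors(features)
            best_k, best_acc = usable[0], -1.0
            for k in usable:
                pred = np.array(
                    [self._vote(labels[row[1 : k + 1]]) for row in idx]
                )
                acc = float(np.mean(pred == labels))
                if acc > best_acc:
                    best_k, best_acc = k, acc
            self.k_ = best_k
        return self

    def _vote(self, neighbour_labels: np.ndarray):
        values, counts = np.unique(neighbour_labels, return_counts=True)
        winners = values[counts == counts.max()]
        if winners.size == 1:
            return winners[0]
        if neighbour_labels[0] in winners:  # nearest neighbour breaks the tie
            return neighbour_labels[0]
        return winners.min()

    def predict(self, features: np.ndarray) -> np.ndarray:
        if self.k_ is None:
            raise RuntimeError("fit before predict")
        features = np.asarray(features, dtype=np.float64)
        _, idx = self._nn.kneighbors(features, n_neighbors=self.k_)
        return np.array([self._vote(self.labels_[row]) for row in idx])


def _inv_sqrt(mat: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    vals, vecs = linalg.eigh(mat)
    vals = np.maximum(vals, floor * vals.max())
    return (vecs / np.sqrt(vals)) @ vecs.T


def msi_index(X, Y) -> float:
    """MSI S-estimator between a data window and one reference set.

    Both sets are standardized per column; the joint correlation matrix C of
    [X, Y] is whitened by the block-diagonal transform built from the
    inverse square roots of the within-set correlation blocks,
    R = U C U^T.  With eigenvalues of R normalized to unit sum,
    ``S = 1 + sum(lam * log(lam)) / log(dim)``: 0 for independent sets
    (R = identity), approaching 1 as the joint matrix degenerates to a
    single direction.  Near-singular blocks are regularized by an
    eigenvalue floor.
    """
    X = _segment_array(X)
    Y = _segment_array(Y)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of samples")
    Z = np.column_stack([X, Y])
    Z = Z - Z.mean(axis=0)
    sd = Z.std(axis=0)
    Z = Z / np.where(sd > 0, sd, 1.0)
    c = Z.T @ Z / Z.shape[0]
    p, q = X.shape[1], Y.shape[1]
    u = np.zeros_like(c)
    u[:p, :p] = _inv_sqrt(c[:p, :p])
    u[p:, p:] = _inv_sqrt(c[p:, p:])
    r = u @ c @ u.T
    lam = linalg.eigh(r, eigvals_only=True)
    lam = np.clip(lam, 0.0, None)
    lam = lam / lam.sum()
    nz = lam[lam > 0]
    return float(1.0 + np.sum(nz * np.log(nz)) / np.log(p + q))


def classify_msi(X, refs: ReferenceSignalSet):
    """Detected frequency = argmax over per-class S-estimators."""
    s = np.array([msi_index(X, refs[f]) for f in refs.frequencies])
    return refs.frequencies[int(np.argmax(s))], s


# ---------------------------------------------------------------------------
# uniform decoder interface


class FrequencyDecoder:
    """Common fit/predict/score surface for all five classifiers.

    ``input_kind`` declares whether the decoder consumes raw time-domain
    windows (``"time"``: array (B, T, n_ch)) or normalized spectral feature
    matrices (``"features"``: array (B, n_fs, n_ch)).
    """

    name: str = "decoder"
    needs_training: bool = True
    input_kind: str = "features"

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FrequencyDecoder":
        raise NotImplementedError

    def predict(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        """Accuracy in percent."""
        return 100.0 * float(np.mean(self.predict(X) == np.asarray(y)))


class CCADecoder(FrequencyDecoder):
    name = "cca"
    needs_training = False
    input_kind = "time"

    def __init__(self, frequencies, sampling_rate: float, ridge: float = 1e-8):
        self.frequencies = tuple(sorted(float(f) for f in frequencies))
        self.sampling_rate = float(sampling_rate)
        self.ridge = ridge
        self._refs: dict[int, ReferenceSignalSet] = {}

    def _refs_for(self, n: int) -> ReferenceSignalSet:
        if n not in self._refs:
            self._refs[n] = build_reference_signals(self.frequencies, n, self.sampling_rate)
        return self._refs[n]

    def fit(self, X, y):  # no training phase
        return self

    def features(self, X: np.ndarray) -> np.ndarray:
        refs = self._refs_for(X.shape[1])
        return np.stack([cca_feature_vector(x, refs, self.ridge) for x in X])

    def predict(self, X: np.ndarray) -> np.ndarray:
        rho = self.features(X)
        return np.array(self.frequencies)[np.argmax(rho, axis=1)]


class MSIDecoder(CCADecoder):
    name = "msi"
    needs_training = False
    input_kind = "time"

    def features(self, X: np.ndarray) -> np.ndarray:
        refs = self._refs_for(X.shape[1])
        return np.stack(
            [[msi_index(x, refs[f]) for f in self.frequencies] for x in X]
        )


class CCAKNNDecoder(CCADecoder):
    name = "cca_knn"
    needs_training = True
    input_kind = "time"

    def __init__(self, frequencies, sampling_rate: float, ks=(1, 3, 5, 7), ridge: float = 1e-8):
        super().__init__(frequencies, sampling_rate, ridge)
        self.ks = ks

    def fit(self, X, y):
        self._knn = CCAKNN(self.ks).fit(self.features(np.asarray(X)), y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._knn.predict(self.features(np.asarray(X)))


class NetworkDecoder(FrequencyDecoder):
    """Wraps one of the three networks behind the decoder interface."""

    needs_training = True
    input_kind = "features"

    def __init__(self, spec: networks.NetworkSpec, cfg: networks.TrainingConfig | None = None):
        self.spec = spec
        self.cfg = cfg or networks.default_training_config(spec.architecture)
        self.name = spec.architecture
        self.model_: networks.TrainedModel | None = None

    def fit(self, X, y):
        self.model_ = networks.train(self.spec, X, y, self.cfg)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("fit before predict")
        return networks.predict(self.model_, X)
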