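"""Uniform contract over trained feed-forward DNA sequence classifiers.

A classifier is viewed through three quantities only: the penultimate-layer
activation vector ``phi(x)``, the output-layer weight matrix ``w[k, i]``, and
the predicted class.  Distances between inputs are measured in penultimate
space with a weighted Euclidean metric whose weights come from the output
layer, so that two sequences are "close" exactly when the output classifier
cannot tell their hidden representations apart.

A small NumPy forward-pass engine (`SequentialModel` with convolutional,
dense, pooling and flatten layers) provides a concrete implementation of the
contract; externally trained networks can be loaded from the HDF5 container
(see :mod:`maxentseq.container`) or adapted by implementing the same
attributes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

__all__ = [
    "ALPHABET",
    "BASE_INDEX",
    "EncodedSequence",
    "MetricWeights",
    "Conv1D",
    "Dense",
    "Flatten",
    "GlobalMaxPool",
    "GlobalAvgPool",
    "SequentialModel",
    "encode_onehot",
    "decode",
    "metric_weights",
    "weighted_distance",
    "predict_class",
]


# ---------------------------------------------------------------------------
# Sequence encoding
# ---------------------------------------------------------------------------


def _bases_to_indices(bases: str) -> np.ndarray:
    if len(bases) == 0:
        raise ValueError("empty sequence cannot be encoded")
    idx = np.empty(len(bases), dtype=np.int64)
    for pos, b in enumerate(bases):
        try:
            idx[pos] = BASE_INDEX[b]
        except KeyError:
            raise ValueError(
                f"ambiguous or invalid base {b!r} at position {pos}; "
                f"only A,C,G,T are accepted"
            ) from None
    return idx


def _as_freq_array(freqs) -> np.ndarray:
    """Coerce per-nucleotide genome frequencies to a length-4 array (A,C,G,T)."""
    if isinstance(freqs, dict):
        arr = np.array([freqs[b] for b in ALPHABET], dtype=float)
    else:
        arr = np.asarray(freqs, dtype=float)
    if arr.shape != (4,):
        raise ValueError("freqs must supply one frequency per nucleotide A,C,G,T")
    if np.any(arr <= 0) or np.any(arr >= 1):
        raise ValueError("nucleotide frequencies must lie strictly in (0, 1)")
    return arr


def encoding_rows(freqs=None) -> np.ndarray:
    """4x4 table: row b is the encoding of nucleotide b.

    Raw mode returns the identity (one-hot).  With genome frequencies ``f``
    supplied, entry ``x`` of the one-hot row is standardized to
    ``(x - f) / (f (1 - f))`` using the frequency of the entry's nucleotide
    column, matching the mean-centred input preprocessing used for long-input
    networks.
    """
    eye = np.eye(4)
    if freqs is None:
        return eye
    f = _as_freq_array(freqs)
    return (eye - f[None, :]) / (f * (1.0 - f))[None, :]


@dataclass(frozen=True)
class EncodedSequence:
    """A DNA sequence over {A,C,G,T} plus its L x 4 numeric encoding."""

    bases: str
    encoding: np.ndarray
    standardized: bool = False
    freqs: np.ndarray | None = None

    @property
    def length(self) -> int:
        return len(self.bases)

    @property
    def indices(self) -> np.ndarray:
        return _bases_to_indices(self.bases)

    def row_table(self) -> np.ndarray:
        """Per-base encoding rows consistent with this sequence's mode."""
        return encoding_rows(self.freqs if self.standardized else None)


def encode_onehot(bases: str, freqs=None) -> EncodedSequence:
    """Encode a DNA string as one-hot, optionally standardized.

    Parameters
    ----------
    bases:
        Sequence over {A,C,G,T}.  Ambiguity codes are rejected with the
        offending position named.
    freqs:
        Per-nucleotide genome frequencies (dict keyed by base or length-4
        array in A,C,G,T order).  When given, each entry x becomes
        ``(x - f) / (f (1 - f))``.
    """
    idx = _bases_to_indices(bases)
    rows = encoding_rows(freqs)
    enc = rows[idx]
    return EncodedSequence(
        bases=bases,
        encoding=enc,
        standardized=freqs is not None,
        freqs=None if freqs is None else _as_freq_array(freqs),
    )


def decode(encoding: np.ndarray) -> str:
    """Recover the base string from a raw one-hot (or standardized) encoding.

    The hottest entry per row identifies the base, which is exact for both
    raw one-hot rows and standardized rows (the "hot" column always carries
    the row maximum).
    """
    enc = np.asarray(encoding)
    if enc.ndim != 2 or enc.shape[1] != 4:
        raise ValueError("encoding must be an L x 4 matrix")
    return "".join(ALPHABET[i] for i in np.argmax(enc, axis=1))


# ---------------------------------------------------------------------------
# Forward-pass engine
# ---------------------------------------------------------------------------


def _activate(z: np.ndarray, name: str) -> np.ndarray:
    if name == "linear":
        return z
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    if name == "softmax":
        e = np.exp(z - np.max(z))
        return e / e.sum()
    raise ValueError(f"unknown activation {name!r}")


@dataclass
class Conv1D:
    """1-D convolution over the position axis, stride 1, valid padding.

    ``weights`` has shape (filters, width, 4); input (L, 4) maps to
    (L - width + 1, filters).
    """

    weights: np.ndarray
    bias: np.ndarray
    activation: str = "relu"

    kind = "conv1d"

    def forward(self, x: np.ndarray) -> np.ndarray:
        w = self.weights
        n_out = x.shape[0] - w.shape[1] + 1
        if n_out < 1:
            raise ValueError("input shorter than convolution width")
        windows = np.lib.stride_tricks.sliding_window_view(x, w.shape[1], axis=0)
        # windows: (n_out, 4, width) ; weights: (F, width, 4)
        z = np.einsum("pcw,fwc->pf", windows, w, optimize=True) + self.bias
        return _activate(z, self.activation)


@dataclass
class Dense:
    """Fully connected layer: weights (units_out, units_in)."""

    weights: np.ndarray
    bias: np.ndarray
    activation: str = "linear"

    kind = "dense"

    def forward(self, x: np.ndarray) -> np.ndarray:
        z = self.weights @ x + self.bias
        return _activate(z, self.activation)


@dataclass
class Flatten:
    kind = "flatten"

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.ravel(x)  # row-major: position-major, filter-minor


@dataclass
class GlobalMaxPool:
    kind = "global_max_pool"

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.max(x, axis=0)


@dataclass
class GlobalAvgPool:
    kind = "global_avg_pool"

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.mean(x, axis=0)


class SequentialModel:
    """Concrete PenultimateModel: a stack of layers ending in a Dense output.

    The final layer is the output classifier (sigmoid for a single output
    unit, softmax for K >= 2); everything before it defines the penultimate
    representation ``phi``.
    """

    def __init__(self, layers: Sequence, input_length: int | None):
        if not layers or not isinstance(layers[-1], Dense):
            raise ValueError("model must end in a Dense output layer")
        self.layers = list(layers)
        # None marks a length-agnostic model (e.g. conv + global pooling)
        self.input_length = None if input_length is None else int(input_length)

    # -- contract -----------------------------------------------------------

    @property
    def output_layer(self) -> Dense:
        return self.layers[-1]

    @property
    def output_weights(self) -> np.ndarray:
        """K x P output weight matrix w[k, i]."""
        return self.output_layer.weights

    @property
    def n_classes(self) -> int:
        k = self.output_weights.shape[0]
        return int(k)

    def _coerce(self, seq) -> np.ndarray:
        if isinstance(seq, EncodedSequence):
            if self.input_length is not None and seq.length != self.input_length:
                raise ValueError(
                    f"sequence length {seq.length} does not match model "
                    f"input length {self.input_length}"
                )
            return seq.encoding
        x = np.asarray(seq, dtype=float)
        if x.ndim != 2 or x.shape[1] != 4:
            raise ValueError("expected an (L, 4) encoding")
        if self.input_length is not None and x.shape[0] != self.input_length:
            raise ValueError("expected an (input_length, 4) encoding")
        return x

    def phi(self, seq) -> np.ndarray:
        """Penultimate-layer activation vector Phi(x)."""
        x = self._coerce(seq)
        for layer in self.layers[:-1]:
            x = layer.forward(x)
        x = np.ravel(x)
        if x.shape[0] != self.output_weights.shape[1]:
            raise ValueError("penultimate size does not match output weights")
        return x

    def output(self, seq) -> np.ndarray:
        return self.output_layer.forward(self.phi(seq))

    def predict(self, seq) -> int:
        return predict_class(self, seq)


# ---------------------------------------------------------------------------
# Metric
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricWeights:
    """Per-unit weights W_i of the penultimate activation metric."""

    W: np.ndarray
    anchor_class: int = 0
    contrast_class: int | None = None


def metric_weights(model, anchor_class: int = 0, contrast_class: int | None = None) -> MetricWeights:
    """Metric weights from the output layer.

    Single-output (K = 1) networks and binary classifiers use the weight row
    feeding the anchor class's output unit.  Multiclass networks contrast the
    anchor class against a user-chosen class k: W = w[anchor] - w[k], which
    weights each penultimate unit by its effect on the log-odds between the
    two classes.
    """
    w = np.asarray(model.output_weights, dtype=float)
    k = w.shape[0]
    if not 0 <= anchor_class < max(k, 1):
        raise ValueError(f"anchor_class {anchor_class} out of range for K={k}")
    if contrast_class is not None and contrast_class == anchor_class:
        raise ValueError("contrast_class must differ from anchor_class")
    if k == 1:
        return MetricWeights(W=w[0].copy(), anchor_class=anchor_class)
    if contrast_class is None:
        if k >= 3:
            raise ValueError("contrast_class is required for K >= 3 classifiers")
        contrast_class = 1 - anchor_class
    if not 0 <= contrast_class < k:
        raise ValueError(f"contrast_class {contrast_class} out of range for K={k}")
    return MetricWeights(
        W=w[anchor_class] - w[contrast_class],
        anchor_class=anchor_class,
        contrast_class=contrast_class,
    )


def weighted_distance(phi0: np.ndarray, phi: np.ndarray, weights: MetricWeights) -> float:
    """Weighted Euclidean distance sqrt(sum_i W_i^2 (phi0_i - phi_i)^2)."""
    a = np.asarray(phi0, dtype=float)
    b = np.asarray(phi, dtype=float)
    w = weights.W if isinstance(weights, MetricWeights) else np.asarray(weights, float)
    if a.shape != b.shape or a.shape != w.shape:
        raise ValueError("activation vectors and metric weights must have equal length")
    diff = a - b
    return float(np.sqrt(np.sum((w * diff) ** 2)))


def predict_class(model, seq) -> int:
    """Predicted class: argmax of output activations.

    Single-output sigmoid networks threshold at 0.5 (class 1 iff output
    > 0.5).  Exact ties break deterministically to the lowest class index.
    """
    out = np.asarray(model.output(seq), dtype=float)
    if out.shape[0] == 1:
        return int(out[0] > 0.5)
    return int(np.argmax(out))
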