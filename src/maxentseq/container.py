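"""HDF5 model container: portable storage for SequentialModel networks.

Layout::

    /                     attrs: input_length, alphabet="ACGT", class_count
    /layers/<n>           attrs: type, activation
    /layers/<n>/weights   dataset (layer-type specific shape)
    /layers/<n>/bias      dataset

Layer types: conv1d, dense, flatten, global_max_pool, global_avg_pool.
"""

from __future__ import annotations

import h5py
import numpy as np

from .network import (
    ALPHABET,
    Conv1D,
    Dense,
    Flatten,
    GlobalAvgPool,
    GlobalMaxPool,
    SequentialModel,
)

__all__ = ["save_model", "load_model"]

_POOLS = {"global_max_pool": GlobalMaxPool, "global_avg_pool": GlobalAvgPool}


def save_model(model: SequentialModel, path) -> None:
    with h5py.File(path, "w") as f:
        # -1 marks a length-agnostic model (conv + global pooling)
        f.attrs["input_length"] = -1 if model.input_length is None else model.input_length
        f.attrs["alphabet"] = ALPHABET
        f.attrs["class_count"] = model.n_classes
        grp = f.create_group("layers")
        for n, layer in enumerate(model.layers):
            g = grp.create_group(str(n))
            g.attrs["type"] = layer.kind
            if layer.kind in ("conv1d", "dense"):
                g.attrs["activation"] = layer.activation
                g.create_dataset("weights", data=np.asarray(layer.weights, float))
                g.create_dataset("bias", data=np.asarray(layer.bias, float))


def load_model(path) -> SequentialModel:
    with h5py.File(path, "r") as f:
        alphabet = f.attrs["alphabet"]
        if isinstance(alphabet, bytes):
            alphabet = alphabet.decode()
        if alphabet != ALPHABET:
            raise ValueError(f"container alphabet {alphabet!r} != {ALPHABET!r}")
        input_length = int(f.attrs["input_length"])
        if input_length < 0:
            input_length = None
        grp = f["layers"]
        layers = []
        for n in sorted(grp, key=int):
            g = grp[n]
            kind = g.attrs["type"]
            if isinstance(kind, bytes):
                kind = kind.decode()
            if kind in ("conv1d", "dense"):
                act = g.attrs["activation"]
                if isinstance(act, bytes):
                    act = act.decode()
                cls = Conv1D if kind == "conv1d" else Dense
                layers.append(
                    cls(weights=g["weights"][()], bias=g["bias"][()], activation=act)
                )
            elif kind == "flatten":
                layers.append(Flatten())
            elif kind in _POOLS:
                layers.append(_POOLS[kind]())
            else:
                raise ValueError(f"unsupported layer type {kind!r} in container")
        model = SequentialModel(layers, input_length=input_length)
        if model.n_classes != int(f.attrs["class_count"]):
            raise ValueError("container class_count disagrees with output layer")
        return model
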