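"""Compile a declarative architecture spec into an executable network.

The network is a small DAG evaluated in spec order (specs are topologically
sorted by construction).  Reverse-mode gradients are accumulated per node,
which covers branch concatenation and DenseNet-style fan-out.
"""

from __future__ import annotations

import numpy as np

from .._rng import rng_for
from ..arch import ArchitectureSpec, FreezePlan
from . import layers as L

__all__ = ["Network", "compile_network"]

_KIND_TO_LAYER = {
    "maxpool": lambda s: L.Pool2D(s.name, pool=s.params.get("pool", 2), stride=s.params.get("stride"), mode="max"),
    "avgpool": lambda s: L.Pool2D(s.name, pool=s.params.get("pool", 2), stride=s.params.get("stride"), mode="avg"),
    "batchnorm": lambda s: L.BatchNorm(s.name),
    "concat": lambda s: L.Concat(s.name),
    "flatten": lambda s: L.Flatten(s.name),
    "gap": lambda s: L.GlobalAvgPool(s.name),
    "dropout": lambda s: L.Dropout(s.name, rate=s.params["rate"]),
    "activation": lambda s: L.Activation(s.name, fn=s.params["fn"]),
}


class Network:
    """Executable model: named layers, forward/backward, freeze control."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        self.seed = int(seed)
        self.layers: dict[str, L.Layer] = {}
        self._inputs: dict[str, list] = {}
        shapes = {"input": tuple(spec.input_shape)}
        for idx, ls in enumerate(spec.layers):
            in_shapes = [shapes[i] for i in ls.inputs]
            layer = self._make(ls, in_shapes)
            layer.init_params(rng_for(self.seed, "init", idx))
            if isinstance(layer, L.Dropout):
                layer.rng = rng_for(self.seed, "dropout", idx)
            self.layers[ls.name] = layer
            self._inputs[ls.name] = list(ls.inputs)
            shapes[ls.name] = tuple(ls.output_shape)
        self._order = [ls.name for ls in spec.layers]

    @staticmethod
    def _make(ls, in_shapes):
        kind = ls.kind
        if kind == "conv":
            layer = L.Conv2D(
                ls.name,
                filters=ls.params["filters"],
                kernel=ls.params.get("kernel", 3),
                stride=ls.params.get("stride", 1),
                activation=ls.params.get("activation"),
            )
            layer.build(in_shapes[0][-1])
        elif kind == "depthwise-conv":
            layer = L.DepthwiseConv2D(
                ls.name,
                kernel=ls.params.get("kernel", 3),
                stride=ls.params.get("stride", 1),
                activation=ls.params.get("activation"),
            )
            layer.build(in_shapes[0][-1])
        elif kind == "dense":
            layer = L.Dense(ls.name, units=ls.params["units"])
            layer.build(in_shapes[0][0])
        elif kind == "sigmoid-output":
            layer = L.SigmoidOutput(ls.name)
            layer.build(in_shapes[0][0])
        elif kind in _KIND_TO_LAYER:
            layer = _KIND_TO_LAYER[kind](ls)
            if isinstance(layer, L.BatchNorm):
                layer.build(in_shapes[0][-1])
        else:
            raise ValueError(f"cannot compile layer kind {kind!r}")
        return layer

    # -- execution ----------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Evaluate the network; caches per-layer outputs for backward."""
        outs: dict[str, np.ndarray] = {"input": x.astype(np.float32, copy=False)}
        for name in self._order:
            xs = [outs[i] for i in self._inputs[name]]
            outs[name] = self.layers[name].forward(xs, training=training)
        self._fwd_outputs = outs
        return outs[self._order[-1]]

    def backward(self, grad_out: np.ndarray) -> None:
        """Backpropagate from the final layer; accumulates fan-out grads."""
        pending: dict[str, np.ndarray] = {self._order[-1]: grad_out}
        for name in reversed(self._order):
            g = pending.pop(name, None)
            if g is None:
                continue
            in_grads = self.layers[name].backward(g)
            for src, gi in zip(self._inputs[name], in_grads):
                if src == "input":
                    continue
                if src in pending:
                    pending[src] = pending[src] + gi
                else:
                    pending[src] = gi

    def backward_from_bce(self, y_true: np.ndarray) -> None:
        """Backward pass seeded by the mean-BCE gradient at the sigmoid output."""
        out_name = self._order[-1]
        out_layer = self.layers[out_name]
        if not isinstance(out_layer, L.SigmoidOutput):
            raise TypeError("network does not end in a sigmoid output layer")
        n = y_true.shape[0]
        in_grads = out_layer.backward_from_bce(y_true.astype(np.float32), n)
        pending: dict[str, np.ndarray] = {}
        for src, gi in zip(self._inputs[out_name], in_grads):
            if src != "input":
                pending[src] = gi
        for name in reversed(self._order[:-1]):
            g = pending.pop(name, None)
            if g is None:
                continue
            in_grads = self.layers[name].backward(g)
            for src, gi in zip(self._inputs[name], in_grads):
                if src == "input":
                    continue
                if src in pending:
                    pending[src] = pending[src] + gi
                else:
                    pending[src] = gi

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Inference-mode probabilities, batched."""
        chunks = [
            self.forward(x[i : i + batch_size], training=False)
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(chunks)

    # -- parameters & freezing ---------------------------------------------
    def trainable_layers(self):
        return [self.layers[n] for n in self._order]

    def snapshot(self) -> dict:
        """Bitwise copy of every parameter array, keyed (layer, param)."""
        return {
            (n, p): v.copy()
            for n in self._order
            for p, v in self.layers[n].params.items()
        }

    def freeze_layers(self, names) -> None:
        for n in names:
            self.layers[n].trainable = False

    def apply_freeze_plan(self, plan: FreezePlan) -> None:
        """Freeze every layer belonging to the plan's frozen units."""
        plan.validate_against(self.spec)
        umap = self.spec.unit_map()
        for unit in plan.frozen_units:
            self.freeze_layers(umap[unit])

    def frozen_layer_names(self) -> list:
        return [n for n in self._order if not self.layers[n].trainable]


def compile_network(spec: ArchitectureSpec, seed: int = 0) -> Network:
    """Materialize a spec as an executable network with seeded random init."""
    return Network(spec, seed=seed)
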