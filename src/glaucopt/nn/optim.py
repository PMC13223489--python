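"""First-order optimizers of the hyperparameter search space.

Five gradient-descent variants are searchable (SGD, RMSprop, Adam, Adamax,
Nadam).  Defaults follow the common deep-learning conventions: 1e-3 for the
adaptive methods, 1e-2 for plain SGD.  Each optimizer steps only the layers
left trainable, so freeze plans reduce to membership in the step loop.
"""

from __future__ import annotations

import numpy as np

__all__ = ["make_optimizer", "OPTIMIZERS"]


class _Optimizer:
    def __init__(self, lr):
        self.lr = lr
        self.t = 0
        self.state: dict[tuple[str, str], dict] = {}

    def step(self, layers) -> None:
        """One update over all trainable parameters, in declaration order."""
        self.t += 1
        for layer in layers:
            if not layer.trainable:
                continue
            for pname, p in layer.params.items():
                g = layer.grads.get(pname)
                if g is None:
                    continue
                s = self.state.setdefault((layer.name, pname), self._init(p))
                self._update(p, g.astype(p.dtype), s)

    def _init(self, p):  # pragma: no cover - interface
        raise NotImplementedError

    def _update(self, p, g, s):  # pragma: no cover - interface
        raise NotImplementedError


class SGD(_Optimizer):
    def __init__(self, lr=1e-2):
        super().__init__(lr)

    def _init(self, p):
        return {}

    def _update(self, p, g, s):
        p -= self.lr * g


class RMSprop(_Optimizer):
    def __init__(self, lr=1e-3, rho=0.9, eps=1e-7):
        super().__init__(lr)
        self.rho, self.eps = rho, eps

    def _init(self, p):
        return {"v": np.zeros_like(p)}

    def _update(self, p, g, s):
        s["v"] = self.rho * s["v"] + (1 - self.rho) * g * g
        p -= self.lr * g / (np.sqrt(s["v"]) + self.eps)


class Adam(_Optimizer):
    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        super().__init__(lr)
        self.b1, self.b2, self.eps = beta1, beta2, eps

    def _init(self, p):
        return {"m": np.zeros_like(p), "v": np.zeros_like(p)}

    def _update(self, p, g, s):
        b1, b2, t = self.b1, self.b2, self.t
        s["m"] = b1 * s["m"] + (1 - b1) * g
        s["v"] = b2 * s["v"] + (1 - b2) * g * g
        mhat = s["m"] / (1 - b1**t)
        vhat = s["v"] / (1 - b2**t)
        p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Adamax(_Optimizer):
    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        super().__init__(lr)
        self.b1, self.b2, self.eps = beta1, beta2, eps

    def _init(self, p):
        return {"m": np.zeros_like(p), "u": np.zeros_like(p)}

    def _update(self, p, g, s):
        b1, t = self.b1, self.t
        s["m"] = b1 * s["m"] + (1 - b1) * g
        s["u"] = np.maximum(self.b2 * s["u"], np.abs(g))
        p -= self.lr * s["m"] / ((1 - b1**t) * (s["u"] + self.eps))


class Nadam(_Optimizer):
    """Adam with a Nesterov look-ahead on the first moment."""

    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        super().__init__(lr)
        self.b1, self.b2, self.eps = beta1, beta2, eps

    def _init(self, p):
        return {"m": np.zeros_like(p), "v": np.zeros_like(p)}

    def _update(self, p, g, s):
        b1, b2, t = self.b1, self.b2, self.t
        s["m"] = b1 * s["m"] + (1 - b1) * g
        s["v"] = b2 * s["v"] + (1 - b2) * g * g
        mhat = s["m"] / (1 - b1 ** (t + 1))
        vhat = s["v"] / (1 - b2**t)
        look = b1 * mhat + (1 - b1) * g / (1 - b1**t)
        p -= self.lr * look / (np.sqrt(vhat) + self.eps)


OPTIMIZERS = {
    "sgd": SGD,
    "rmsprop": RMSprop,
    "adam": Adam,
    "adamax": Adamax,
    "nadam": Nadam,
}


def make_optimizer(name: str, lr: float | None = None) -> _Optimizer:
    """Instantiate an optimizer by its search-space name."""
    key = name.lower()
    if key not in OPTIMIZERS:
        raise ValueError(f"unknown optimizer {name!r}; choose from {sorted(OPTIMIZERS)}")
    cls = OPTIMIZERS[key]
    return cls() if lr is None else cls(lr=lr)
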