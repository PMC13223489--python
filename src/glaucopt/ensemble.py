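"""Dirichlet-sampled weighted-average ensembling.

The ensemble prediction is the convex combination of the member models'
glaucoma probabilities,

    Y_E = sum_i  w_i * Y_i ,        w on the (K-1)-simplex,

and candidate weight vectors are drawn from a Dirichlet distribution with
density

    f(w; alpha) = Gamma(sum alpha_i) / prod Gamma(alpha_i)
                  * prod w_i^(alpha_i - 1).

Two hundred sampled vectors (the reference trial budget), quantized to four
decimal places, are scored by thresholded validation accuracy; the first
trial attaining the maximum wins.  The all-ones default concentration
explores the simplex uniformly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._rng import rng_for

__all__ = [
    "WeightVector",
    "DirichletParams",
    "ModelPredictions",
    "EnsembleResult",
    "dirichlet_pdf",
    "sample_weights",
    "quantize",
    "weighted_average_predict",
    "search_weights",
]

_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class WeightVector:
    """Point on the simplex; ``quantized`` marks 4-decimal resolution."""

    weights: tuple
    quantized: bool = False

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or len(w) < 1:
            raise ValueError("weights must be a 1-d sequence")
        if np.any(w < -_SIMPLEX_TOL) or np.any(w > 1 + _SIMPLEX_TOL):
            raise ValueError(f"weights must lie in [0, 1], got {self.weights}")
        tol = 1e-4 if self.quantized else _SIMPLEX_TOL
        if abs(w.sum() - 1.0) > tol:
            raise ValueError(f"weights must sum to 1, got sum {w.sum()!r}")
        if self.quantized and not np.allclose(w, np.round(w, 4), atol=1e-12):
            raise ValueError("quantized weights must have 4-decimal resolution")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)

    def __len__(self):
        return len(self.weights)


@dataclass(frozen=True)
class DirichletParams:
    """Concentration parameters; K models (the reference ensemble has 3)."""

    alpha: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        a = np.asarray(self.alpha, dtype=float)
        if len(a) < 2:
            raise ValueError("need at least 2 models")
        if np.any(a <= 0):
            raise ValueError(f"all concentration parameters must be positive, got {self.alpha}")

    @property
    def n_models(self) -> int:
        return len(self.alpha)


@dataclass
class ModelPredictions:
    """Per-model glaucoma probabilities over one sample set, plus labels.

    ``probs`` has shape (K models, n samples); ``labels`` are 0/1 with
    glaucoma = 1 (string labels are accepted and mapped).
    """

    probs: np.ndarray
    labels: np.ndarray
    model_names: list = field(default_factory=list)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        labels = np.asarray(self.labels)
        if labels.dtype.kind in "US":
            labels = (labels == "glaucoma").astype(int)
        self.labels = labels.astype(int)
        if self.probs.ndim != 2:
            raise ValueError("probs must be 2-d (models x samples)")
        if self.probs.shape[1] != len(self.labels):
            raise ValueError(
                f"length mismatch: {self.probs.shape[1]} predictions vs {len(self.labels)} labels"
            )
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if not self.model_names:
            self.model_names = [f"model{i + 1}" for i in range(self.probs.shape[0])]
        if len(self.model_names) != self.probs.shape[0]:
            raise ValueError("one name per model required")

    @property
    def n_models(self) -> int:
        return self.probs.shape[0]

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"sample_id": np.arange(len(self.labels)), "label": self.labels})
        for name, p in zip(self.model_names, self.probs):
            df[f"p_{name}"] = p
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ModelPredictions":
        df = pd.read_csv(path)
        pcols = [c for c in df.columns if c.startswith("p_")]
        if not pcols:
            raise ValueError(f"{path} has no p_<model> columns")
        return cls(
            probs=df[pcols].to_numpy().T,
            labels=df["label"].to_numpy(),
            model_names=[c[2:] for c in pcols],
        )


def dirichlet_pdf(w: WeightVector, params: DirichletParams) -> float:
    """Dirichlet density at a simplex point.

    Boundary points (some w_i = 0) are allowed only when the matching
    alpha_i >= 1; with alpha_i < 1 the density is unbounded there and an
    error is raised.
    """
    wv = w.as_array()
    a = np.asarray(params.alpha, dtype=float)
    if len(wv) != len(a):
        raise ValueError(f"dimension mismatch: {len(wv)} weights vs {len(a)} alphas")
    if abs(wv.sum() - 1.0) > 1e-6:
        raise ValueError(f"w is off the simplex (sum {wv.sum()!r})")
    zero = wv <= 0
    if np.any(zero & (a < 1)):
        raise ValueError("density is unbounded: some w_i = 0 with alpha_i < 1")
    if np.any(zero & (a > 1)):
        return 0.0
    mask = ~zero
    log_norm = gammaln(a.sum()) - gammaln(a).sum()
    log_kernel = np.sum((a[mask] - 1.0) * np.log(wv[mask]))
    return float(np.exp(log_norm + log_kernel))


def sample_weights(params: DirichletParams, n_trials: int = 200, seed: int = 0) -> list:
    """``n_trials`` raw simplex draws; identical for identical seeds."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = rng_for(seed, "dirichlet")
    draws = rng.dirichlet(np.asarray(params.alpha, dtype=float), size=n_trials)
    return [WeightVector(tuple(row), quantized=False) for row in draws]


def quantize(w: WeightVector) -> WeightVector:
    """Round to 4 decimals, assigning the rounding residual to the largest
    weight (lowest index on ties) so the quantized sum is exactly 1.0000."""
    rounded = np.round(w.as_array(), 4)
    residual = round(1.0 - rounded.sum(), 4)
    k = int(np.argmax(rounded))  # argmax takes the lowest index on ties
    rounded[k] = round(rounded[k] + residual, 4)
    return WeightVector(tuple(rounded), quantized=True)


def weighted_average_predict(preds: ModelPredictions, w: WeightVector) -> np.ndarray:
    """Convex combination of the member probabilities, elementwise."""
    if len(w) != preds.n_models:
        raise ValueError(f"{len(w)} weights for {preds.n_models} models")
    return w.as_array() @ preds.probs


@dataclass
class EnsembleResult:
    best_weights: WeightVector
    best_accuracy: float
    trial_log: list  # of (WeightVector, accuracy)
    winning_trial_index: int  # 1-based

    def to_dict(self) -> dict:
        return {
            "best_weights": list(self.best_weights.weights),
            "best_accuracy": self.best_accuracy,
            "winning_trial_index": self.winning_trial_index,
            "trial_log": [
                {"weights": list(w.weights), "accuracy": a} for w, a in self.trial_log
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


def search_weights(
    preds: ModelPredictions,
    params: DirichletParams | None = None,
    n_trials: int = 200,
    seed: int = 0,
    threshold: float = 0.5,
) -> EnsembleResult:
    """Score sampled-and-quantized weight vectors by ensemble accuracy.

    Each trial's weights are drawn from the Dirichlet, quantized to 4
    decimals, applied to the member predictions and scored at the
    classification threshold (ties positive).  Returns the first trial
    attaining the maximum accuracy.
    """
    if preds.probs.shape[1] == 0:
        raise ValueError("empty predictions")
    y = preds.labels
    if preds.n_models == 1:
        # degenerate ensemble: the single model with weight 1
        w = WeightVector((1.0,), quantized=True)
        acc = float(np.mean((preds.probs[0] >= threshold).astype(int) == y))
        return EnsembleResult(
            best_weights=w,
            best_accuracy=acc,
            trial_log=[(w, acc)],
            winning_trial_index=1,
        )
    if params is None:
        params = DirichletParams(alpha=(1.0,) * preds.n_models)
    if params.n_models != preds.n_models:
        raise ValueError(
            f"{params.n_models} concentration parameters for {preds.n_models} models"
        )
    log = []
    best_idx, best_acc = 0, -1.0
    for i, raw in enumerate(sample_weights(params, n_trials, seed), start=1):
        w = quantize(raw)
        p = weighted_average_predict(preds, w)
        acc = float(np.mean((p >= threshold).astype(int) == y))
        log.append((w, acc))
        if acc > best_acc:
            best_idx, best_acc = i, acc
    return EnsembleResult(
        best_weights=log[best_idx - 1][0],
        best_accuracy=best_acc,
        trial_log=log,
        winning_trial_index=best_idx,
    )
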