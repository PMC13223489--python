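"""Bayesian optimization of the classifier-head hyperparameters.

A sequential search over the 7-dimensional head space (8 with the conv
activation of the from-scratch extractor): after ``n_initial`` random
configurations, a Gaussian-process surrogate (scikit-learn, Matern 5/2 +
white noise; categorical dimensions one-hot encoded, integer dimensions
relaxed to continuous and rounded) is fit to all observed (config,
validation accuracy) pairs, and the next configuration maximizes Expected
Improvement over a random candidate set.  The objective is the validation
accuracy of a head trained for a short budget (16 epochs in the reference
setting); a failing trial scores 0 and the run continues, so a 40-iteration
trace is always complete.
"""

from __future__ import annotations

import inspect
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from ._rng import derive_seed, rng_for
from .arch import (
    ACTIVATION_CHOICES,
    OPTIMIZER_CHOICES,
    HEAD_RANGES,
    ArchitectureSpec,
    HeadConfig,
    build_backbone,
    build_classifier,
    build_multibranch_extractor,
)
from .train import TrainConfig, accuracy, fit, load_images
from .nn import compile_network

__all__ = [
    "SearchSpace",
    "BOTrial",
    "BOTrace",
    "expected_improvement",
    "run_bo",
    "make_training_objective",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchSpace:
    """The head hyperparameter box.

    Integer dimensions: dense blocks 1-5, dense nodes 32-1024.  Continuous:
    dropout 0.2-0.5.  Categorical: batch norm on/off, flatten vs global
    average pooling, activation, optimizer, and (only when
    ``include_conv_activation``) the shared conv activation of the
    from-scratch extractor.
    """

    include_conv_activation: bool = False

    def sample(self, rng: np.random.Generator) -> HeadConfig:
        lo_b, hi_b = HEAD_RANGES["n_dense_blocks"]
        lo_n, hi_n = HEAD_RANGES["n_dense_nodes"]
        lo_d, hi_d = HEAD_RANGES["dropout_rate"]
        return HeadConfig(
            n_dense_blocks=int(rng.integers(lo_b, hi_b + 1)),
            n_dense_nodes=int(rng.integers(lo_n, hi_n + 1)),
            dropout_rate=float(rng.uniform(lo_d, hi_d)),
            batch_norm=bool(rng.integers(0, 2)),
            flatten_type=str(rng.choice(HEAD_RANGES["flatten_type"])),
            activation=str(rng.choice(ACTIVATION_CHOICES)),
            optimizer=str(rng.choice(OPTIMIZER_CHOICES)),
            conv_activation=(
                str(rng.choice(ACTIVATION_CHOICES)) if self.include_conv_activation else "relu"
            ),
        )

    def encode(self, config: HeadConfig) -> np.ndarray:
        """Numeric embedding: scaled numerics + one-hot categoricals."""
        lo_b, hi_b = HEAD_RANGES["n_dense_blocks"]
        lo_n, hi_n = HEAD_RANGES["n_dense_nodes"]
        lo_d, hi_d = HEAD_RANGES["dropout_rate"]
        parts = [
            (config.n_dense_blocks - lo_b) / (hi_b - lo_b),
            (config.n_dense_nodes - lo_n) / (hi_n - lo_n),
            (config.dropout_rate - lo_d) / (hi_d - lo_d),
            1.0 if config.batch_norm else 0.0,
            1.0 if config.flatten_type == "gap" else 0.0,
        ]
        parts += [1.0 if config.activation == a else 0.0 for a in ACTIVATION_CHOICES]
        parts += [1.0 if config.optimizer == o else 0.0 for o in OPTIMIZER_CHOICES]
        if self.include_conv_activation:
            parts += [1.0 if config.conv_activation == a else 0.0 for a in ACTIVATION_CHOICES]
        return np.array(parts)


@dataclass(frozen=True)
class BOTrial:
    index: int  # 1-based iteration
    config: HeadConfig
    objective: float  # validation accuracy in [0, 1]
    epochs_used: int = 0
    failed: bool = False

    def __post_init__(self):
        if not 0.0 <= self.objective <= 1.0:
            raise ValueError(f"objective must be in [0, 1], got {self.objective!r}")


@dataclass
class BOTrace:
    trials: list = field(default_factory=list)
    seed: int = 0

    @property
    def best_so_far(self) -> list:
        out, best = [], -np.inf
        for t in self.trials:
            best = max(best, t.objective)
            out.append(best)
        return out

    def best_trial(self) -> BOTrial:
        return max(self.trials, key=lambda t: (t.objective, -t.index))

    def to_jsonl(self) -> str:
        lines = []
        for t in self.trials:
            d = asdict(t)
            d["config"] = t.config.to_dict()
            lines.append(json.dumps(d))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_jsonl(cls, text: str, seed: int = 0) -> "BOTrace":
        trials = []
        for line in text.strip().splitlines():
            d = json.loads(line)
            d["config"] = HeadConfig.from_dict(d["config"])
            trials.append(BOTrial(**d))
        return cls(trials=trials, seed=seed)


def expected_improvement(mu, sigma, best, xi: float = 0.0):
    """EI acquisition for maximization.

    With z = (mu - best - xi) / sigma:
        EI = (mu - best - xi) * Phi(z) + sigma * phi(z),
    and the sigma -> 0 limit max(mu - best - xi, 0).  Vectorized over mu
    and sigma; any negative sigma raises.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be nonnegative")
    delta = mu - best - xi
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, delta / np.where(sigma > 0, sigma, 1.0), 0.0)
        ei = np.where(
            sigma > 0,
            delta * norm.cdf(z) + sigma * norm.pdf(z),
            np.maximum(delta, 0.0),
        )
    return ei if ei.ndim else float(ei)


def _call_objective(objective, config, trial_seed):
    params = inspect.signature(objective).parameters
    if "trial_seed" in params or any(
        p.kind is inspect.Parameter.VAR_KEYWORD for p in params.values()
    ):
        return objective(config, trial_seed=trial_seed)
    return objective(config)


def _fit_surrogate(x, y, seed):
    kernel = ConstantKernel(1.0) * Matern(length_scale=np.ones(x.shape[1]), nu=2.5) + WhiteKernel(
        noise_level=1e-4, noise_level_bounds=(1e-8, 1e-1)
    )
    gp = GaussianProcessRegressor(
        kernel=kernel,
        normalize_y=True,
        n_restarts_optimizer=1,
        random_state=seed % (2**32),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(x, y)
    return gp


def run_bo(
    objective,
    space: SearchSpace = SearchSpace(),
    n_iterations: int = 40,
    n_initial: int = 10,
    seed: int = 0,
    xi: float = 0.01,
    n_candidates: int = 256,
):
    """Sequential search; returns (BOTrace, best HeadConfig).

    The first ``n_initial`` configurations are uniform draws from the box;
    each later one maximizes EI under the surrogate fit to all previous
    trials, over a fresh random candidate set.  An objective that raises is
    recorded as a failed trial with objective 0 (and a warning), so the
    trace always has exactly ``n_iterations`` entries.  Per-trial seeds
    derive from (seed, trial index), making traces replayable.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    n_initial = min(max(1, n_initial), n_iterations)
    trace = BOTrace(seed=seed)
    xs, ys = [], []
    for i in range(1, n_iterations + 1):
        if i <= n_initial:
            config = space.sample(rng_for(seed, "bo-init", i))
        else:
            gp = _fit_surrogate(np.array(xs), np.array(ys), derive_seed(seed, "bo-gp", i))
            cand_rng = rng_for(seed, "bo-cand", i)
            candidates = [space.sample(cand_rng) for _ in range(n_candidates)]
            enc = np.array([space.encode(c) for c in candidates])
            mu, sigma = gp.predict(enc, return_std=True)
            ei = expected_improvement(mu, sigma, best=max(ys), xi=xi)
            config = candidates[int(np.argmax(ei))]
        trial_seed = derive_seed(seed, "bo-trial", i)
        try:
            value = float(_call_objective(objective, config, trial_seed))
            failed = False
        except Exception as e:  # noqa: BLE001 - a failed trial must not kill the run
            logger.warning("trial %d failed (%s); recording objective 0", i, e)
            value, failed = 0.0, True
        epochs = getattr(objective, "epochs", 0)
        trial = BOTrial(index=i, config=config, objective=value, epochs_used=epochs, failed=failed)
        trace.trials.append(trial)
        xs.append(space.encode(config))
        ys.append(value)
        logger.info("BO iteration %d/%d: acc=%.4f (best=%.4f)", i, n_iterations, value, max(ys))
    return trace, trace.best_trial().config


def make_training_objective(
    extractor,
    train_manifest,
    val_manifest,
    epochs: int = 16,
    batch_size: int = 32,
    image_size: int | None = None,
    width: float = 1.0,
):
    """Validation-accuracy objective for :func:`run_bo`.

    ``extractor`` is either a ready :class:`ArchitectureSpec` feature
    extractor, or one of the names ``"multibranch"`` (rebuilt per config so
    its conv activation is searchable), ``"mobilenet"`` / ``"densenet201"``
    (random-weight backbone, feature layers frozen during the search, as in
    transfer learning).  Each call builds the head from the config, trains
    for ``epochs`` under BCE with the config's optimizer, and returns
    validation accuracy; weight init and batch order are keyed to the
    per-trial seed.  A non-finite loss scores 0 with a warning.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if len(train_manifest) == 0 or len(val_manifest) == 0:
        raise ValueError("train and validation manifests must be non-empty")

    if isinstance(extractor, ArchitectureSpec):
        size = extractor.input_shape[0]
    else:
        size = image_size or 128
    x_train, y_train = load_images(train_manifest, size)
    x_val, y_val = load_images(val_manifest, size)

    def _extractor_for(config: HeadConfig):
        if isinstance(extractor, ArchitectureSpec):
            return extractor, None
        name = extractor.lower()
        if name == "multibranch":
            return (
                build_multibranch_extractor(
                    (size, size, 3), conv_activation=config.conv_activation, width=width
                ),
                None,
            )
        spec = build_backbone(name, weights="random", input_shape=(size, size, 3))
        frozen = [l.name for l in spec.layers]  # feature layers fixed in the search phase
        return spec, frozen

    def objective(config: HeadConfig, trial_seed: int = 0) -> float:
        ext, frozen = _extractor_for(config)
        spec = build_classifier(ext, config)
        net = compile_network(spec, seed=trial_seed)
        tc = TrainConfig(
            epochs=epochs, optimizer=config.optimizer, batch_size=batch_size, seed=trial_seed
        )
        try:
            fit(net, x_train, y_train, tc, freeze=frozen)
        except FloatingPointError as e:
            logger.warning("objective diverged (%s); scoring 0", e)
            return 0.0
        return accuracy(y_val, net.predict(x_val))

    objective.epochs = epochs
    return objective
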