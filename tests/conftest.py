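"""Shared fixtures: synthetic datasets and the frozen easy-set training run.

Everything is generated at test time from seeded configs; nothing is stored
on disk in the repository.
"""

from __future__ import annotations

import numpy as np
import pytest

import glaucopt as g
from glaucopt.train import TrainConfig, fit, load_images

# Frozen easy-set fixture: stated generator world (clear class separation,
# cdr 0.3 vs 0.7 at sd 0.05, low noise) at desk scale (32 px, 100 images).
EASY_SYNTH = dict(
    n_images=100, class_balance=0.5, image_size=32, cdr_sd=0.05, noise_sd=0.02, seed=11
)
EASY_SPLIT_SEED = 5
EASY_TRAIN_SEED = 0
TINY_WIDTH = 0.25  # channel multiplier of the desk-scale two-branch model


@pytest.fixture(scope="session")
def easy_dataset(tmp_path_factory):
    """(manifest, SynthConfig, out_dir) of the easy synthetic set."""
    out = tmp_path_factory.mktemp("easy")
    cfg = g.SynthConfig(**EASY_SYNTH)
    return g.generate_dataset(cfg, out), cfg, out


@pytest.fixture(scope="session")
def easy_split(easy_dataset):
    manifest, _, _ = easy_dataset
    return g.split(manifest, g.SplitSpec(seed=EASY_SPLIT_SEED))


@pytest.fixture(scope="session")
def easy_arrays(easy_split):
    train_m, val_m, _ = easy_split
    size = EASY_SYNTH["image_size"]
    return load_images(train_m, size), load_images(val_m, size)


def tiny_multibranch_classifier(conv_activation="relu"):
    size = EASY_SYNTH["image_size"]
    ext = g.build_multibranch_extractor(
        (size, size, 3), conv_activation=conv_activation, width=TINY_WIDTH
    )
    head = g.HeadConfig(
        n_dense_blocks=1,
        n_dense_nodes=64,
        dropout_rate=0.2,
        batch_norm=False,
        flatten_type="flatten",
        activation="relu",
        optimizer="adam",
    )
    return g.build_classifier(ext, head)


@pytest.fixture(scope="session")
def easy_training_run(easy_arrays):
    """The frozen seeded run behind the >= 0.9 validation-accuracy check."""
    (x_train, y_train), (x_val, y_val) = easy_arrays
    net = g.compile_network(tiny_multibranch_classifier(), seed=EASY_TRAIN_SEED)
    config = TrainConfig(
        epochs=5, optimizer="adam", learning_rate=1e-3, batch_size=4, seed=EASY_TRAIN_SEED
    )
    history = fit(net, x_train, y_train, config, x_val, y_val)
    return net, history


@pytest.fixture(scope="session")
def bo_recovery():
    """Search-vs-grid comparison on a small discrete toy objective.

    The objective depends only on (n_dense_blocks, activation); the grid
    oracle enumerates all 25 combinations.  Five independent 40-iteration
    searches record whether each attains the grid optimum.
    """
    peaks = {"relu": 0.15, "elu": 0.30, "tanh": 0.05, "swish": 0.22, "softplus": 0.10}

    def objective(config, trial_seed=0):
        return peaks[config.activation] + 0.6 * np.exp(-((config.n_dense_blocks - 4) ** 2))

    grid_best = max(
        objective(g.HeadConfig(n_dense_blocks=b, activation=a))
        for b in range(1, 6)
        for a in peaks
    )
    hits = []
    for seed in range(5):
        trace, best = g.run_bo(
            objective, g.SearchSpace(), n_iterations=40, n_initial=10, seed=seed
        )
        hits.append(abs(trace.best_so_far[-1] - grid_best) < 1e-12)
    return hits, grid_best


@pytest.fixture(scope="session")
def mobilenet_freeze_run():
    """One training epoch of a frozen-stem MobileNet classifier at 32 px.

    Returns (plan, spec, parameter snapshots before/after) for bit-stability
    checks on the frozen units.
    """
    rng = np.random.default_rng(42)
    x = rng.random((8, 32, 32, 3)).astype(np.float32)
    y = np.array([0, 1] * 4, dtype=np.float32)
    ext = g.build_backbone("mobilenet", weights="random", input_shape=(32, 32, 3))
    spec = g.build_classifier(ext, g.HeadConfig(n_dense_nodes=32, flatten_type="gap"))
    net = g.compile_network(spec, seed=1)
    plan = g.freeze_plan("mobilenet")
    net.apply_freeze_plan(plan)
    before = net.snapshot()
    fit(net, x, y, TrainConfig(epochs=1, optimizer="sgd", batch_size=4, seed=1))
    after = net.snapshot()
    return plan, spec, before, after
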