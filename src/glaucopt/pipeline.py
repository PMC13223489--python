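"""End-to-end orchestration: synth -> split -> tune -> train -> ensemble -> evaluate.

A :class:`RunConfig` (constructible in Python or loaded from YAML with a
versioned schema; unknown keys are rejected) drives a fully seeded run.
Every stage writes its artifacts into the run directory as it completes, so
a failure partway leaves the upstream outputs in place, and a
:class:`StageError` names the stage that failed.

Reference-scale defaults mirror the published workflow (40 BO iterations of
16 epochs each per model, fine-tuning at 32 epochs with the backbone freeze
plans, 200 Dirichlet ensemble trials); desk-scale runs shrink the budgets
through the same fields.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from ._rng import derive_seed
from .arch import build_backbone, build_classifier, build_multibranch_extractor, freeze_plan
from .bo import SearchSpace, make_training_objective, run_bo
from .data import ImageManifest, SplitSpec, read_manifest, split, write_manifest
from .ensemble import DirichletParams, ModelPredictions, search_weights, weighted_average_predict
from .evaluate import evaluate_scores, format_report_table
from .nn import compile_network
from .synth import SynthConfig, generate_dataset
from .train import TrainConfig, fit, load_images

__all__ = ["RunConfig", "StageError", "run_pipeline", "load_run_config"]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
_MODELS = ("multibranch", "mobilenet", "densenet201")


class StageError(RuntimeError):
    """A pipeline stage failed; upstream artifacts are kept on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    out_dir: str = "run"
    source: str = "synthetic"  # or "manifest"
    manifest_path: str | None = None
    synth: SynthConfig = field(default_factory=SynthConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    models: tuple = ("multibranch",)
    image_size: int | None = None  # default: synth.image_size
    multibranch_width: float = 1.0
    bo_iterations: int = 40
    bo_epochs: int = 16
    bo_n_initial: int = 10
    bo_batch_size: int = 32
    finetune: bool = True
    finetune_epochs: int = 32
    finetune_lr: float = 1e-4
    ensemble_trials: int = 200
    alpha: tuple | None = None
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self):
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {self.schema_version!r}")
        if self.source not in ("synthetic", "manifest"):
            raise ValueError(f"source must be 'synthetic' or 'manifest', got {self.source!r}")
        if self.source == "manifest" and not self.manifest_path:
            raise ValueError("manifest_path is required when source='manifest'")
        bad = [m for m in self.models if m not in _MODELS]
        if bad:
            raise ValueError(f"unknown models {bad}; choose from {_MODELS}")
        if not self.models:
            raise ValueError("at least one model is required")
        for name in ("bo_iterations", "bo_epochs", "bo_n_initial", "finetune_epochs", "ensemble_trials"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def resolved_image_size(self) -> int:
        return self.image_size or self.synth.image_size


def load_run_config(path) -> RunConfig:
    """YAML -> RunConfig, rejecting unknown keys (fail-fast reproducibility)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "synth" in raw:
        raw["synth"] = SynthConfig(**raw["synth"])
    if "split" in raw:
        raw["split"] = SplitSpec(**raw["split"])
    if "models" in raw:
        raw["models"] = tuple(raw["models"])
    if "alpha" in raw and raw["alpha"] is not None:
        raw["alpha"] = tuple(raw["alpha"])
    return RunConfig(**raw)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as e:  # noqa: BLE001 - annotate with the stage name
                raise StageError(name, e) from e

        return inner

    return wrap


@_stage("data")
def _stage_data(config: RunConfig, out: Path):
    if config.source == "synthetic":
        manifest = generate_dataset(config.synth, out / "images")
    else:
        manifest = read_manifest(config.manifest_path)
    write_manifest(manifest, out / "manifest.csv")
    train_m, val_m, test_m = split(manifest, config.split)
    for name, m in (("train", train_m), ("val", val_m), ("test", test_m)):
        write_manifest(m, out / f"{name}.csv")
    return train_m, val_m, test_m


@_stage("tune")
def _stage_tune(config: RunConfig, out: Path, model: str, train_m, val_m):
    size = config.resolved_image_size
    space = SearchSpace(include_conv_activation=(model == "multibranch"))
    objective = make_training_objective(
        model,
        train_m,
        val_m,
        epochs=config.bo_epochs,
        batch_size=config.bo_batch_size,
        image_size=size,
        width=config.multibranch_width,
    )
    trace, best = run_bo(
        objective,
        space,
        n_iterations=config.bo_iterations,
        n_initial=config.bo_n_initial,
        seed=derive_seed(config.seed, "tune", _MODELS.index(model)),
    )
    (out / f"{model}_trace.jsonl").write_text(trace.to_jsonl())
    (out / f"{model}_best_config.json").write_text(json.dumps(best.to_dict(), indent=1))
    return trace, best

@_stage("train")
def _stage_train(config: RunConfig, out: Path, model: str, best, train_m, val_m, test_m):
    size = config.resolved_image_size
    if model == "multibranch":
        ext = build_multibranch_extractor(
            (size, size, 3), conv_activation=best.conv_activation, width=config.multibranch_width
        )
        frozen = None
    else:
        ext = build_backbone(model, weights="random", input_shape=(size, size, 3))
        frozen = None if config.finetune else [l.name for l in ext.layers]
    spec = build_classifier(ext, best)
    epochs = config.finetune_epochs if config.finetune else config.bo_epochs
    tc = TrainConfig(
        epochs=epochs,
        optimizer=best.optimizer,
        learning_rate=config.finetune_lr if (config.finetune and model != "multibranch") else None,
        batch_size=config.bo_batch_size,
        seed=derive_seed(config.seed, "final-train", _MODELS.index(model)),
    )
    net = compile_network(spec, seed=tc.seed)
    if model != "multibranch" and config.finetune:
        net.apply_freeze_plan(freeze_plan(model))
    x_train, y_train = load_images(train_m, size)
    x_val, y_val = load_images(val_m, size)
    history = fit(net, x_train, y_train, tc, x_val, y_val, freeze=frozen)
    (out / f"{model}_history.json").write_text(json.dumps(history, indent=1))
    np.savez(out / f"{model}_params.npz", **{f"{n}/{p}": v for (n, p), v in net.snapshot().items()})
    x_test, y_test = load_images(test_m, size)
    return {
        "val": (y_val, net.predict(x_val)),
        "test": (y_test, net.predict(x_test)),
        "history": history,
    }


@_stage("ensemble")
def _stage_ensemble(config: RunConfig, out: Path, preds_val: ModelPredictions):
    if preds_val.n_models == 1:
        params = None  # degenerate single-model ensemble
    else:
        alpha = config.alpha or (1.0,) * preds_val.n_models
        params = DirichletParams(alpha=tuple(alpha))
    result = search_weights(
        preds_val,
        params,
        n_trials=config.ensemble_trials,
        seed=derive_seed(config.seed, "ensemble"),
    )
    (out / "ensemble.json").write_text(result.to_json())
    return result


@_stage("evaluate")
def _stage_evaluate(out: Path, labels, scores_by_model: dict, tag: str):
    reports = {name: evaluate_scores(labels, s) for name, s in scores_by_model.items()}
    payload = {name: r.to_dict() for name, r in reports.items()}
    (out / f"report_{tag}.json").write_text(json.dumps(payload, indent=1))
    (out / f"report_{tag}.txt").write_text(format_report_table(reports))
    return reports


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns (and writes) the run summary.

    Artifacts in the run directory: the manifest and split CSVs, per-model
    BO traces and best head configs, training histories and parameters,
    validation/test prediction CSVs, the ensemble weight search result, and
    per-split evaluation reports (JSON + text table).  Identical configs
    produce identical summaries.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    train_m, val_m, test_m = _stage_data(config, out)
    summary = {
        "seed": config.seed,
        "split_sizes": {"train": len(train_m), "val": len(val_m), "test": len(test_m)},
        "models": {},
    }

    val_scores, test_scores = {}, {}
    for model in config.models:
        _, best = _stage_tune(config, out, model, train_m, val_m)
        res = _stage_train(config, out, model, best, train_m, val_m, test_m)
        y_val, p_val = res["val"]
        y_test, p_test = res["test"]
        val_scores[model], test_scores[model] = p_val, p_test
        summary["models"][model] = {
            "best_config": best.to_dict(),
            "final_val_acc": res["history"][-1].get("val_acc"),
        }

    preds_val = ModelPredictions(
        probs=np.stack([val_scores[m] for m in config.models]),
        labels=y_val,
        model_names=list(config.models),
    )
    preds_test = ModelPredictions(
        probs=np.stack([test_scores[m] for m in config.models]),
        labels=y_test,
        model_names=list(config.models),
    )
    preds_val.to_csv(out / "val_preds.csv")
    preds_test.to_csv(out / "test_preds.csv")

    ens = _stage_ensemble(config, out, preds_val)
    summary["ensemble"] = {
        "weights": list(ens.best_weights.weights),
        "val_accuracy": ens.best_accuracy,
        "winning_trial_index": ens.winning_trial_index,
    }

    val_scores["ensemble"] = weighted_average_predict(preds_val, ens.best_weights)
    test_scores["ensemble"] = weighted_average_predict(preds_test, ens.best_weights)
    reports_val = _stage_evaluate(out, y_val, val_scores, "val")
    reports_test = _stage_evaluate(out, y_test, test_scores, "test")
    summary["metrics"] = {
        "val": {m: {"acc": r.acc, "auc": r.auc} for m, r in reports_val.items()},
        "test": {m: {"acc": r.acc, "auc": r.auc} for m, r in reports_test.items()},
    }

    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    logger.info("run complete: %s", summary["metrics"]["test"])
    return summary
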