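# glaucopt

Bayesian-optimized CNN ensembles for glaucoma detection from
optic-disc-centered retinal fundus images — a desk-scale, CPU-only toolkit.

Glaucoma screening from fundus photographs hinges on the cup-to-disc ratio
(CDR): the bright optic disc's brighter central cup enlarges as the disease
progresses. This package implements a complete detection workflow around
that signal, for researchers who want to study the *method* — architecture
search, transfer-learning freeze policies, ensemble weighting — without a
GPU or access to clinical images:

- **Two-branch CNN extractor**: parallel conv/pool branches (3x3x32→64 and
  3x3x64→128) concatenated and refined to a 16x16x256 feature map on
  128x128x3 input.
- **Backbone adapters**: MobileNet and DenseNet201 feature extractors as
  declarative layer graphs with block-level unit tags and fine-tuning
  freeze plans (MobileNet: depthwise blocks 6–13 trainable; DenseNet201:
  dense block 3 onward).
- **Bayesian head search**: 7 hyperparameters (dense blocks 1–5, nodes
  32–1024, dropout 0.2–0.5, batch norm, flatten/GAP, activation, optimizer)
  tuned by Expected Improvement, `EI = (μ−y*−ξ)Φ(z) + σφ(z)`, on a
  Gaussian-process surrogate of validation accuracy.
- **Dirichlet weighted-average ensemble**: `Y_E = Σ w_i Y_i` with weight
  vectors sampled from `Dir(α)`, quantized to 4 decimals, scored by
  validation accuracy over 200 trials.
- **Evaluation**: per-class and macro PREC/SEN/F1 from the confusion
  matrix, ACC, and rank-statistic AUC.
- **Synthetic fundus generator**: seeded, byte-reproducible disc/cup images
  with class-dependent CDR (0.3 normal vs 0.7 glaucoma), so every stage is
  testable without downloads.

A small reverse-mode NumPy engine (finite-difference-verified gradients,
the five searchable optimizers, layer freezing) backs all training; no
deep-learning framework is required.

## Worked example

```python
import glaucopt as g

# 1. A seeded synthetic dataset and the 70/15/15 split
manifest = g.generate_dataset(
    g.SynthConfig(n_images=100, image_size=32, cdr_sd=0.05, noise_sd=0.02, seed=11),
    "scratch/demo",
)
train_m, val_m, test_m = g.split(manifest, g.SplitSpec(seed=5))
print(len(train_m), len(val_m), len(test_m))   # 70 15 15

# 2. Train a small two-branch classifier for 5 epochs
from glaucopt.train import TrainConfig, load_images, fit
ext = g.build_multibranch_extractor((32, 32, 3), width=0.25)
spec = g.build_classifier(ext, g.HeadConfig(n_dense_nodes=64, optimizer="adam"))
net = g.compile_network(spec, seed=0)
history = fit(net, *load_images(train_m, 32),
              TrainConfig(epochs=5, optimizer="adam", learning_rate=1e-3,
                          batch_size=4, seed=0),
              *load_images(val_m, 32))
print(round(history[-1]["val_acc"], 2))        # 1.0

# 3. Evaluate on the held-out test set
x_test, y_test = load_images(test_m, 32)
report = g.evaluate_scores(y_test, net.predict(x_test))
print(round(report.acc, 2), round(report.auc, 2))   # 1.0 1.0
```

The validation accuracy is the fraction of the 15 held-out validation
images classified correctly at the 0.5 threshold; `report.acc` / `report.auc`
are test-set accuracy and the probability that a random glaucoma image is
scored above a random normal one. The `examples/` directory holds one
narrative script per capability (generation, assembly/splitting,
architecture shapes and the depthwise-separable cost formula, Bayesian head
search, Dirichlet ensembling, evaluation tables, and the full pipeline);
each prints what it computes and says what the numbers mean.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main workflow from scratch at the given seed —
synthetic data, split, per-model Bayesian head search, final training with
the MobileNet freeze plan, Dirichlet ensemble search, and test-set
evaluation — printing the resulting metrics and writing the results JSON to
`--out`. Runtime is well under a minute on one CPU; intermediate artifacts
land under `scratch/`.

## Scope

Backbones initialize with random weights (no network access for pretrained
checkpoints), so they exercise structure and freeze semantics rather than
transfer-learning accuracy; reproducing published clinical-image accuracies
is out of scope. See `docs/methods.md` for model details, defaults,
numerical choices and limitations.
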