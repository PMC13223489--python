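# Methods

`glaucopt` implements a complete glaucoma-detection workflow for
optic-disc-centered retinal fundus images at desk scale: a two-branch
convolutional feature extractor trained from scratch, MobileNet and
DenseNet201 backbone adapters with selective fine-tuning, Gaussian-process
Bayesian optimization of the classifier-head hyperparameters, a
Dirichlet-sampled weighted-average ensemble, and a confusion-matrix
evaluation suite. This note records the models, the defaults and why they
hold, the numerical choices, and what the synthetic benchmark does and does
not establish.

## Problem and data model

The task is binary: classify an RGB fundus image as *glaucoma* or *normal*.
The clinically decisive signal in disc-centered crops is the cup-to-disc
ratio (CDR): the optic cup — the brighter central depression of the bright
optic disc — enlarges relative to the disc as glaucoma progresses.

Datasets are CSV manifests (`path,label,source`). `assemble` merges
collections (duplicate paths are an error), images are decoded to
`size x size x 3` float tensors in [0, 1] by dividing 8-bit intensities by
255, and `center_crop` extracts a central square window as an automated
stand-in for manual disc cropping of full-fundus views.

### Split convention

`split` sizes the subsets `floor(0.70 N)`, `floor(0.15 N)`, remainder — the
only rounding that maps 1355 records to the published 948/203/204. With
stratification (default on), those *global* sizes are fixed first and then
divided across the classes by largest remainder. The more obvious
stratified rule — apply the floor rule inside each class — would give
947/202/206 on the 564/791 class mix and contradict the published totals;
preserving the global sizes keeps both the totals and per-class proportions
within one record of the global fraction. Whether the original split was
stratified is not documented; stratification is a flag.

## Architectures

Architectures are declarative layer graphs (`ArchitectureSpec`): each layer
records its kind, parameters, inputs and output shape, and specs compile to
an executable NumPy network. All convolutions use TensorFlow-style "same"
padding; pooling uses stride = pool size.

**Two-branch extractor.** Branch 1: conv 3x3x32 → maxpool 2x2/2 → conv
3x3x64; branch 2: conv 3x3x64 → maxpool 2x2/2 → conv 3x3x128; channel
concatenation; conv 3x3x256 → maxpool 2x2 → batch norm. The published
shape chain (128 → 64 after pooling, yet 32 after the next convolution)
forces an unstated downsampling; here the second convolution of each branch
uses stride 2, the smallest change that reproduces the printed 32x32x64 /
32x32x128 tensors exactly. A `width` multiplier scales every channel count
for desk-scale variants with identical topology. The conv layers share one
activation, searchable as the 8th hyperparameter.

**Classifier head.** Flatten or global average pooling, then 1–5 dense
blocks of [dense → activation → optional batch norm → dropout], then a
fixed single-unit sigmoid output. The searched box:

| hyperparameter | range |
|---|---|
| dense blocks | 1–5 |
| dense nodes | 32–1024 |
| dropout rate | 0.2–0.5 |
| batch norm | on / off |
| flatten type | flatten / GAP |
| activation | relu, elu, tanh, swish, softplus |
| optimizer | nadam, rmsprop, adam, sgd, adamax |

**Backbones.** MobileNet (stem + 13 depthwise-separable blocks, standard
channel schedule) and DenseNet201 (stem, dense blocks of 6/12/48/32
composite layers with growth 32, halving transitions) are generated as
layer graphs whose layers carry unit tags, so freeze plans address whole
blocks. Pretrained ImageNet weights are unavailable offline; backbones
compile with seeded random initialization, which preserves every structural
contract (shapes, unit addressing, freeze semantics) but not transfer
learning's accuracy benefit. An `avgpool` layer kind was added for the
DenseNet transitions.

**Depthwise-separable cost.** `C = D_K^2 M D_F^2 + M N D_F^2` (depthwise +
pointwise terms); the ratio to a standard convolution is `1/N + 1/D_K^2`.
The MobileNet width/resolution multipliers α and ρ are documented on
`ConvCostSpec` but not propagated further.

## Training and fine-tuning

Training minimizes mean binary cross-entropy (probabilities clipped to
[1e-7, 1 − 1e-7]) by mini-batch gradient descent with one of the five
searchable optimizers (defaults: 1e-3 adaptive, 1e-2 SGD). A freeze plan
pins early units — MobileNet: stem + blocks 1–5 frozen, 6–13 trainable;
DenseNet201: stem through transition 2 frozen, dense block 3 onward
trainable — and frozen parameters are bit-identical before and after
training (they are simply excluded from the update loop). The fine-tuning
learning rate defaults to 1e-4 (undocumented in the source setting; a
conventional choice), and the fine-tune phase doubles the per-run budget
from 16 to 32 epochs. Everything (init, batch order, dropout) is keyed to
`(seed, stage, index)`, so runs replay exactly.

The engine itself is a small reverse-mode NumPy implementation (NHWC,
float32) written for this package because no deep-learning framework is
assumed; its gradients are verified against central finite differences in
float64 (relative error ≤ 1e-5), and its convolution/pooling forward passes
against scipy oracles.

## Bayesian optimization

The head search is sequential: `n_initial` (default 10; the source setting
documents only "randomly selected" initialization) uniform draws, then each
iteration fits a Gaussian-process surrogate (scikit-learn, constant × Matérn
5/2 + white noise, normalized targets) to all (encoded config, validation
accuracy) pairs and picks the candidate maximizing Expected Improvement

    EI(x) = (μ − y* − ξ) Φ(z) + σ φ(z),   z = (μ − y* − ξ)/σ,

with the σ → 0 limit `max(μ − y* − ξ, 0)` and ξ = 0.01 (a common default;
undocumented in the source setting). Categorical dimensions are one-hot
encoded; integers are relaxed to continuous and rounded to the nearest
in-range value. EI is maximized over a fresh random candidate set (256 by
default) rather than by gradient ascent — adequate for a 7–8 dimensional
box and simpler to make deterministic. A trial whose objective raises is
recorded with objective 0 and a warning so the 40-iteration trace is always
complete. Per-trial seeds derive from (run seed, trial index).

The objective trains the head (backbone feature layers frozen for the
pretrained models, everything trainable for the two-branch model) for a
short budget — 16 epochs at reference scale — and returns validation
accuracy.

## Dirichlet weighted-average ensemble

The ensemble predicts `Y_E = Σ w_i Y_i` with `w` on the simplex. Candidate
weights are Dirichlet draws (200 trials at reference scale); the
concentration defaults to all ones — uniform on the simplex — since the
source setting does not document its α. Each draw is quantized to 4 decimal
places, with the rounding residual added to the largest weight (lowest
index on ties) so the quantized sum is exactly 1.0000 while staying closest
to the raw draw in max-norm among single-coordinate corrections. Trials are
scored by thresholded validation accuracy (threshold 0.5, ties positive);
the earliest trial attaining the maximum wins, which makes reported winning
iteration indices reproducible. With a single model the search degenerates
to that model with weight 1.

## Evaluation

From confusion counts at threshold 0.5 (ties → positive):
`ACC = (TP+TN)/n`, `PREC = TP/(TP+FP)`, `SEN = TP/(TP+FN)`,
`F1 = 2·PREC·SEN/(PREC+SEN)`. Reports compute the per-class metrics twice —
each class taken as positive — plus their unweighted (macro) mean, the
convention the published "Average" rows follow (confirmed by the printed
97.44/93.02 → 95.23 row). AUC is the rank statistic (probability a random
positive outranks a random negative, midranks giving ties half credit),
which equals the trapezoidal area under the empirical ROC. Metrics with a
zero denominator are reported as NaN and flagged by name rather than
silently coerced to 0, so macro averages cannot be corrupted.

## Synthetic data

The generator emits disc-centered images with: a reddish, radially shaded
background; a bright disc (center jittered up to 10% of the side, radius
26–32% of the side) containing a brighter concentric cup with
`cup radius = CDR × disc radius`; 2–4 dark quadratic vessel curves
emanating at the disc rim (the cup region stays vessel-free, as in real
disc crops — early versions let vessels cross the cup, which destroyed the
class signal the generator exists to provide); and additive Gaussian pixel
noise. Per-class CDR is truncated-normal (rejection sampling) with means
0.3 (normal) and 0.7 (glaucoma). Output is PNG (lossless), so identical
configs are byte-identical; per-image randomness is keyed to (seed, image
index).

What it does not emulate: photographic texture, vessel branching,
peripapillary atrophy, illumination artifacts, camera variation, or any
pathology beyond the CDR proxy. A model that passes the synthetic benchmark
has demonstrated that the pipeline wiring, optimization and ensembling work
— not that it detects glaucoma in real photographs.

**Desk-scale benchmark.** The "easy set" is 100 images at 32x32, CDR sd
0.05, noise sd 0.02; a width-0.25 two-branch model (dense block of 64
nodes, flatten, relu, adam at 1e-3, batch 4) trained 5 epochs on its
70/15/15 split reaches ≥ 0.9 validation accuracy in roughly a second on one
CPU. Seeds (generator 11, split 5, training 0) were frozen after one
verification run. Published accuracies on the real merged dataset with
ImageNet-pretrained backbones at GPU scale are explicitly out of scope.

## Known limitations

- Random-initialized backbones: structural fidelity without transfer
  learning, so MobileNet/DenseNet201 accuracy on synthetic desk-scale runs
  is near chance; the two-branch model carries the demonstration.
- The GP surrogate treats one-hot categoricals as continuous coordinates, a
  standard pragmatic encoding, not a principled categorical kernel.
- Average pooling includes "same"-padding zeros in its mean when the window
  overhangs (it never does for even sizes with 2x2/2 pooling, the only case
  the built architectures use).
- The BCE clip (1e-7) biases the loss at fully saturated outputs; gradients
  use the exact `(p − y)/n` form at the sigmoid output and are unaffected.
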