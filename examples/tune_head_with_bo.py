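"""Bayesian-optimize a classifier head on the easy synthetic set.

A short search (8 iterations of 2 epochs each — the reference workflow uses
40 x 16) over the 7-hyperparameter head box, guided by Expected Improvement
on a Gaussian-process surrogate of validation accuracy.
"""

import glaucopt as g

manifest = g.generate_dataset(
    g.SynthConfig(n_images=60, image_size=32, cdr_sd=0.05, noise_sd=0.02, seed=11),
    "scratch/example_bo",
)
train_m, val_m, _ = g.split(manifest, g.SplitSpec(seed=5))

objective = g.make_training_objective(
    "multibranch", train_m, val_m, epochs=2, batch_size=8, image_size=32, width=0.25
)
trace, best = g.run_bo(
    objective,
    g.SearchSpace(include_conv_activation=True),
    n_iterations=8,
    n_initial=4,
    seed=0,
)

print("best validation accuracy per iteration:", [round(b, 3) for b in trace.best_so_far])
print("best head:", best.to_dict())
# The running best is nondecreasing; the winning config is the head the
# final training stage would use.
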