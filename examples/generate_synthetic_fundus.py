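"""Generate a seeded synthetic fundus dataset and inspect its class signal.

The generator draws optic-disc-centered images whose cup-to-disc ratio
(CDR) differs by class — the enlarged-cup hallmark of glaucoma — so any
downstream model has a learnable, known signal.
"""

import pandas as pd

import glaucopt as g

config = g.SynthConfig(
    n_images=40, class_balance=0.5, image_size=64, cdr_normal=0.3, cdr_glaucoma=0.7, seed=7
)
manifest = g.generate_dataset(config, "scratch/example_synth")

print("class counts:", manifest.class_counts())
meta = pd.read_csv("scratch/example_synth/synth_meta.csv")
print(meta.groupby("label")["cdr"].describe()[["mean", "std"]])
# The glaucoma rows' mean CDR sits near 0.7 and the normal rows' near 0.3:
# the generator encodes the class exactly through that ratio.
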