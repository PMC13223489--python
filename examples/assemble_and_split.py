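"""Merge two labeled collections and split 70/15/15.

Uses manifests with the published source sizes (396/309 and 168/482
images) to show the merged totals (564 glaucoma, 791 normal, 1355) and the
split sizes (948/203/204) those numbers imply.
"""

import glaucopt as g
from glaucopt.data import ManifestRecord


def sized_manifest(n_glaucoma, n_normal, source):
    recs = [
        ManifestRecord(f"{source}/g{i}.png", "glaucoma", source) for i in range(n_glaucoma)
    ] + [ManifestRecord(f"{source}/n{i}.png", "normal", source) for i in range(n_normal)]
    return g.ImageManifest(recs)


merged = g.assemble([sized_manifest(396, 309, "acrima"), sized_manifest(168, 482, "origa")])
print("merged:", merged.class_counts(), "total", len(merged))

train, val, test = g.split(merged, g.SplitSpec(train_frac=0.70, val_frac=0.15, test_frac=0.15, seed=0))
print("split sizes:", len(train), len(val), len(test))
# 948 train / 203 validation / 204 test: floor rounding for train and
# validation, remainder to test, stratified by class.
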