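"""Per-class and macro evaluation of probability scores.

Builds the full confusion-matrix report (PREC/SEN/F1 for each class as
positive, unweighted macro averages, ACC, rank-statistic AUC) and prints
the Normal/Glaucoma/Average table.
"""

import numpy as np

import glaucopt as g

rng = np.random.default_rng(1)
labels = np.array(["glaucoma"] * 40 + ["normal"] * 60)
scores = np.clip((labels == "glaucoma") * 0.7 + rng.normal(0.15, 0.18, 100), 0, 1)

reports = g.report(labels, {"demo-model": scores})
print(g.format_report_table(reports))
rep = reports["demo-model"]
print("macro F1:", round(rep.macro.f1, 4), "| ACC:", round(rep.acc, 4), "| AUC:", round(rep.auc, 4))
# PREC/SEN/F1 are listed per class (each class as positive in turn); the
# Average row is their unweighted mean; AUC is the probability a random
# glaucoma sample outranks a random normal one.
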