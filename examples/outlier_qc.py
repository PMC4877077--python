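"""Sample-level QC: spot a sample that does not cluster with the cohort.

Builds a 10-sample cohort in which one sample has a displaced expression
profile, computes pairwise Euclidean distances on the log-transformed
data, and screens for isolated samples.  The displaced sample's
nearest-neighbour distance far exceeds the cohort's median, so it is
flagged; re-screening after exclusion is clean.
"""

import numpy as np

from gsanova import detect_outliers, sample_distances
from gsanova.normalize import ExpressionMatrix

rng = np.random.default_rng(0)
values = rng.normal(8.0, 1.0, size=(200, 10))
values[:, 9] += 6.0  # sample 10 drawn from a shifted profile
samples = [f"TG-{j + 1}" for j in range(9)] + ["TG-odd"]
em = ExpressionMatrix([f"g{i}" for i in range(200)], samples, values)

report = detect_outliers(sample_distances(em), multiplier=2.0)
print("flagged:", report.flagged)
print(f"threshold (2 x median NN distance): {report.threshold:.1f}")
for s in samples:
    mark = " <-- flagged" if s in report.flagged else ""
    print(f"  {s:<8} nearest-neighbour distance {report.isolation_score[s]:6.1f}{mark}")

keep = [s for s in samples if s not in report.flagged]
em2 = ExpressionMatrix(em.gene_ids, keep,
                       em.values[:, [samples.index(s) for s in keep]])
print("re-screen after exclusion:", detect_outliers(sample_distances(em2)).flagged)
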