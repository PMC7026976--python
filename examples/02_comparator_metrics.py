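"""Compare SPECS with the classical profile-based specificity metrics.

The comparators (z-score, Gini, Tau, TSI, JSD) collapse replicates to
per-tissue means first; SPECS keeps every replicate. The table shows all six
side by side for two genes with the same mean profile but different
within-tissue spread — only SPECS distinguishes them.
"""

import numpy as np

from specscore import CountMatrix, SampleGrouping, score_all_metrics

rng = np.random.default_rng(0)
grouping = SampleGrouping(
    [f"T1_{i}" for i in range(10)] + [f"T2_{i}" for i in range(10)] + [f"T3_{i}" for i in range(10)],
    ["T1"] * 10 + ["T2"] * 10 + ["T3"] * 10,
)

tight = np.concatenate([rng.normal(50, 1, 10), rng.normal(10, 1, 10), rng.normal(10, 1, 10)])
noisy = np.concatenate([rng.normal(50, 45, 10), rng.normal(10, 12, 10), rng.normal(10, 12, 10)])
counts = CountMatrix(["tight", "noisy"], grouping.samples,
                     np.clip(np.vstack([tight, noisy]), 0, None))

table = score_all_metrics(counts, grouping)
cols = ["SPECS_T1", "zscore_T1", "JSD_T1", "Gini", "Tau", "TSI"]
print(table[cols].round(3).to_string())

# Both genes have mean profiles near (50, 10, 10), so the mean-collapsing
# metrics score them almost identically. SPECS drops for the noisy gene
# because its T1 distribution overlaps the other tissues.
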