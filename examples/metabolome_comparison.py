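"""Quantitative metabolome comparison: heatmap scale, overlap, volcano.

Builds the family-normalized -log10 congener abundance matrix, partitions
features by group presence, and runs the two-group volcano test.
"""

import numpy as np
import pandas as pd

from glyconet import quantify_compare as qc
from glyconet import feature_pipeline as fp

# congener x sample EIC areas; congener "sar3" is absent from sample s1
areas = pd.DataFrame(
    {"s1": [2.0e6, 1.3e4, 0.0, 8.0e5], "s2": [1.1e6, 0.0, 5.0e3, 9.0e5]},
    index=["sar1", "sar2", "sar3", "mel1"],
)
family = {"sar1": "sarasinoside", "sar2": "sarasinoside",
          "sar3": "sarasinoside", "mel1": "melophlin"}
heat = qc.congener_heatmap(areas, family)
print("-log10 family-normalized abundances (0 = family maximum, 6 = absent):")
print(heat.round(2).to_string())

feats = [
    fp.Feature("F0", 500.0, 5.0, 1, {"a1": 1.0, "a2": 1.0, "b1": 1.0, "b2": 1.0}),
    fp.Feature("F1", 510.0, 5.5, 1, {"a1": 1.0, "a2": 1.0}),
    fp.Feature("F2", 520.0, 6.0, 1, {"b2": 1.0}),
]
table = fp.AlignedFeatureTable(feats, ["a1", "a2", "b1", "b2"])
summary = qc.feature_overlap(table, {"A": ["a1", "a2"], "B": ["b1", "b2"]})
print("\nfeature overlap (groups sharing each feature -> count, percent):")
for k, v in summary.counts.items():
    print(f"  {'+'.join(sorted(k)):5s} {v}  ({summary.percentages()[k]}%)")

rng = np.random.default_rng(0)
mat = pd.DataFrame(rng.lognormal(10, 0.2, (60, 8)),
                   columns=["a1", "a2", "a3", "a4", "b1", "b2", "b3", "b4"])
mat.iloc[0, :4] *= 8.0  # plant one 8-fold enriched feature in group A
res = qc.volcano(mat, ["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"])
sig = res.significant()
print(f"\nvolcano (FC >= 3, p <= 0.05): {len(sig)} significant of {len(res.table)}")
print(sig.round(4).to_string(index=False))
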