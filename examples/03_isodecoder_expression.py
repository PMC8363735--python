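"""Isodecoder differential expression with the NB exact test.

Counts are CPM-normalized and filtered (mean CPM >= 20 in a group), then
tested with a conditional negative-binomial exact test at a common
method-of-moments dispersion; calls require BKY q < 0.05 and
|fold change| >= 1.5.
"""

import pandas as pd

from glytrome import ScenarioConfig, expression as expr
from glytrome import simulate as sim

cfg = ScenarioConfig(seed=42)
ref = sim.generate_reference(cfg)
counts = sim.generate_count_tables(ref, cfg)

de = expr.isodecoder_de(expr.CountMatrix(counts))
families = pd.Series({i: i.split("-")[1] for i in de.index})

gly = de[families == "Gly"].sort_values("logfc")
print(gly[["mean_cpm_wt", "mean_cpm_ko", "logfc", "q",
           "significant"]].round(3).to_string())

rollup = expr.family_rollup(de, families)
print("\nfamily roll-up (families with significant calls):")
print(rollup[rollup["n_significant"] > 0].to_string())

# The glycine family carries the depletion: negative logFC throughout,
# with the significant downregulated calls concentrated in Gly
# isodecoders, mirroring the anticodon-specific tRNA loss.
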