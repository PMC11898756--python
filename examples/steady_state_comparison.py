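"""Differential proteome analysis between two adapted conditions.

Builds a small MaxQuant-style protein-groups table with three replicates per
carbon source, applies the acceptance filter, log10 transform and
down-shifted-normal imputation, and calls fivefold differential expression.
"""

import numpy as np
import pandas as pd

import pulselab as pl

rng = np.random.default_rng(0)
samples = ["glu_1", "glu_2", "glu_3", "gal_1", "gal_2", "gal_3"]
condition_map = {s: ("glucose" if s.startswith("glu") else "galactose") for s in samples}

n = 200
base = rng.uniform(6.5, 9.5, n)  # log10 LFQ levels
shift = np.zeros(n)
shift[:10] = 1.0   # ten proteins 10x higher on glucose
shift[10:20] = -1.0  # ten proteins 10x lower
rows = {"Protein IDs": [f"P{i:04d}" for i in range(n)],
        "Reverse": "", "Only identified by site": "",
        "Peptides": 5, "Unique peptides": 2}
table = pd.DataFrame(rows)
for s in samples:
    level = base + (shift if condition_map[s] == "glucose" else 0.0)
    values = 10 ** (level + rng.normal(0, 0.05, n))
    values[values < 10**7] = 0.0  # detection-limit censoring
    table[f"LFQ intensity {s}"] = values
    table[f"iBAQ {s}"] = values

kept, drops = pl.acceptance_filter(table, condition_map)
log_lfq = pl.log10_transform(kept, [f"LFQ intensity {s}" for s in samples])
log_lfq.columns = samples
imputed = pl.impute_missing(log_lfq, seed=1)
de = pl.fold_change_de(imputed, condition_map, "glucose", "galactose",
                       cutoff=5, protein_ids=kept["Protein IDs"])

print(f"proteins after filtering:  {len(kept)} (drops: {drops})")
print(f"differential at fivefold:  {int(de['is_differential'].sum())}")
print(de[de["is_differential"]].head(8).to_string(index=False))
print()
print("fold_change = 10^(mean log10 glucose - mean log10 galactose);")
print("values >= 5 or <= 0.2 are called differentially expressed.")
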