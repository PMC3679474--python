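"""Housekeeping-normalised expression and the MMP-9:TIMP-1 ratio.

Builds a Ct table with a programmed protease/antiprotease shift in the
combined-insult group (MMP9 up, TIMP1 down vs the RPL13a housekeeping
gene), then computes per-animal relative expression and ratios.
"""

import pandas as pd

from lungquant import generate_ct_table, mmp9_timp1_ratio, relative_expression

animals = pd.DataFrame({
    "animal_id": [f"m{i}" for i in range(8)],
    "group": ["CD-NS"] * 4 + ["VDD-CSE"] * 4,
})
log2fc = {"MMP9": {"VDD-CSE": 0.8}, "TIMP1": {"VDD-CSE": -1.0}}
ct = generate_ct_table(animals, log2fc=log2fc, ct_noise_sd=0.3, seed=5)

rel = relative_expression(ct)  # rel = 2^-(Ct_gene - Ct_RPL13a)
per_animal, per_group = mmp9_timp1_ratio(rel)

print(per_group.round(3).to_string(index=False))
# The programmed shift is 0.8 - (-1.0) = 1.8 log2 units, so the
# VDD-CSE group's mean ratio sits near 2^1.8 ~ 3.5x the control group's.
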