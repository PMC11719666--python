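"""Extract the 31 raw features (9 color means + 22 texture categories)
from a small synthetic dataset and show the class structure.

The class means reproduce the documented orderings of the real seeds:
brightness L* HAS > ZSS > ZMS; redness a* and yellowness b* highest in
ZMS; GLCM contrast highest in ZSS; homogeneity and energy highest in
HAS; every Law's texture energy highest in ZMS.
"""

import pandas as pd

from seedvision import feature_table, generate_dataset

pd.set_option("display.width", 120)

images, _ = generate_dataset(n_per_class=10, seed=42)
table = feature_table(images)
print(f"feature table: {len(table)} samples x "
      f"{table.shape[1] - 2} features\n")

means = table.groupby("label").mean(numeric_only=True)
cols = ["mean_Lstar", "mean_astar", "mean_bstar", "contrast",
        "homogeneity", "energy", "E5E5", "R5R5"]
print("class means of selected features:")
print(means[cols].round(3).T)
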