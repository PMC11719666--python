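"""Fuse the 31 features of each seed into the two fire-ice scalars.

The fire value fuses the nine range-normalized color channels over the
Otsu fire foreground; the ice value fuses the 22 bounded-normalized
texture categories. Per-class fire means follow the brightness ordering
HAS > ZSS > ZMS, and the two scalars alone keep the classes separated.
"""

from seedvision import generate_dataset, reduce_dataset

images, _ = generate_dataset(n_per_class=10, seed=42)
fused = reduce_dataset(images)

print(fused.head(3).round(4).to_string(index=False))
print()
stats = fused.groupby("label")[["fire", "ice"]].agg(["mean", "std"]).round(4)
print(stats)
means = fused.groupby("label")["fire"].mean()
print("\nfire ordering:",
      " > ".join(means.sort_values(ascending=False).index))
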