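"""Reverse validation: four classifier families on the raw 31-feature
table versus the fused 2-feature fire-ice table.

Each model trains on a stratified 70% split and is scored on the held
out 30%. If the two fused scalars match the raw features' accuracy, the
fusion kept the discriminative signal while cutting the dimensionality
by a factor of ~15.
"""

from seedvision import (MODEL_KINDS, SplitSpec, compare_matrices,
                        feature_table, generate_dataset, reduce_dataset,
                        stratified_split, train_eval)

images, _ = generate_dataset(n_per_class=30, seed=42)
raw = feature_table(images)
fused = reduce_dataset(images)

spec = SplitSpec(seed=42)
raw_tr, raw_te = stratified_split(raw, spec)
fi_tr, fi_te = stratified_split(fused, spec)

raw_reports, fi_reports = {}, {}
for kind in MODEL_KINDS:
    raw_reports[kind] = train_eval(kind, raw_tr, raw_te, seed=42)
    fi_reports[kind] = train_eval(kind, fi_tr, fi_te, seed=42)
    r, f = raw_reports[kind], fi_reports[kind]
    print(f"{kind:3s} raw: train {r.train_accuracy:6.2f}% "
          f"test {r.test_accuracy:6.2f}%   fire-ice: "
          f"train {f.train_accuracy:6.2f}% test {f.test_accuracy:6.2f}%")

comparison = compare_matrices(raw_reports, fi_reports)
print(f"\nmean test-accuracy delta (fire-ice minus raw): "
      f"{comparison['delta'].mean():+.2f} points")
print("\nfire-ice RF confusion matrix (rows = true class):")
print(fi_reports["RF"].confusion)
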