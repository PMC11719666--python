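"""PCA, PLS-DA with permutation validation, and VIP/ANOVA marker
selection on the fused fire-ice table.

With only two variables, the full 2-component PCA necessarily explains
100.0% of the variance; the interesting outputs are the PLS-DA fit
quality (R2Y, cross-validated Q2), the permutation p-value (small =
the class separation is not an overfit), and which of the two fused
scalars passes the VIP > 1 and p < 0.05 marker rule.
"""

from seedvision import (generate_dataset, one_way_anova, pca,
                        permutation_test, reduce_dataset, select_markers)

images, _ = generate_dataset(n_per_class=30, seed=42)
fused = reduce_dataset(images)
X = fused[["fire", "ice"]]
labels = fused["label"]

res = pca(X, ncomp=2)
print(f"PCA explained %: PC1 {res.explained_pct[0]:.1f}, "
      f"PC2 {res.explained_pct[1]:.1f}, "
      f"cumulative {res.explained_pct.sum():.1f}")

perm = permutation_test(X, labels, ncomp=2, nperm=200, seed=42)
m = perm.model
print(f"PLS-DA: R2Y {m.r2y:.4f}, Q2 {m.q2:.4f} "
      f"(7-fold stratified CV), permutation p {perm.p_value:.4f}")

_, pvals = one_way_anova(X, labels)
markers = select_markers(m.vip, pvals, ["fire", "ice"])
for name, v, p in zip(["fire", "ice"], m.vip, pvals):
    flag = "selected" if name in markers.names else "not selected"
    print(f"  {name}: VIP {v:.4f}, ANOVA p {p:.2e} -> {flag}")
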