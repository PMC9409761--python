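"""Correlation structure, principal components and hierarchical clusters.

All three operate on the genotype x trait matrix of adjusted means, with
traits standardised so that centimetre- and gram-scaled traits weigh
equally.
"""

from phenodiv import (
    adjusted_means_frame,
    correlation_matrix,
    hierarchical_cluster,
    paper_like_fixture,
    pca,
)

trial, _ = paper_like_fixture(seed=1)
means = adjusted_means_frame(trial)

corr = correlation_matrix(means)
r = corr.r.loc["YP", "NFP"]
print(f"yield vs fruits-per-plant: r = {r:.2f} {corr.stars.loc['YP', 'NFP']}")

res = pca(means)
print(f"\nretained components (eigenvalue >= 1): {res.n_retained}")
for i in range(res.n_retained):
    print(f"  PC{i + 1}: eigenvalue {res.eigenvalues[i]:.3f}, "
          f"cumulative {res.cumulative[i]:.1f}% of variance")

clus = hierarchical_cluster(means, k=6, linkage="complete")
sizes = clus.assignments.value_counts().sort_index()
print("\ncluster sizes:", {int(k): int(v) for k, v in sizes.items()})
print("\ncluster means (original units, first 6 traits):")
print(clus.cluster_means.iloc[:, :6].to_string(float_format=lambda v: f"{v:.1f}"))
print("\nClusters whose means are extreme for a target trait point to the")
print("accession groups worth crossing to improve that trait.")
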