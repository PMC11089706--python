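"""Covariate-adjusted NB differential region expression.

Counts are modelled as NB with variance mu + alpha*mu^2 and design
(intercept, status, gender, age); the status coefficient is the
case-vs-control log2 fold change. Because global expression structure
follows gender, not tumor status (check the PCA), the test adjusts for
gender and age. Planted markers are snoRNA regions with log2 fold
changes of about -2 to -3.5 (lower in cases).
"""

import numpy as np
from scipy.stats import pearsonr

import uroev

cfg = uroev.SimulationConfig(seed=11, n_case=47, n_control=16,
                             n_contaminated=0, n_contigs=2,
                             contig_length=50_000)
sheet = uroev.simulate_cohort(cfg)
index, annotation = uroev.simulate_genome(cfg)
grid = uroev.tile_genome(index, cfg.region_width)
counts, truth = uroev.simulate_counts(cfg, grid, sheet, annotation)
filtered = uroev.filter_expressed(counts)

# cohort structure: PCA of log2(TPM+1)
tpm = uroev.compute_tpm(filtered)
scores, _, var_exp = uroev.pca(uroev.log_transform(tpm), n_components=2)
meta = sheet.rows.set_index("sample_id")
male = (meta["gender"] == "male").astype(float)[scores.index]
case = (meta["group"] == "case").astype(float)[scores.index]
print("PC1 correlation with gender: %.2f, with status: %.2f"
      % (pearsonr(scores["PC1"], male)[0], pearsonr(scores["PC1"], case)[0]))

# complete-linkage clustering on the same matrix: cutting the tree into
# two groups recovers gender far better than tumor status
from scipy.cluster.hierarchy import fcluster
Z, ids = uroev.hierarchical_cluster(uroev.log_transform(tpm))
two = fcluster(Z, t=2, criterion="maxclust")


def agreement(labels):
    """Best accuracy over the two ways of naming the clusters."""
    vals = labels.unique()
    hits = ((two == 1) == (labels == vals[0]).to_numpy()).mean()
    return max(hits, 1 - hits)


print("2-cluster agreement: gender %.2f, status %.2f"
      % (agreement(meta["gender"][ids]), agreement(meta["group"][ids])))

de = uroev.differential_expression(filtered, sheet, annotation=annotation)
sig = de.result[de.result["p_adjusted"] < 0.05]
print(f"\n{len(sig)} of {len(de.result)} regions significant at FDR < 0.05")
print(sig[["log2fc", "p_adjusted", "genes"]].head(10).round(3).to_string())

markers = set(truth.marker_region_ids)
print("\nplanted markers recovered:",
      f"{len(set(sig.index) & markers)}/{len(markers)}")
print("all significant fold changes negative (lower in cases):",
      bool((sig['log2fc'] < 0).all()))
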