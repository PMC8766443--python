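"""Cluster a mixed-cell-line run and gate a clonal B-cell population.

Part 1 mirrors the benchmarking experiment: k-means (k = 4) on the top-3
principal components of CLR scores separates the two cell lines, the
hashtag-only controls, and non-specifically stained cells.

Part 2 mirrors the clinical readout: gate CD19+CD3- B cells inside CD45+
and compute the kappa/lambda light-chain ratio, whose normal range is 1-2.
"""

import numpy as np

import qbc2 as q

# --- part 1: two cell lines + controls --------------------------------
_, cfg = q.fixture_config("two_lines", seed=3, n_cells=800,
                          ht3_spike_fraction=0.0)
cells = q.simulate_cells(cfg)
clr = q.clr_transform(q.counts_from_truth(cells, cfg.panel))
emb = q.pca(clr, n_components=3)
labels = q.kmeans_cluster(emb.coords, k=4, seed=0)
truth = np.array([c.cell_type for c in cells])
print("k-means (k=4) on top-3 PCs of CLR scores:")
for k in np.unique(labels):
    members = truth[labels == k]
    top = max(set(members), key=list(members).count)
    purity = (members == top).mean()
    print(f"  cluster {k}: {len(members):4d} cells, dominant type "
          f"{top:12s} (purity {purity:.0%})")

mask = q.flag_nonspecific(clr, q.pca(clr, 4),
                          control_markers=["IgG1-isotype", "HT3"])
print(f"non-specific cells flagged: {mask.sum()} "
      f"(simulated: {(truth == 'nonspecific').sum()})")

# --- part 2: clonal B-cell gating -------------------------------------
_, cfg2 = q.fixture_config("ten_patients", seed=4, cells_per_sample=80,
                           ht2_spike_fraction=0.0, ht3_spike_fraction=0.0)
cfg2.sample_sizes = {"p1": 1000}
# clonal kappa-restricted B cells on top of a residual normal repertoire
cfg2.sample_composition = {"p1": {"cll_kappa": 0.45, "b_kappa": 0.05,
                                  "b_lambda": 0.05, "t_cd4": 0.2,
                                  "t_cd8": 0.1, "nk": 0.05, "mono": 0.1}}
cfg2.hashtag_code = q.HashtagCode({"p1": frozenset({"H1"})})
cells2 = q.simulate_cells(cfg2)
clr2 = q.clr_transform(q.counts_from_truth(cells2, cfg2.panel))

gates = q.gate(clr2, "CD45", ">", threshold=0.0, name="CD45+")
gates = q.gate(clr2, "CD19", ">", parent="CD45+", gates=gates, name="CD19+")
gates = q.gate(clr2, "CD3", "<", parent="CD19+", gates=gates,
               name="CD19+CD3-")
b_frac = gates.fraction_of_parent("CD19+") * \
    gates.fraction_of_parent("CD19+CD3-")
print(f"\nB cells (CD19+CD3-) among CD45+: "
      f"{gates.entries['CD19+CD3-'].count} "
      f"({b_frac:.0%} of {gates.entries['CD45+'].count} CD45+ cells)")

result = q.kappa_lambda_ratio(clr2, gates.mask("CD19+CD3-"))
print(f"kappa+: {result.n_kappa}, lambda+: {result.n_lambda}, "
      f"ratio {result.ratio:.1f} -> {result.interpretation}")
print()
print("Meaning: the clusters recover the mixed populations with high")
print("purity, and the gated B-cell compartment shows a kappa-restricted")
print("(ratio > 2) clonal expansion, the leukemia signature this assay")
print("is designed to surface.")
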