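"""Cluster cells, pick the resolution by the minimum-MCC rule, label types.

A multinomial logistic classifier is trained on 2/3 of the cells per
resolution; the largest resolution whose worst cluster still exceeds MCC
0.75 on held-out cells wins.  Clusters are labeled by their best marker.
"""
import dataclasses

import isletime as it

cfg = dataclasses.replace(it.SimulationConfig(), n_genes=900,
                          n_cells_per_well=40, n_replicates_per_donor=1)
counts, truth = it.simulate_dataset(cfg, seed=1)
filtered, _ = it.apply_qc_filters(counts)
expr = it.normalize_log_cp10k(filtered)

emb = it.embed_cells(expr, seed=0)
print(f"knee-selected PCs: {emb.n_pcs}")

res = it.resolution_sweep(emb, expr, resolutions=(0.05, 0.1, 0.25, 0.5),
                          seed=0)
print(res.sweep.round(3).to_string(index=False))
print(f"chosen resolution: {res.resolution}")

labels, ties = it.assign_cell_types(res.clusters, expr,
                                    it.default_marker_table(cfg))
truth_types = truth.cells.loc[labels.index, "cell_type"]
acc = (labels == truth_types).mean()
print(f"cells labeled with their true type: {acc:.1%}")
# The sweep table shows the MCC rule at work: coarse resolutions produce
# classifier-separable clusters (high min MCC); resolutions that shatter a
# real population fail and are rejected.
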