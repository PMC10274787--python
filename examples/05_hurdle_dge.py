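"""Two-part hurdle differential expression: discrete and continuous designs.

Each gene gets a logistic (detected or not) and a Gaussian (level when
detected) regression; dropping the tested term from both parts gives a
summed-χ² likelihood-ratio test.  Planted glucose effects should surface in
the low-vs-high (LvH) contrast but not in basal-vs-low (BvL).
"""
import dataclasses

import numpy as np

import isletime as it
from isletime.hurdle import HurdleDesign, run_design

cfg = dataclasses.replace(
    it.SimulationConfig(),
    cell_types=(it.CellTypeSpec("beta", 1.0, ("INS",)),),
    n_genes=1200, n_cells_per_well=120, n_replicates_per_donor=1,
    base_log_sd=0.8,
    effect_spec=it.EffectSpec(0, 0.0, 40, 1.0, 0, 0.0),
    module_spec=it.ModuleSpec(sizes=(), shapes=()),
    hurdle_spec=it.HurdleSpec(mean_detection=0.85, logit_sd=0.5),
    depth_spec=it.DepthSpec(log_mean=np.log(50000.0)))
counts, truth = it.simulate_dataset(cfg, seed=2)
filtered, _ = it.apply_qc_filters(counts)
expr = it.normalize_log_cp10k(filtered)
labels = truth.cells.loc[expr.obs_names, "cell_type"]
planted = truth.genes.index[truth.genes["glucose_effect"]]

for design in (HurdleDesign("LvH", 24.0), HurdleDesign("BvL", 24.0),
               HurdleDesign("glucose")):
    res = run_design(expr, design, "beta", labels).set_index("gene")
    hits = res.reindex(planted)["q"] < 0.05
    fpr = (res.drop(index=planted.intersection(res.index))["p"] < 0.05).mean()
    print(f"{design.name:8s}: planted glucose genes recovered "
          f"{int(hits.sum())}/{len(planted)}  |  null-gene p<0.05 rate {fpr:.3f}")

res = run_design(expr, HurdleDesign("LvH", 24.0), "beta", labels)
top = res.nsmallest(5, "p")[["gene", "coef_cont", "chisq", "df", "p", "q"]]
print("\ntop LvH genes at 24 h:")
print(top.round(4).to_string(index=False))
# LvH and the continuous glucose model flag the planted genes; BvL, which
# compares basal to low glucose and never sees the high arm, stays null.
# The elevated null-gene rate of the same-axis contrasts is the CP10K
# compositional artifact: 40 strongly shifted genes move every other gene's
# relative abundance slightly in the opposite direction.
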