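"""Interpolated response time from expression-space neighbors.

t_hat = t*w + (inverse-distance-weighted mean neighbor time)*(1-w).
Cells sampled at the same hour sit at different response phases; blending
the sampled time with the neighborhood average orders cells by phase better
than the sampled time alone.
"""
import dataclasses

import numpy as np
from scipy.stats import spearmanr

import isletime as it
from isletime.pipeline import _interpolate_all

# worked formula example: t=4, w=0.25, neighbors (d,t) = (1,2), (2,4), (4,8)
F = np.zeros((4, 3))
F[1, 0], F[2, 1], F[3, 2] = 1.0, 2.0, 4.0
th = it.interpolate_time(F, np.array([4.0, 2.0, 4.0, 8.0]),
                         it.InterpolationParams(n=3, w=0.25))
print(f"worked example: t_hat = {th[0]:.6f} (= 25/7)")

cfg = dataclasses.replace(
    it.SimulationConfig(),
    cell_types=(it.CellTypeSpec("beta", 1.0, ("INS",)),),
    n_genes=800, n_cells_per_well=150, n_replicates_per_donor=1,
    base_log_sd=0.8,
    effect_spec=it.EffectSpec(n_time_genes=300, time_log_fc=1.2,
                              n_glucose_genes=0, n_interaction_genes=0),
    hurdle_spec=it.HurdleSpec(mean_detection=0.8),
    depth_spec=it.DepthSpec(log_mean=np.log(20000.0)))
counts, truth = it.simulate_dataset(cfg, seed=1)
filtered, _ = it.apply_qc_filters(counts)
expr = it.normalize_log_cp10k(filtered)
labels = truth.cells.loc[expr.obs_names, "cell_type"]
t_hat, _ = _interpolate_all(expr, labels, n=75, w=0.25, seed=0)

phase = truth.cells.loc[expr.obs_names, "phase_time_h"]
for arm in ("low", "high"):
    sel = (expr.obs["glucose_arm"] == arm) & (expr.obs["time_h"] > 0)
    cells = t_hat.index.intersection(expr.obs.index[sel])
    r_hat = spearmanr(t_hat[cells], phase[cells]).statistic
    r_t = spearmanr(expr.obs.loc[cells, "time_h"], phase[cells]).statistic
    print(f"{arm:4s} arm: Spearman(t_hat, true phase) = {r_hat:.3f}  "
          f"vs Spearman(t, true phase) = {r_t:.3f}")
# A positive gap means the interpolated time recovers the planted
# response-phase ordering better than the sampled time point does.
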