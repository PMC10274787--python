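"""Candidate effector-gene nomination by polygenic priority scoring.

Gene-level association scores are modeled from single-cell-derived features
by a GCV-tuned ridge regression; significance comes from a pooled
permutation null with empirical p = (r+1)/(n+1).
"""
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from isletime.prioritize import pops_prioritize

rng = np.random.default_rng(2)
G = 1000
X = rng.normal(size=(G, 20))
signal = 2 * X[:, 0] + X[:, 1] - 1.5 * X[:, 2]  # 3 informative features
scores = pd.Series(signal + rng.normal(0, 0.8, G),
                   index=[f"g{i}" for i in range(G)])
features = pd.DataFrame(X, index=scores.index)

res = pops_prioritize(features, scores, n_perm=1000, seed=3)
print(f"ridge penalty chosen by GCV: {res.alpha:.3g}")
print(f"significant genes at FDR<5%: {int(res.table['significant'].sum())}")

top_true = set(np.argsort(signal)[-100:])
top_pred = set(np.argsort(res.table["score"].to_numpy())[-100:])
k = len(top_true & top_pred)
print(f"top-decile overlap with planted high-score genes: {k}/100 "
      f"(hypergeometric p = {hypergeom.sf(k - 1, G, 100, 100):.2e})")

null_scores = pd.Series(rng.normal(size=G), index=scores.index)
res0 = pops_prioritize(features, null_scores, n_perm=1000, seed=4)
print(f"with feature-independent scores: "
      f"{int(res0.table['significant'].sum())} significant genes")
# The planted 3-feature signal dominates the ranking; scores unrelated to
# the features produce (essentially) no discoveries.
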