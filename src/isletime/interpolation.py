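"""Interpolated time: expression-neighborhood smoothing of sampled times.

Cells captured at the same nominal time point are not synchronized in their
response phase.  Interpolated time blends each cell's sampled time ``t`` with
the inverse-distance-weighted mean sampled time of its ``n`` nearest
expression-space neighbors::

    t_hat = t * w + (sum_i t_i / d_i) / (sum_i 1 / d_i) * (1 - w)

Distances are Euclidean in the knee-selected PC space of the cell type ×
glucose-arm stratum (configurable).  The 0 h time point is excluded upstream
(it has no high-glucose arm).  Raw values are min-max standardized to [0, 1]
within each stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .annotation import kneedle

__all__ = ["InterpolationParams", "InterpolatedTime", "stratum_embedding",
           "interpolate_time", "select_params", "standardize_time"]

_EPS = 1e-12  # floor for inverse-distance weights at zero distance


@dataclass(frozen=True)
class InterpolationParams:
    n: int = 75
    w: float = 0.25
    n_grid: tuple[int, ...] = tuple(range(0, 151, 5))
    w_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    distance_space: str = "pca"

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")


@dataclass
class InterpolatedTime:
    t_sampled: pd.Series
    t_hat_raw: pd.Series
    t_hat_std: pd.Series | None
    params: InterpolationParams
    warnings: list[str] = field(default_factory=list)


def stratum_embedding(values: np.ndarray, max_pcs: int = 30,
                      seed: int = 0,
                      nuisance: np.ndarray | None = None) -> np.ndarray:
    """Knee-selected PC coordinates of one stratum's expression matrix.

    ``nuisance`` (typically log total counts) is linearly regressed out of
    the PC coordinates so neighbor distances are not dominated by sequencing
    depth — the same nuisance the differential-expression models absorb via
    the cell-complexity covariate.
    """
    values = np.asarray(values, dtype=float)
    n_comp = int(min(max_pcs, values.shape[0] - 1, values.shape[1]))
    if n_comp < 2:
        return values
    pca = PCA(n_components=n_comp, svd_solver="randomized", random_state=seed)
    pcs = pca.fit_transform(values - values.mean(axis=0))
    n_keep = max(2, kneedle(pca.explained_variance_ratio_))
    pcs = pcs[:, :n_keep]
    if nuisance is not None:
        d = np.asarray(nuisance, dtype=float)[:, None]
        d = d - d.mean()
        pcs = pcs - d @ np.linalg.lstsq(d, pcs, rcond=None)[0]
    return pcs


def interpolate_time(features: np.ndarray, times: np.ndarray,
                     params: InterpolationParams) -> np.ndarray:
    """Raw interpolated time for every cell of one stratum.

    ``features`` are the coordinates used for the neighbor search (PC space
    by convention); ``times`` the sampled times in hours.  Neighbors exclude
    the cell itself; zero distances are floored at 1e-12 so inverse-distance
    weights stay finite.  With ``n = 0``, ``w`` must be 1 (pure sampled time).
    """
    features = np.asarray(features, dtype=float)
    times = np.asarray(times, dtype=float)
    if features.shape[0] != times.shape[0]:
        raise ValueError("features and times must align")
    n, w = params.n, params.w
    if n == 0:
        if w < 1.0:
            raise ValueError("n=0 requires w=1 (no neighbors to average)")
        return times.copy()
    if n >= features.shape[0]:
        raise ValueError(f"n={n} must be smaller than the stratum size "
                         f"{features.shape[0]}")
    nn = NearestNeighbors(n_neighbors=n + 1).fit(features)
    dist, idx = nn.kneighbors(features)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    inv = 1.0 / np.maximum(dist, _EPS)
    neighbor_term = (inv * times[idx]).sum(axis=1) / inv.sum(axis=1)
    return times * w + neighbor_term * (1.0 - w)


def select_params(features: np.ndarray, times: np.ndarray,
                  n_grid: tuple[int, ...] | None = None,
                  w_grid: tuple[float, ...] | None = None,
                  stability_tol: float | None = None,
                  default_w: float = 0.25) -> tuple[InterpolationParams, pd.DataFrame]:
    """Stability-based selection of the neighbor count ``n``.

    For each ``w``, interpolated time is computed along the ``n`` grid and
    the mean squared difference between consecutive ``n`` values recorded.
    The selected ``n`` is the smallest grid value after which every
    subsequent MSE step stays below ``stability_tol`` (default: 1 % of the
    variance of the sampled times), maximized across ``w`` values.  ``w``
    itself defaults to ``default_w``; the stability curve is returned so a
    caller can run its own downstream-concordance check.
    """
    base = InterpolationParams()
    n_grid = tuple(n_grid if n_grid is not None else base.n_grid)
    w_grid = tuple(w_grid if w_grid is not None else base.w_grid)
    if len(n_grid) < 2:
        raise ValueError("n grid must contain at least two values")
    n_grid = tuple(n for n in sorted(n_grid) if n < len(times))
    times = np.asarray(times, dtype=float)
    if stability_tol is None:
        stability_tol = 0.01 * max(times.var(), 1e-12)

    rows = []
    chosen_n: dict[float, int] = {}
    for w in w_grid:
        prev = None
        mses = []
        for n in n_grid:
            if n == 0 and w < 1.0:
                t_hat = times.copy()  # n=0 column treated as pure self time
            else:
                t_hat = interpolate_time(features, times,
                                         InterpolationParams(n=n, w=w))
            if prev is not None:
                mses.append(float(np.mean((t_hat - prev) ** 2)))
            prev = t_hat
        for n, mse in zip(n_grid[1:], mses):
            rows.append((w, n, mse))
        stable = [i for i in range(len(mses))
                  if all(m <= stability_tol for m in mses[i:])]
        chosen_n[w] = n_grid[1 + stable[0]] if stable else n_grid[-1]

    diagnostics = pd.DataFrame(rows, columns=["w", "n", "mse_vs_prev_n"])
    n_star = max(chosen_n.values()) if chosen_n else n_grid[-1]
    return InterpolationParams(n=int(n_star), w=default_w,
                               n_grid=n_grid, w_grid=w_grid), diagnostics


def standardize_time(t_hat: pd.Series, strata: pd.Series) -> tuple[pd.Series, list[str]]:
    """Min-max scale interpolated time to [0, 1] within each stratum.

    Constant strata map to 0.5 with a warning rather than an error.
    """
    out = pd.Series(np.nan, index=t_hat.index, dtype=float)
    warnings_: list[str] = []
    for key, idx in t_hat.groupby(strata, observed=True).groups.items():
        vals = t_hat.loc[idx]
        lo, hi = vals.min(), vals.max()
        if hi - lo <= 0:
            out.loc[idx] = 0.5
            warnings_.append(f"stratum {key}: constant interpolated time")
        else:
            out.loc[idx] = (vals - lo) / (hi - lo)
    return out, warnings_
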