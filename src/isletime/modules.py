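"""Temporal co-expression modules from smoothed profiles.

Pipeline: genes differentially expressed in any non-BvH design are smoothed
over standardized interpolated time (local polynomial regression, one fit per
glucose arm, evaluated on a 21-point grid), clustered with a Dirichlet-process
mixture of Gaussian processes (DPGP), stabilized by consensus over 45
(alpha, num-empty-clusters) configurations, and the consensus co-clustering
matrix is cut into modules by an iterative k-means rule (extract clusters
whose minimum within-cluster co-clustering frequency is ≥ 0.75, repeat until
no genes remain, drop modules of < 5 genes).

DPGP model: each cluster has a latent mean curve with a zero-mean GP prior
(squared-exponential kernel; per-cluster length-scale resampled over a fixed
grid) and genes scatter around it with iid Gaussian noise of a global,
Gibbs-sampled variance.  Cluster means are marginalized analytically, so the
collapsed Gibbs sampler (Neal's algorithm 8, ``n_aux`` auxiliary clusters)
only needs diagonal computations in the kernel eigenbasis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = ["SmoothedProfiles", "DPGPResult", "ConsensusResult", "ModuleSet",
           "select_module_genes", "smooth_profiles", "dpgp_cluster",
           "default_config_grid", "consensus_from_runs", "extract_modules"]

GRID = np.round(np.arange(0.0, 1.0001, 0.05), 10)  # 21 points


# ---------------------------------------------------------------------------
# gene selection and smoothing
# ---------------------------------------------------------------------------

def select_module_genes(dge_results, fdr: float = 0.05) -> list[str]:
    """Union of genes at q < fdr in any design other than BvH."""
    genes: set[str] = set()
    for res in dge_results:
        sub = res[(res["design"] != "BvH") & (res["q"] < fdr)]
        genes |= set(sub["gene"])
    return sorted(genes)


@dataclass
class SmoothedProfiles:
    values: np.ndarray          # genes × 21 × arms
    genes: list[str]
    arms: tuple[str, ...]
    grid: np.ndarray
    frac: float                 # lowess bandwidth (fraction of points)
    linear_fallback: dict[str, bool] = field(default_factory=dict)

    def concatenated(self) -> np.ndarray:
        """genes × (21 × n_arms), arms side by side."""
        return self.values.transpose(0, 2, 1).reshape(self.values.shape[0], -1)


def smooth_profiles(y: np.ndarray, t_hat_std: np.ndarray, arm_labels,
                    genes: list[str], frac: float = 0.3,
                    arms: tuple[str, ...] = ("low", "high"),
                    min_cells: int = 10) -> SmoothedProfiles:
    """Per-gene, per-arm lowess fits evaluated on the 21-point time grid.

    ``y`` is the cells × genes ln(CP10K+1) matrix restricted to the chosen
    genes; an arm with fewer than ``min_cells`` cells falls back to a global
    linear fit (flagged).
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t_hat_std, dtype=float)
    arm_labels = np.asarray(arm_labels)
    out = np.zeros((y.shape[1], len(GRID), len(arms)))
    fallback: dict[str, bool] = {}
    for ai, arm in enumerate(arms):
        sel = arm_labels == arm
        if not sel.any():
            raise ValueError(f"arm {arm!r} has no cells")
        ta, ya = t[sel], y[sel]
        use_linear = sel.sum() < min_cells
        fallback[arm] = bool(use_linear)
        order = np.argsort(ta, kind="stable")
        ta_o = ta[order]
        for gi in range(y.shape[1]):
            yg = ya[order, gi]
            if use_linear or np.ptp(ta_o) == 0:
                coef = np.polyfit(ta_o, yg, 1) if np.ptp(ta_o) > 0 else [0.0, yg.mean()]
                out[gi, :, ai] = np.polyval(coef, GRID)
            else:
                out[gi, :, ai] = lowess(yg, ta_o, frac=frac, it=0, xvals=GRID)
    if not np.isfinite(out).all():
        # lowess can emit NaN outside the data range; patch by interpolation
        for gi in range(out.shape[0]):
            for ai in range(out.shape[2]):
                v = out[gi, :, ai]
                bad = ~np.isfinite(v)
                if bad.any():
                    v[bad] = np.interp(GRID[bad], GRID[~bad], v[~bad])
    return SmoothedProfiles(values=out, genes=list(genes), arms=arms,
                            grid=GRID.copy(), frac=frac,
                            linear_fallback=fallback)


# ---------------------------------------------------------------------------
# DPGP sampler
# ---------------------------------------------------------------------------

@dataclass
class DPGPResult:
    assignments: np.ndarray      # MAP-sample cluster id per gene (0..k-1)
    similarity: np.ndarray       # posterior co-assignment frequency
    log_posterior_trace: np.ndarray
    map_log_posterior: float
    converged: bool
    sigma2: float


def _se_kernel_eigen(D: int, segments: np.ndarray, ls_grid, jitter=1e-6):
    """Eigendecompositions of block-diagonal SE kernels, one per length-scale."""
    coords = np.zeros(D)
    for seg in np.unique(segments):
        idx = np.where(segments == seg)[0]
        coords[idx] = np.linspace(0.0, 1.0, len(idx))
    lams, vecs = [], []
    for ls in ls_grid:
        K = np.exp(-0.5 * ((coords[:, None] - coords[None, :]) / ls) ** 2)
        K *= (segments[:, None] == segments[None, :])
        K += jitter * np.eye(D)
        lam, E = np.linalg.eigh(K)
        lams.append(np.clip(lam, 1e-10, None))
        vecs.append(E)
    return np.array(lams), vecs


def _cluster_joint_ll(n, S, sq, lam, sigma2):
    """Marginal log-likelihood of n member curves with the cluster mean
    integrated out (eigenbasis sums S, total squared norm sq)."""
    D = lam.shape[-1]
    denom = n * lam + sigma2
    quad = sq - (lam * S ** 2 / denom).sum(-1)
    return (-0.5 * n * D * np.log(2 * np.pi)
            - 0.5 * (n - 1) * D * np.log(sigma2)
            - 0.5 * np.log(denom).sum(-1)
            - 0.5 * quad / sigma2)


def dpgp_cluster(profiles: np.ndarray, alpha: float = 1.0, n_aux: int = 4,
                 seed: int = 0, n_iter: int = 60, burn_in: int | None = None,
                 segments: np.ndarray | None = None,
                 ls_grid: tuple[float, ...] = (0.15, 0.3, 0.6),
                 init: np.ndarray | None = None,
                 sigma2_prior: tuple[float, float] = (2.0, 0.2),
                 noise_floor: float = 0.1) -> DPGPResult:
    """Collapsed Gibbs sampling of the DP mixture of Gaussian processes.

    ``profiles`` is genes × grid-points (z-scored by the caller);
    ``segments`` labels columns by glucose arm so the kernel is
    block-diagonal across arms.  Returns the maximum-posterior sample as the
    point clustering plus the posterior pairwise co-assignment frequency.

    ``noise_floor`` bounds the Gibbs-sampled noise variance from below, on
    the scale of the standardized profiles: at least this share of a
    profile's unit variance is treated as unstructured, so smooth gene-level
    deviations below that scale do not splinter clusters.
    """
    Y = np.asarray(profiles, dtype=float)
    G, D = Y.shape
    if G < 2:
        raise ValueError("need at least two genes to cluster")
    if burn_in is None:
        burn_in = max(2, n_iter // 3)
    segments = (np.zeros(D, dtype=int) if segments is None
                else np.asarray(segments))
    rng = np.random.default_rng(seed)
    L = len(ls_grid)
    LAM, EIG = _se_kernel_eigen(D, segments, ls_grid)
    YT = np.stack([Y @ EIG[l] for l in range(L)])     # L × G × D
    sqn = (Y ** 2).sum(axis=1)                         # per-gene ||y||²

    maxk = G + n_aux + 1
    S = np.zeros((maxk, D))        # eigenbasis member sums, in own ls basis
    nmem = np.zeros(maxk, dtype=int)
    lsi = np.zeros(maxk, dtype=int)
    sqsum = np.zeros(maxk)
    c = np.zeros(G, dtype=int) if init is None else np.asarray(init).copy()
    sigma2 = max(0.3, noise_floor)
    a0, b0 = sigma2_prior

    for cid in np.unique(c):
        mem = c == cid
        lsi[cid] = 0
        S[cid] = YT[0][mem].sum(axis=0)
        nmem[cid] = mem.sum()
        sqsum[cid] = sqn[mem].sum()

    def active_ids():
        return np.where(nmem > 0)[0]

    sim = np.zeros((G, G))
    n_samples = 0
    trace = []
    best_lp, best_c = -np.inf, c.copy()

    for sweep in range(n_iter):
        # per-(ls, gene) empty-cluster predictive, refreshed when sigma2 moves
        v0 = LAM + sigma2                                   # L × D
        ll_empty = (-0.5 * np.log(2 * np.pi * v0).sum(axis=1)[:, None]
                    - 0.5 * (YT ** 2 / v0[:, None, :]).sum(axis=2))  # L × G

        for g in range(G):
            old = c[g]
            S[old] -= YT[lsi[old], g]
            nmem[old] -= 1
            sqsum[old] -= sqn[g]
            if nmem[old] == 0:
                S[old] = 0.0
                sqsum[old] = 0.0
            act = active_ids()
            k = len(act)
            lam_k = LAM[lsi[act]]                           # k × D
            denom = nmem[act][:, None] * lam_k + sigma2
            mu = lam_k * S[act] / denom
            v = sigma2 + sigma2 * lam_k / denom
            yg = YT[lsi[act], g]                            # k × D
            ll = (-0.5 * (np.log(2 * np.pi * v)
                          + (yg - mu) ** 2 / v).sum(axis=1))
            logw_exist = np.log(nmem[act]) + ll
            aux_ls = rng.integers(0, L, n_aux)
            logw_aux = np.log(alpha / n_aux) + ll_empty[aux_ls, g]
            logw = np.concatenate([logw_exist, logw_aux])
            pick = int(np.argmax(logw + rng.gumbel(size=logw.size)))
            if pick < k:
                new = act[pick]
            else:
                new = int(np.where(nmem == 0)[0][0])
                lsi[new] = aux_ls[pick - k]
                S[new] = 0.0
                sqsum[new] = 0.0
            c[g] = new
            S[new] += YT[lsi[new], g]
            nmem[new] += 1
            sqsum[new] += sqn[g]

        # resample each cluster's length-scale over the grid
        for cid in active_ids():
            mem = np.where(c == cid)[0]
            T = YT[:, mem, :].sum(axis=1)                   # L × D
            lls = _cluster_joint_ll(nmem[cid], T, sqsum[cid], LAM, sigma2)
            pick = int(np.argmax(lls + rng.gumbel(size=L)))
            lsi[cid] = pick
            S[cid] = T[pick]

        # global noise variance (inverse gamma, conditioned on sampled means)
        ss = 0.0
        for cid in active_ids():
            lam = LAM[lsi[cid]]
            denom = nmem[cid] * lam + sigma2
            post_mu = lam * S[cid] / denom
            post_var = sigma2 * lam / denom
            m = post_mu + np.sqrt(post_var) * rng.standard_normal(D)
            ss += (sqsum[cid] - 2 * m @ S[cid] + nmem[cid] * (m @ m))
        shape = a0 + 0.5 * G * D
        scale = b0 + 0.5 * max(ss, 0.0)
        sigma2 = float(np.clip(scale / rng.gamma(shape), noise_floor, 10.0))

        act = active_ids()
        lp = float(sum(_cluster_joint_ll(nmem[cid], S[cid], sqsum[cid],
                                         LAM[lsi[cid]], sigma2)
                       for cid in act))
        lp += len(act) * np.log(alpha)
        lp += sum(float(np.sum(np.log(np.arange(1, nmem[cid]))))
                  for cid in act)
        trace.append(lp)
        if sweep >= burn_in:
            sim += c[:, None] == c[None, :]
            n_samples += 1
            if lp > best_lp:
                best_lp, best_c = lp, c.copy()

    sim = sim / max(n_samples, 1)
    trace = np.asarray(trace)
    post = trace[burn_in:]
    converged = True
    if len(post) >= 8:
        half = len(post) // 2
        drift = abs(post[half:].mean() - post[:half].mean())
        spread = post.std() + 1e-8
        converged = bool(drift <= 2.0 * spread)
    if not converged:
        warnings.warn("DPGP chain shows a trend in its log-posterior trace; "
                      "increase n_iter", RuntimeWarning, stacklevel=2)
    # relabel the MAP sample contiguously
    _, labels = np.unique(best_c, return_inverse=True)
    return DPGPResult(assignments=labels, similarity=sim,
                      log_posterior_trace=trace, map_log_posterior=best_lp,
                      converged=converged, sigma2=sigma2)


# ---------------------------------------------------------------------------
# consensus over configurations
# ---------------------------------------------------------------------------

def default_config_grid() -> list[tuple[float, int]]:
    """45 (alpha, n_aux) pairs: 9 log-spaced alphas × 5 auxiliary counts."""
    alphas = np.logspace(np.log10(0.001), np.log10(10.0), 9)
    n_aux = (2, 4, 8, 12, 16)
    return [(float(a), int(m)) for a in alphas for m in n_aux]


@dataclass
class ConsensusResult:
    matrix: pd.DataFrame             # gene × gene co-clustering frequency
    n_configs_used: int
    clusterings: list[np.ndarray]
    mean_arm_similarity: np.ndarray  # diagnostic: averaged per-arm similarity
    failures: list[str] = field(default_factory=list)


def _zscore_rows(M: np.ndarray) -> np.ndarray:
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, keepdims=True)
    return (M - mu) / np.where(sd > 1e-12, sd, 1.0)


def consensus_from_runs(profiles: SmoothedProfiles,
                        configs: list[tuple[float, int]] | None = None,
                        seed: int = 0, n_iter: int = 40,
                        burn_in: int | None = None) -> ConsensusResult:
    """Consensus co-clustering over DPGP parameter configurations.

    Per configuration: one DPGP run per glucose arm, the per-arm similarity
    matrices are averaged (kept as a diagnostic), and a merged run on the
    arm-concatenated profiles is initialized from the higher-likelihood arm
    labeling; the merged clustering contributes to the consensus.  Failed
    configurations are dropped from the denominator with a warning.
    """
    configs = configs if configs is not None else default_config_grid()
    genes = profiles.genes
    G = len(genes)
    arm_mats = [_zscore_rows(profiles.values[:, :, a])
                for a in range(len(profiles.arms))]
    cat = _zscore_rows(profiles.concatenated())
    segments = np.repeat(np.arange(len(profiles.arms)), len(profiles.grid))
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(len(configs) * (len(profiles.arms) + 1))

    co = np.zeros((G, G))
    arm_sim = np.zeros((G, G))
    clusterings, failures = [], []
    used = 0
    for ci, (alpha, n_aux) in enumerate(configs):
        try:
            runs = []
            for a in range(len(arm_mats)):
                s = int(child[ci * (len(arm_mats) + 1) + a].generate_state(1)[0]
                        % (2 ** 31))
                runs.append(dpgp_cluster(arm_mats[a], alpha=alpha,
                                         n_aux=n_aux, seed=s, n_iter=n_iter,
                                         burn_in=burn_in))
            avg_sim = np.mean([r.similarity for r in runs], axis=0)
            best = max(runs, key=lambda r: r.map_log_posterior)
            s = int(child[ci * (len(arm_mats) + 1) + len(arm_mats)]
                    .generate_state(1)[0] % (2 ** 31))
            merged = dpgp_cluster(cat, alpha=alpha, n_aux=n_aux, seed=s,
                                  n_iter=n_iter, burn_in=burn_in,
                                  segments=segments, init=best.assignments)
            lab = merged.assignments
            co += lab[:, None] == lab[None, :]
            arm_sim += avg_sim
            clusterings.append(lab)
            used += 1
        except Exception as exc:  # noqa: BLE001 — config excluded, logged
            failures.append(f"config (alpha={alpha}, n_aux={n_aux}): {exc}")
            warnings.warn(failures[-1], RuntimeWarning, stacklevel=2)
    if used == 0:
        raise RuntimeError("every DPGP configuration failed")
    consensus = pd.DataFrame(co / used, index=genes, columns=genes)
    np.fill_diagonal(consensus.values, 1.0)
    return ConsensusResult(matrix=consensus, n_configs_used=used,
                           clusterings=clusterings,
                           mean_arm_similarity=arm_sim / used,
                           failures=failures)


# ---------------------------------------------------------------------------
# module extraction
# ---------------------------------------------------------------------------

@dataclass
class ModuleSet:
    modules: dict[int, list[str]]
    unassigned: list[str]
    freq_min: float
    min_size: int
    profiles: SmoothedProfiles | None = None

    def labels(self) -> pd.Series:
        lab = {}
        for mid, gs in self.modules.items():
            for g in gs:
                lab[g] = mid
        genes = sorted(set(lab) | set(self.unassigned))
        return pd.Series([lab.get(g, -1) for g in genes], index=genes,
                         name="module_id")

    def module_mean_profiles(self) -> dict[int, np.ndarray] | None:
        if self.profiles is None:
            return None
        gi = {g: i for i, g in enumerate(self.profiles.genes)}
        return {mid: self.profiles.values[[gi[g] for g in gs]].mean(axis=0)
                for mid, gs in self.modules.items()}


def _min_cofreq(consensus: np.ndarray, idx: np.ndarray) -> float:
    if len(idx) <= 1:
        return 1.0
    sub = consensus[np.ix_(idx, idx)]
    off = sub[~np.eye(len(idx), dtype=bool)]
    return float(off.min())


def extract_modules(consensus: pd.DataFrame, freq_min: float = 0.75,
                    min_size: int = 5, seed: int = 0,
                    profiles: SmoothedProfiles | None = None) -> ModuleSet:
    """Iterative k-means on consensus rows with the minimum-frequency rule.

    Starting from k = 2, k-means clusters the rows of the (remaining)
    consensus matrix; clusters whose minimum within-cluster co-clustering
    frequency reaches ``freq_min`` are extracted and k is reduced by the
    number removed, otherwise k is incremented; the loop runs until no genes
    remain (genes that can never satisfy the rule end up unassigned when k
    would exceed the remaining gene count).  Extracted clusters smaller than
    ``min_size`` are discarded to the unassigned list.  Gene input order does
    not matter: genes are processed in sorted order internally.
    """
    genes_sorted = sorted(consensus.index)
    C = consensus.loc[genes_sorted, genes_sorted].to_numpy(float)
    remaining = np.arange(len(genes_sorted))
    raw_modules: list[list[int]] = []
    unassigned: list[int] = []
    k = 2
    while len(remaining) > 0:
        if len(remaining) == 1 or k > len(remaining):
            if len(remaining) > 1 and _min_cofreq(C, remaining) >= freq_min:
                raw_modules.append(list(remaining))
            else:
                unassigned.extend(remaining.tolist())
            break
        sub = C[np.ix_(remaining, remaining)]
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(sub)
        extracted = []
        for cl in range(k):
            members = remaining[km.labels_ == cl]
            if len(members) and _min_cofreq(C, members) >= freq_min:
                extracted.append(members)
        if extracted:
            for members in extracted:
                raw_modules.append(members.tolist())
            drop = np.concatenate(extracted)
            remaining = np.array([g for g in remaining if g not in set(drop)])
            k = max(2, k - len(extracted))
        else:
            k += 1

    modules: dict[int, list[str]] = {}
    mid = 0
    for members in raw_modules:
        names = [genes_sorted[i] for i in members]
        if len(names) >= min_size:
            mid += 1
            modules[mid] = sorted(names)
        else:
            unassigned.extend(members)
    return ModuleSet(modules=modules,
                     unassigned=sorted(genes_sorted[i] for i in unassigned),
                     freq_min=freq_min, min_size=min_size, profiles=profiles)
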