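"""Cell clustering and marker-based cell-type annotation.

The clustering resolution is chosen empirically: Leiden clusters are computed
over a grid of resolutions; at each resolution a multinomial logistic
classifier is trained on 2/3 of the cells (expression of all genes) and
evaluated on the held-out 1/3; the largest resolution whose minimum
per-cluster one-vs-rest Matthews correlation coefficient exceeds a threshold
(default 0.75) wins.  Clusters are then labeled by the cell type whose marker
genes show the highest mean standardized expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy import sparse
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

__all__ = ["Embedding", "AnnotationResult", "kneedle", "embed_cells",
           "compute_mcc", "resolution_sweep", "assign_cell_types"]


@dataclass
class Embedding:
    pcs: np.ndarray              # cells × n_pcs (knee-selected)
    n_pcs: int
    variance_ratio: np.ndarray   # all computed components
    variable_genes: list[str]
    loadings: pd.DataFrame       # genes × selected PCs (HVG only)


@dataclass
class AnnotationResult:
    clusters: pd.Series                 # cluster id per cell
    cell_types: pd.Series | None        # label per cell (after assignment)
    resolution: float
    sweep: pd.DataFrame                 # resolution, n_clusters, min_mcc, chosen
    mcc_per_cluster: dict[float, pd.Series]
    warning: str | None = None
    tie_log: list[str] = field(default_factory=list)


def kneedle(y: np.ndarray) -> int:
    """Knee index of a decreasing curve (scree plot).

    Normalizes the curve to the unit square and returns the index maximizing
    the vertical distance below the chord from the first to the last point —
    the standard knee-point construction for convex decreasing curves.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        return len(y)
    x_n = np.linspace(0.0, 1.0, len(y))
    rng = y[0] - y[-1]
    if rng <= 0:
        return 1
    y_n = (y - y[-1]) / rng
    chord = 1.0 - x_n  # line from (0, 1) to (1, 0)
    return int(np.argmax(chord - y_n))


def embed_cells(expr: ad.AnnData, n_top_genes: int = 2000,
                max_pcs: int = 50, sample_key: str = "sample",
                seed: int = 0) -> Embedding:
    """Variable-gene selection, scaling, PCA, and knee-based PC selection.

    Variable genes are ranked per sample (seurat flavor) and chosen by
    cross-sample frequency voting (scanpy's ``batch_key`` mechanism); with a
    single sample the voting degenerates to that sample's top genes.
    """
    a = expr.copy()
    n_top = min(n_top_genes, a.n_vars)
    batch = sample_key if (sample_key in a.obs and
                           a.obs[sample_key].nunique() > 1) else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(a, n_top_genes=n_top, flavor="seurat",
                                    batch_key=batch)
    hvg = a.var_names[a.var["highly_variable"]].tolist()
    sub = a[:, hvg].copy()
    if sparse.issparse(sub.X):
        sub.X = sub.X.toarray()
    sc.pp.scale(sub)  # mean-center, unit variance
    n_comp = int(min(max_pcs, sub.n_obs - 1, sub.n_vars - 1))
    sc.tl.pca(sub, n_comps=n_comp, svd_solver="arpack", random_state=seed)
    var_ratio = sub.uns["pca"]["variance_ratio"]
    knee = kneedle(var_ratio)
    n_pcs = int(max(2, knee))
    loadings = pd.DataFrame(sub.varm["PCs"][:, :n_pcs], index=hvg,
                            columns=[f"PC{i + 1}" for i in range(n_pcs)])
    return Embedding(pcs=sub.obsm["X_pca"][:, :n_pcs], n_pcs=n_pcs,
                     variance_ratio=var_ratio, variable_genes=hvg,
                     loadings=loadings)


def compute_mcc(confusion: np.ndarray) -> np.ndarray:
    """One-vs-rest Matthews correlation coefficient per class.

    ``confusion[i, j]`` counts items of true class ``i`` predicted as ``j``.
    Classes with a zero margin (no true or no predicted items both ways)
    yield 0.
    """
    C = np.asarray(confusion, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("confusion matrix must be square")
    if C.sum() <= 0:
        raise ValueError("confusion matrix totals must be positive")
    total = C.sum()
    mcc = np.zeros(C.shape[0])
    for k in range(C.shape[0]):
        tp = C[k, k]
        fn = C[k].sum() - tp
        fp = C[:, k].sum() - tp
        tn = total - tp - fn - fp
        denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc[k] = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom
    return mcc


def _leiden(pcs: np.ndarray, resolution: float, seed: int,
            n_neighbors: int = 15) -> pd.Series:
    tmp = ad.AnnData(X=np.zeros((pcs.shape[0], 1), dtype=np.float32))
    tmp.obsm["X_pca"] = pcs
    sc.pp.neighbors(tmp, n_neighbors=n_neighbors, use_rep="X_pca",
                    random_state=seed)
    sc.tl.leiden(tmp, resolution=resolution, flavor="igraph",
                 n_iterations=2, directed=False, random_state=seed)
    return tmp.obs["leiden"].astype(int)


def resolution_sweep(embedding: Embedding, expr: ad.AnnData,
                     resolutions: tuple[float, ...] = (0.05, 0.1, 0.25, 0.5, 1.0),
                     mcc_min: float = 0.75, train_frac: float = 2 / 3,
                     seed: int = 0, n_neighbors: int = 15,
                     classifier_max_iter: int = 200) -> AnnotationResult:
    """Pick the largest Leiden resolution whose minimum cluster MCC passes.

    At each resolution the classifier (multinomial logistic regression, a
    deterministic stand-in for a single-layer dense network) is trained on
    ``train_frac`` of the cells using the full ln(CP10K+1) expression matrix
    and scored on the rest; if no resolution passes, the smallest is returned
    with a warning flag.
    """
    if len(resolutions) < 2:
        raise ValueError("need at least two resolutions to sweep")
    resolutions = tuple(sorted(resolutions))
    X = expr.X.toarray() if sparse.issparse(expr.X) else np.asarray(expr.X)
    rows, mcc_by_res, labels_by_res = [], {}, {}
    for res in resolutions:
        clusters = _leiden(embedding.pcs, res, seed, n_neighbors)
        labels_by_res[res] = clusters
        k = clusters.nunique()
        if k == 1:
            # a single cluster is trivially self-consistent
            mcc_by_res[res] = pd.Series([1.0], index=[0])
            rows.append((res, 1, 1.0))
            continue
        idx = np.arange(len(clusters))
        strat = clusters if clusters.value_counts().min() >= 2 else None
        tr, te = train_test_split(idx, train_size=train_frac,
                                  random_state=seed, stratify=strat)
        clf = LogisticRegression(max_iter=classifier_max_iter, tol=1e-3)
        clf.fit(X[tr], clusters.iloc[tr])
        pred = clf.predict(X[te])
        conf = pd.crosstab(pd.Series(clusters.iloc[te].values),
                           pd.Series(pred)).reindex(
            index=range(k), columns=range(k), fill_value=0)
        mcc = compute_mcc(conf.to_numpy())
        mcc_by_res[res] = pd.Series(mcc, index=range(k))
        rows.append((res, k, float(mcc.min())))

    sweep = pd.DataFrame(rows, columns=["resolution", "n_clusters", "min_mcc"])
    passing = sweep.loc[sweep["min_mcc"] > mcc_min, "resolution"]
    warning = None
    if len(passing):
        chosen = float(passing.max())
    else:
        chosen = float(resolutions[0])
        warning = "no resolution passed the minimum-MCC rule"
    sweep["chosen"] = sweep["resolution"] == chosen
    clusters = pd.Series(labels_by_res[chosen].values, index=expr.obs_names,
                         name="cluster")
    return AnnotationResult(clusters=clusters, cell_types=None,
                            resolution=chosen, sweep=sweep,
                            mcc_per_cluster=mcc_by_res, warning=warning)


def assign_cell_types(clusters: pd.Series, expr: ad.AnnData,
                      marker_table: pd.DataFrame) -> tuple[pd.Series, list[str]]:
    """Label each cluster by the cell type with highest mean standardized
    marker expression; ties break by marker count then type name, and every
    tie is recorded."""
    present = marker_table[marker_table["gene_symbol"].isin(expr.var_names)]
    if present.empty:
        raise ValueError("no marker genes present in the expression matrix")
    X = expr[:, present["gene_symbol"].unique()].X
    X = X.toarray() if sparse.issparse(X) else np.asarray(X)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Z = (X - mu) / np.where(sd > 0, sd, 1.0)
    zdf = pd.DataFrame(Z, index=expr.obs_names,
                       columns=present["gene_symbol"].unique())

    tie_log: list[str] = []
    cluster_label: dict = {}
    for cl in sorted(clusters.unique()):
        cells = clusters.index[clusters == cl]
        scores = {}
        for ctype, grp in present.groupby("cell_type"):
            markers = grp["gene_symbol"].tolist()
            scores[ctype] = (float(zdf.loc[cells, markers].mean().mean()),
                             len(markers))
        best = max(scores.values())[0]
        winners = sorted([(v[1], t) for t, v in scores.items()
                          if v[0] == best], key=lambda p: (-p[0], p[1]))
        if len(winners) > 1:
            tie_log.append(f"cluster {cl}: tie among "
                           f"{[t for _, t in winners]} -> {winners[0][1]}")
        cluster_label[cl] = winners[0][1]
    labels = clusters.map(cluster_label).rename("cell_type")
    return labels, tie_log
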