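"""Cell/gene quality-control filters, CP10K normalization and QC reports.

Filter order is fixed: contaminated droplets (> 10 % ambient fraction), then
high-mitochondrial cells (> 50 %), then UMI/complexity outliers, then genes
expressed in too few *surviving* cells, then mitochondrial and ribosomal
genes.  Normalization scales each cell to counts per 10,000 and applies
``ln(CP10K + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy.stats import pearsonr

__all__ = ["QCReport", "apply_qc_filters", "normalize_log_cp10k", "qc_reports"]


@dataclass
class QCReport:
    """Counts of cells/genes removed by each rule, in application order."""

    n_cells_in: int = 0
    n_genes_in: int = 0
    cells_removed: dict[str, int] = field(default_factory=dict)
    genes_removed: dict[str, int] = field(default_factory=dict)
    n_cells_out: int = 0
    n_genes_out: int = 0

    def check_totals(self) -> bool:
        return (self.n_cells_in - sum(self.cells_removed.values()) == self.n_cells_out
                and self.n_genes_in - sum(self.genes_removed.values()) == self.n_genes_out)


def _robust_z(v: np.ndarray) -> np.ndarray:
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    scale = 1.4826 * mad if mad > 0 else (np.std(v) or 1.0)
    return (v - med) / scale


def apply_qc_filters(adata: ad.AnnData,
                     contamination_max: float = 0.10,
                     mito_max: float = 0.50,
                     gene_min_cells: int = 5,
                     outlier_method: str = "robust_z",
                     outlier_z: float = 4.0,
                     seed: int = 0) -> tuple[ad.AnnData, QCReport]:
    """Apply the fixed-order cell and gene filters.

    Cells with contamination fraction strictly greater than
    ``contamination_max`` or mitochondrial fraction strictly greater than
    ``mito_max`` are removed, then UMI/complexity outliers
    (``outlier_method``: ``"robust_z"`` — joint median/MAD rule on
    log counts and log genes detected at ``|z| > outlier_z``;
    ``"isolation_forest"``; or ``"none"``).  Genes expressed (≥ 1 count) in
    at most ``gene_min_cells`` surviving cells are removed, then
    mitochondrial and ribosomal genes.
    """
    if not (0 <= contamination_max <= 1 and 0 <= mito_max <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    report = QCReport(n_cells_in=adata.n_obs, n_genes_in=adata.n_vars)

    keep = np.ones(adata.n_obs, dtype=bool)
    contam = adata.obs["contamination_frac"].to_numpy()
    bad = contam > contamination_max  # strict >: 0.10 itself is retained
    report.cells_removed["contamination"] = int(bad.sum())
    keep &= ~bad

    mito = adata.obs["mito_frac"].to_numpy()
    bad = (mito > mito_max) & keep
    report.cells_removed["mito_fraction"] = int(bad.sum())
    keep &= ~bad

    if outlier_method == "robust_z":
        sub = np.where(keep)[0]
        z1 = _robust_z(np.log1p(adata.obs["n_umi"].to_numpy()[sub]))
        z2 = _robust_z(np.log1p(adata.obs["n_genes_detected"].to_numpy()[sub]))
        out = (np.abs(z1) > outlier_z) | (np.abs(z2) > outlier_z)
        report.cells_removed["umi_outlier"] = int(out.sum())
        keep[sub[out]] = False
    elif outlier_method == "isolation_forest":
        from sklearn.ensemble import IsolationForest
        sub = np.where(keep)[0]
        F = np.column_stack([
            np.log1p(adata.obs["n_umi"].to_numpy()[sub]),
            np.log1p(adata.obs["n_genes_detected"].to_numpy()[sub])])
        pred = IsolationForest(random_state=seed).fit_predict(F)
        out = pred == -1
        report.cells_removed["umi_outlier"] = int(out.sum())
        keep[sub[out]] = False
    elif outlier_method == "none":
        report.cells_removed["umi_outlier"] = 0
    else:
        raise ValueError(f"unknown outlier_method {outlier_method!r}")

    if not keep.any():
        raise ValueError("all cells removed by QC filters")
    out_adata = adata[keep].copy()

    # gene prevalence computed on surviving cells; remove genes in <= k cells
    X = out_adata.X
    n_cells_expr = (X > 0).sum(axis=0)
    n_cells_expr = np.asarray(n_cells_expr).ravel()
    gene_keep = n_cells_expr > gene_min_cells
    report.genes_removed["low_prevalence"] = int((~gene_keep).sum())

    is_mito = out_adata.var.get(
        "is_mito", pd.Series(False, index=out_adata.var_names)).to_numpy(bool)
    is_ribo = out_adata.var.get(
        "is_ribo", pd.Series(False, index=out_adata.var_names)).to_numpy(bool)
    report.genes_removed["mito"] = int((gene_keep & is_mito).sum())
    gene_keep &= ~is_mito
    report.genes_removed["ribo"] = int((gene_keep & is_ribo).sum())
    gene_keep &= ~is_ribo

    out_adata = out_adata[:, gene_keep].copy()
    # refresh per-cell summaries on the filtered gene panel
    out_adata.obs["n_umi"] = np.asarray(out_adata.X.sum(axis=1)).ravel().astype(int)
    nnz = (out_adata.X > 0).sum(axis=1)
    out_adata.obs["n_genes_detected"] = np.asarray(nnz).ravel().astype(int)
    report.n_cells_out, report.n_genes_out = out_adata.shape
    return out_adata, report


def normalize_log_cp10k(adata: ad.AnnData) -> ad.AnnData:
    """Return an AnnData with ``ln(CP10K + 1)`` in ``.X`` and counts in a layer."""
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise ValueError("cells with zero total counts cannot be normalized")
    expr = adata.copy()
    expr.layers["counts"] = expr.X.copy()
    sc.pp.normalize_total(expr, target_sum=1e4)
    sc.pp.log1p(expr)
    return expr


def _pseudobulk_cp(counts: np.ndarray) -> np.ndarray:
    total = counts.sum()
    return counts / total * 1e4 if total > 0 else counts.astype(float)


def qc_reports(adata: ad.AnnData,
               cell_types: pd.Series | None = None,
               sample_key: str = "sample") -> dict:
    """Sex-check ratios and (optionally) replicate pseudobulk correlations.

    The sex check compares pseudobulk XIST CP10K to the mean CP10K of Y
    chromosome genes per sample.  With cell-type annotations, pseudobulk
    (summed counts, total-normalized) Pearson correlations are computed
    between replicate pairs within donor × cell type × time × glucose arm.
    """
    out: dict = {}
    var = adata.var
    has_xist = "XIST" in adata.var_names
    chry = (var.get("chromosome", pd.Series("", index=var.index)) == "Y")
    if has_xist and chry.any():
        rows = []
        for sample, idx in adata.obs.groupby(sample_key, observed=True).groups.items():
            sub = adata[idx]
            pb = _pseudobulk_cp(np.asarray(sub.X.sum(axis=0)).ravel())
            xist = pb[sub.var_names.get_loc("XIST")]
            ymean = pb[chry.to_numpy()].mean()
            rows.append((sample, xist, ymean,
                         xist / ymean if ymean > 0 else np.inf))
        out["sex_check"] = pd.DataFrame(
            rows, columns=["sample", "xist_cp10k", "chry_mean_cp10k",
                           "xist_to_chry_ratio"])
    else:
        out["sex_check"] = None  # marked unavailable, not an error

    if cell_types is not None:
        obs = adata.obs.copy()
        obs["cell_type"] = pd.Series(cell_types, index=adata.obs_names)
        X = adata.X
        rows = []
        keys = ["donor", "cell_type", "time_h", "glucose_arm"]
        for key, grp in obs.groupby(keys, observed=True):
            reps = sorted(grp["replicate"].unique())
            if len(reps) < 2:
                continue
            pbs = {}
            for rep in reps:
                idx = obs.index.get_indexer(grp.index[grp["replicate"] == rep])
                pbs[rep] = _pseudobulk_cp(np.asarray(X[idx].sum(axis=0)).ravel())
            for i in range(len(reps)):
                for j in range(i + 1, len(reps)):
                    r, _ = pearsonr(pbs[reps[i]], pbs[reps[j]])
                    rows.append((*key, reps[i], reps[j], r))
        out["replicate_correlation"] = pd.DataFrame(
            rows, columns=[*keys, "rep_a", "rep_b", "pearson_r"])
    return out
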