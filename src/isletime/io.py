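"""Disk formats: 10x-dialect MTX trio, cell-metadata TSV, GMT gene sets.

The on-disk layout mirrors a CellRanger ``filtered_feature_bc_matrix``
directory: a genes × cells MatrixMarket coordinate file plus ``features.tsv``
and ``barcodes.tsv``, extended with ``cell_metadata.tsv`` (donor, replicate,
time, glucose arm, contamination and mitochondrial fractions).  A paired
reader round-trips losslessly.
"""

from __future__ import annotations

import os
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from gseapy.parser import read_gmt as _read_gmt
from scipy import io as spio
from scipy import sparse

__all__ = ["write_tenx", "read_tenx", "read_gmt", "write_gmt",
           "read_gene_scores", "write_gene_scores"]

_META_COLS = ["donor", "replicate", "time_h", "glucose_arm",
              "contamination_frac", "mito_frac"]


def write_tenx(adata: ad.AnnData, directory: str | os.PathLike) -> Path:
    """Write a count AnnData as a 10x-dialect MTX trio plus metadata TSV."""
    X = adata.X
    if sparse.issparse(X):
        data = X.data
    else:
        data = np.asarray(X).ravel()
    if not np.allclose(data, np.round(data)):
        raise ValueError("write_tenx requires integer counts")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    mat = sparse.coo_matrix(X.T)  # 10x stores genes (features) × cells
    spio.mmwrite(directory / "matrix.mtx", mat, field="integer")

    feats = pd.DataFrame({
        "gene_id": adata.var.get("gene_id", adata.var_names),
        "symbol": adata.var_names,
        "feature_type": "Gene Expression",
    })
    feats.to_csv(directory / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False)

    meta = adata.obs.copy()
    meta.index.name = "cell_id"
    meta.to_csv(directory / "cell_metadata.tsv", sep="\t")
    gm = adata.var[[c for c in ("gene_id", "chromosome", "is_mito", "is_ribo")
                    if c in adata.var]].copy()
    gm.index.name = "gene"
    gm.to_csv(directory / "gene_metadata.tsv", sep="\t")
    return directory


def read_tenx(directory: str | os.PathLike) -> ad.AnnData:
    """Read a directory written by :func:`write_tenx` back into AnnData."""
    directory = Path(directory)
    mat = spio.mmread(directory / "matrix.mtx").T.tocsr().astype(np.int32)
    feats = pd.read_csv(directory / "features.tsv", sep="\t", header=None,
                        names=["gene_id", "symbol", "feature_type"])
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0]
    obs = pd.read_csv(directory / "cell_metadata.tsv", sep="\t", index_col=0)
    obs.index = obs.index.astype(str)
    if not (obs.index == barcodes.astype(str).values).all():
        raise ValueError("cell_metadata.tsv is not aligned with barcodes.tsv")
    var = pd.DataFrame({"gene_id": feats["gene_id"].values,
                        "symbol": feats["symbol"].values},
                       index=pd.Index(feats["symbol"].astype(str), name="gene"))
    gm_path = directory / "gene_metadata.tsv"
    if gm_path.exists():
        gm = pd.read_csv(gm_path, sep="\t", index_col=0)
        for col in gm.columns:
            if col != "gene_id":
                var[col] = gm[col].values
    adata = ad.AnnData(X=mat, obs=obs, var=var)
    adata.obs_names = obs.index
    return adata


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a GMT gene-set collection into ``{set name: [gene, ...]}``."""
    return {k: list(v) for k, v in _read_gmt(str(path)).items()}


def write_gmt(sets: dict[str, list[str]], path: str | os.PathLike,
              description: str = "na") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *map(str, members)]) + "\n")
    return path


def read_gene_scores(path: str | os.PathLike) -> pd.DataFrame:
    """Gene-level association scores: TSV with gene_id, score[, phenotype]."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns or "score" not in df.columns:
        raise ValueError("gene score TSV needs 'gene_id' and 'score' columns")
    if "phenotype" not in df.columns:
        df["phenotype"] = "trait"
    return df


def write_gene_scores(df: pd.DataFrame, path: str | os.PathLike) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path
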