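"""Over-representation of gene sets (effector genes, GO-style sets) in modules.

Upper-tail hypergeometric test: with a universe of N genes of which K belong
to the set, a module of m genes overlapping the set in k genes has
p = P(X ≥ k).  The universe is the set of genes tested for differential
expression in the cell type (post-prefilter).  The effector family adjusts
Benjamini-Hochberg within each cell type; the GO-style variant adjusts within
each module and drops tests whose overlap is ≤ 1 gene.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom

from .hurdle import bh_adjust

__all__ = ["overrepresentation_test", "enrich_modules"]


def overrepresentation_test(module_genes, gene_set, universe) -> tuple[int, float]:
    """Overlap count and upper-tail hypergeometric p-value.

    The module must lie inside the universe; the set is intersected with the
    universe before testing.
    """
    module = set(module_genes)
    if not module:
        raise ValueError("empty module")
    universe = set(universe)
    if not module <= universe:
        raise ValueError("module genes must be a subset of the universe")
    gset = set(gene_set) & universe
    if not gset:
        raise ValueError("gene set does not intersect the universe")
    N, K, m = len(universe), len(gset), len(module)
    k = len(module & gset)
    p = float(hypergeom.sf(k - 1, N, K, m))  # P(X >= k)
    return k, min(p, 1.0)


def enrich_modules(module_set, collections: dict[str, list[str]],
                   universe, cell_type: str = "all",
                   fdr_scope: str = "cell_type",
                   go_mode: bool = False) -> pd.DataFrame:
    """Test every (module, gene set) pair and BH-adjust within the family.

    ``fdr_scope='cell_type'`` adjusts across all tests of the cell type (the
    effector convention); ``'module'`` adjusts within each module (the
    GO-style convention).  ``go_mode`` drops tests with ≤ 1 overlapping gene
    before adjustment.
    """
    if not collections:
        raise ValueError("empty gene-set collection")
    universe = set(universe)
    rows = []
    for mid, genes in module_set.modules.items():
        module = set(genes) & universe
        if not module:
            continue
        for set_name, members in collections.items():
            gset = set(members) & universe
            if not gset:
                continue
            k, p = overrepresentation_test(module, gset, universe)
            if go_mode and k <= 1:
                continue
            rows.append({
                "cell_type": cell_type, "module": mid, "set": set_name,
                "k": k, "K": len(gset), "m": len(module), "N": len(universe),
                "p": p, "overlap_genes": ",".join(sorted(module & gset)),
            })
    table = pd.DataFrame(rows)
    if table.empty:
        table["q"] = []
        return table
    if fdr_scope == "cell_type":
        table["q"] = bh_adjust(table["p"].to_numpy())
    elif fdr_scope == "module":
        table["q"] = 1.0
        for mid, idx in table.groupby("module").groups.items():
            table.loc[idx, "q"] = bh_adjust(table.loc[idx, "p"].to_numpy())
    else:
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")
    return table
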