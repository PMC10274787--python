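"""Two-part hurdle differential expression with summed-χ² likelihood-ratio tests.

For gene *i* and cell *k*, let ``Z_ki = 1`` when the gene is detected and
``Y_ki`` its ln(CP10K+1) expression.  The model is

    logit Pr(Z_ki = 1 | X_k) = X_k · beta_i            (detection part)
    Y_ki | Z_ki = 1          ~ N(X_k · beta'_i, s2_i)   (level part)

A tested term is dropped from both parts; the likelihood-ratio statistic is
the sum of the two parts' 2·Δlog-likelihoods, referred to a χ² distribution
whose degrees of freedom count the dropped parameters of the non-degenerate
parts.  Designs: three discrete contrasts (basal-vs-high BvH, basal-vs-low
BvL, low-vs-high LvH, each at one time point) and three continuous models
(time, glucose, time:glucose interaction) sharing cell complexity and donor
covariates.  Genes with median CP10K < 1 in the tested cells are removed
before fitting; q-values are Benjamini-Hochberg within each
(cell type, design) family.

All per-gene fits are vectorized across genes (shared design matrix,
per-gene Newton / weighted-least-squares updates).
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.special import expit
from statsmodels.stats.multitest import multipletests

__all__ = ["HurdleDesign", "HurdleFit", "DISCRETE_DESIGNS", "CONTINUOUS_DESIGNS",
           "bh_adjust", "prefilter_genes", "fit_hurdle", "lrt_hurdle",
           "run_design"]

DISCRETE_DESIGNS = ("BvH", "BvL", "LvH")
CONTINUOUS_DESIGNS = ("time", "glucose", "time_glucose")

_BETA_CAP = 30.0  # logistic coefficients beyond this are saturated


@dataclass(frozen=True)
class HurdleDesign:
    """A named design; discrete designs carry the compared time point."""

    name: str
    time_point: float | None = None

    def __post_init__(self):
        if self.name not in DISCRETE_DESIGNS + CONTINUOUS_DESIGNS:
            raise ValueError(f"unknown design {self.name!r}")
        if self.name in DISCRETE_DESIGNS and self.time_point is None:
            raise ValueError(f"discrete design {self.name} needs a time point")

    @property
    def is_discrete(self) -> bool:
        return self.name in DISCRETE_DESIGNS


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# batched fits
# ---------------------------------------------------------------------------

def _batch_logistic(Z: np.ndarray, X: np.ndarray, ridge: float = 1e-6,
                    max_iter: int = 40, tol: float = 1e-10):
    """Ridge-stabilized Newton logistic fits for all genes at once.

    Z: cells × genes binary; X: cells × p shared design.  Returns
    (coefs G×p, loglik G (unpenalized), degenerate mask G, capped mask G).
    The tiny ridge keeps near-separated genes finite; coefficients are capped
    at ±30 (fully saturated probabilities) and flagged.
    """
    n, G = Z.shape
    p = X.shape[1]
    pos = Z.sum(axis=0)
    degen = (pos == 0) | (pos == n)
    beta = np.zeros((G, p))
    pbar = np.clip(pos / n, 1e-3, 1 - 1e-3)
    beta[:, 0] = np.log(pbar / (1 - pbar))  # intercept warm start
    XX = (X[:, :, None] * X[:, None, :]).reshape(n, p * p)
    eye = ridge * np.eye(p)
    active = ~degen
    for _ in range(max_iter):
        if not active.any():
            break
        eta = np.clip(X @ beta[active].T, -35, 35)
        mu = expit(eta)
        W = np.clip(mu * (1 - mu), 1e-10, None)
        grad = (Z[:, active] - mu).T @ X - ridge * beta[active]
        H = (W.T @ XX).reshape(-1, p, p) + eye
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        newb = np.clip(beta[active] + step, -_BETA_CAP, _BETA_CAP)
        moved = np.abs(newb - beta[active]).max(axis=1)
        beta[active] = newb
        sub = moved > tol
        idx = np.where(active)[0]
        active = np.zeros(G, dtype=bool)
        active[idx[sub]] = True
    eta = np.clip(X @ beta.T, -35, 35)
    mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    ll = (Z * np.log(mu) + (1 - Z) * np.log(1 - mu)).sum(axis=0)
    ll[degen] = 0.0
    capped = (np.abs(beta) >= _BETA_CAP - 1e-9).any(axis=1) & ~degen
    return beta, ll, degen, capped


def _batch_wls(Y: np.ndarray, Z: np.ndarray, X: np.ndarray,
               ridge: float = 1e-8):
    """Per-gene Gaussian fits on detected cells (0/1 weights), batched.

    Returns (coefs G×p, sigma2 G, loglik G, degenerate mask G).  A gene is
    degenerate when fewer than p+2 cells express it.
    """
    n, G = Y.shape
    p = X.shape[1]
    n_pos = Z.sum(axis=0)
    degen = n_pos < p + 2
    XX = (X[:, :, None] * X[:, None, :]).reshape(n, p * p)
    H = (Z.T @ XX).reshape(G, p, p) + ridge * np.eye(p)
    B = (Z * Y).T @ X
    beta = np.linalg.solve(H, B[..., None])[..., 0]
    resid = Y - X @ beta.T
    rss = (Z * resid ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = np.where(n_pos > 0, rss / np.maximum(n_pos, 1), np.nan)
        ll = -0.5 * n_pos * (np.log(2 * np.pi * sigma2) + 1.0)
    ll = np.where(degen | (sigma2 <= 0) | ~np.isfinite(ll), 0.0, ll)
    degen = degen | (rss <= 1e-12)
    beta[degen] = np.nan
    return beta, sigma2, ll, degen


@dataclass
class HurdleFit:
    """One gene's two-part fit (or a batch, with arrays per field)."""

    coefs_disc: np.ndarray
    coefs_cont: np.ndarray
    sigma2: np.ndarray
    ll_disc: np.ndarray
    ll_cont: np.ndarray
    disc_degenerate: np.ndarray
    cont_degenerate: np.ndarray
    disc_capped: np.ndarray
    n_params: int


def fit_hurdle(y: np.ndarray, X: np.ndarray, ridge: float = 1e-6) -> HurdleFit:
    """Fit the two-part model for one gene (y ≥ 0, ln(CP10K+1) scale).

    The detection part is a ridge-stabilized logistic regression of
    ``1[y > 0]`` on X; the level part an ordinary least-squares fit of y on X
    over cells with ``y > 0``.  An all-zero or all-detected gene leaves the
    detection part degenerate (it then contributes 0 df to any test).
    """
    y = np.asarray(y, dtype=float)
    if (y < 0).any():
        raise ValueError("y must be nonnegative")
    X = np.asarray(X, dtype=float)
    Y = y[:, None]
    Z = (Y > 0).astype(float)
    bd, lld, dd, cap = _batch_logistic(Z, X, ridge=ridge)
    bc, s2, llc, dc = _batch_wls(Y, Z, X)
    return HurdleFit(coefs_disc=bd[0], coefs_cont=bc[0], sigma2=s2[:1],
                     ll_disc=lld[:1], ll_cont=llc[:1], disc_degenerate=dd[:1],
                     cont_degenerate=dc[:1], disc_capped=cap[:1],
                     n_params=X.shape[1])


def lrt_hurdle(full: HurdleFit, reduced: HurdleFit):
    """Summed-χ² likelihood-ratio test of nested hurdle fits.

    χ² adds the detection and level parts' 2·Δlog-likelihoods; df counts the
    dropped parameters of each part that is non-degenerate in both fits.
    Degenerate-part genes keep whatever df their live part provides; df = 0
    yields p = 1.
    """
    dropped = full.n_params - reduced.n_params
    if dropped <= 0:
        raise ValueError("reduced model must be nested in the full model")
    disc_live = ~(full.disc_degenerate | reduced.disc_degenerate)
    cont_live = ~(full.cont_degenerate | reduced.cont_degenerate)
    chi2 = (np.clip(2 * (full.ll_disc - reduced.ll_disc), 0, None) * disc_live
            + np.clip(2 * (full.ll_cont - reduced.ll_cont), 0, None) * cont_live)
    df = dropped * (disc_live.astype(int) + cont_live.astype(int))
    p = np.ones_like(chi2)
    live = df > 0
    p[live] = stats.chi2.sf(chi2[live], df[live])
    return chi2, df, p


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------

def prefilter_genes(counts: np.ndarray | sparse.spmatrix,
                    totals: np.ndarray | None = None) -> np.ndarray:
    """Mask of genes with median CP10K ≥ 1 in the given cells.

    ``totals`` are per-cell total counts (defaults to the row sums of the
    matrix handed in, i.e. the post-QC gene panel).
    """
    if sparse.issparse(counts):
        counts = counts.toarray()
    counts = np.asarray(counts, dtype=float)
    if totals is None:
        totals = counts.sum(axis=1)
    totals = np.maximum(np.asarray(totals, dtype=float), 1.0)
    cp10k = counts / totals[:, None] * 1e4
    keep = np.median(cp10k, axis=0) >= 1.0
    if not keep.any():
        raise ValueError("median-CP10K prefilter removed every gene")
    return keep


def _select_cells(obs: pd.DataFrame, design: HurdleDesign) -> tuple[np.ndarray, np.ndarray]:
    """Boolean cell mask and the tested-term column for a design."""
    t = obs["time_h"].to_numpy(float)
    high = (obs["glucose_arm"] == "high").to_numpy()
    if design.name == "BvH":
        mask = ((t == 0) & ~high) | ((t == design.time_point) & high)
        term = high[mask].astype(float)
    elif design.name == "BvL":
        mask = (~high) & ((t == 0) | (t == design.time_point))
        term = (t[mask] == design.time_point).astype(float)
    elif design.name == "LvH":
        mask = t == design.time_point
        term = high[mask].astype(float)
    else:  # continuous designs use all post-0h cells; term built later
        mask = t > 0
        term = np.zeros(int(mask.sum()))
    return mask, term


def _design_matrices(obs: pd.DataFrame, design: HurdleDesign,
                     tested: np.ndarray, time_value: np.ndarray | None):
    """Full/reduced design matrices with shared covariates.

    Columns: intercept, centered/scaled cell complexity, donor indicators
    (constant columns dropped with a warning), design-specific terms, and
    the tested term last in the full model.
    """
    warnings_: list[str] = []
    cols = [np.ones(len(obs))]
    names = ["intercept"]
    comp = obs["n_genes_detected"].to_numpy(float)
    sd = comp.std()
    cols.append((comp - comp.mean()) / (sd if sd > 0 else 1.0))
    names.append("complexity")
    donors = sorted(obs["donor"].unique())
    if len(donors) > 1:
        for d in donors[1:]:
            cols.append((obs["donor"] == d).to_numpy(float))
            names.append(f"donor[{d}]")
    else:
        warnings_.append("single donor: donor covariate dropped")

    if design.is_discrete:
        shared = []
    else:
        high = (obs["glucose_arm"] == "high").to_numpy(float)
        tval = np.asarray(time_value, dtype=float)
        if design.name == "time":
            shared, tested = [("glucose", high)], tval
        elif design.name == "glucose":
            shared, tested = [("time", tval)], high
        else:  # time_glucose: both mains shared, interaction tested
            shared, tested = [("time", tval), ("glucose", high)], tval * high
    for nm, col in shared:
        cols.append(col)
        names.append(nm)
    X_reduced = np.column_stack(cols)
    X_full = np.column_stack(cols + [tested])
    names_full = names + [f"{design.name}_term"]
    return X_full, X_reduced, names_full, warnings_


def run_design(expr: ad.AnnData, design: HurdleDesign, cell_type: str,
               cell_types: pd.Series, t_hat_std: pd.Series | None = None,
               ridge: float = 1e-6, fdr_prefilter: bool = True) -> pd.DataFrame:
    """Run one (cell type, design) differential-expression family.

    ``expr`` holds ln(CP10K+1) in ``.X`` and raw counts in
    ``layers["counts"]``.  Continuous designs use standardized interpolated
    time when ``t_hat_std`` is given, otherwise sampled time min-max scaled
    within the cell type.  Returns one row per prefiltered gene with the
    hurdle coefficients of the tested term, the summed-χ² LRT, BH q-values
    within this family, and the tested-term sign.
    """
    in_type = (pd.Series(cell_types, index=expr.obs_names) == cell_type)
    sub = expr[in_type.to_numpy()]
    mask, tested = _select_cells(sub.obs, design)
    if design.is_discrete and (tested.sum() == 0 or tested.sum() == mask.sum()):
        raise ValueError(f"{design.name} at t={design.time_point}: "
                         "one comparison group is empty")
    if not mask.any():
        raise ValueError("no cells selected for design")
    cells = sub[mask]

    time_value = None
    if not design.is_discrete:
        if t_hat_std is not None:
            time_value = t_hat_std.reindex(cells.obs_names).to_numpy(float)
            if np.isnan(time_value).any():
                raise ValueError("t_hat_std missing for selected cells")
        else:
            t = cells.obs["time_h"].to_numpy(float)
            time_value = (t - t.min()) / (t.max() - t.min())

    X_full, X_red, names, warn = _design_matrices(
        cells.obs, design, tested, time_value)

    counts = cells.layers["counts"]
    keep = (prefilter_genes(counts) if fdr_prefilter
            else np.ones(cells.n_vars, dtype=bool))
    genes = cells.var_names[keep]
    Y = cells.X[:, keep]
    Y = Y.toarray() if sparse.issparse(Y) else np.asarray(Y, dtype=float)
    Z = (Y > 0).astype(float)

    bd_f, lld_f, dd_f, cap_f = _batch_logistic(Z, X_full, ridge=ridge)
    bc_f, s2_f, llc_f, dc_f = _batch_wls(Y, Z, X_full)
    bd_r, lld_r, dd_r, _ = _batch_logistic(Z, X_red, ridge=ridge)
    bc_r, _, llc_r, dc_r = _batch_wls(Y, Z, X_red)
    full = HurdleFit(bd_f, bc_f, s2_f, lld_f, llc_f, dd_f, dc_f, cap_f,
                     X_full.shape[1])
    red = HurdleFit(bd_r, bc_r, None, lld_r, llc_r, dd_r, dc_r, None,
                    X_red.shape[1])
    chi2, df, p = lrt_hurdle(full, red)

    coef_cont = bc_f[:, -1]
    coef_disc = bd_f[:, -1]
    sign = np.sign(np.where(np.isfinite(coef_cont), coef_cont, coef_disc))
    res = pd.DataFrame({
        "gene": genes,
        "cell_type": cell_type,
        "design": design.name,
        "time_point": design.time_point,
        "coef_disc": coef_disc,
        "coef_cont": coef_cont,
        "sigma2": s2_f,
        "chisq": chi2,
        "df": df,
        "p": p,
        "q": bh_adjust(p),
        "sign": sign,
        "disc_degenerate": dd_f,
        "cont_degenerate": dc_f,
        "disc_capped": cap_f,
    })
    res.attrs["design_columns"] = names
    res.attrs["warnings"] = warn
    res.attrs["n_cells"] = int(mask.sum())
    return res
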