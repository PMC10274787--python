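"""Seeded generator of islet-like glucose time-course scRNA-seq counts.

The generator emulates a two-donor, two-replicate stimulation experiment in
which islets are held at low (2.8 mM) or high (15 mM) glucose and sampled for
single-cell RNA-seq at 0, 1, 2, 4, 8, 12 and 24 hours (no high-glucose arm at
0 h).  Cells belong to a small set of islet cell types, each carrying a
canonical marker gene (GCG/INS/SST/PPY/PRSS1/KRT19) plus a block of signature
genes.  Gene expression follows a two-part process: a Bernoulli detection
component and, when detected, a count component (negative binomial by default,
or a rounded log-normal mode whose log-scale values are approximately
Gaussian).  The log-mean carries planted time slopes, glucose shifts,
time:glucose interactions and planted co-expression module profiles, all
evaluated at the cell's *phase-offset* time — a truncated-normal jitter around
the sampled time that models response-phase asynchrony between cells captured
at the same time point.

Every simulated cell and gene has a ground-truth record so that downstream
stages (QC, annotation, interpolated time, hurdle differential expression,
module discovery, enrichment, prioritization) can be validated end to end
without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import expit, logit
from scipy.stats import truncnorm

__all__ = [
    "CellTypeSpec",
    "EffectSpec",
    "ModuleSpec",
    "HurdleSpec",
    "DepthSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_dataset",
    "default_marker_table",
    "MODULE_SHAPES",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellTypeSpec:
    """One islet cell type: sampling proportion, canonical markers, signature."""

    name: str
    proportion: float
    markers: tuple[str, ...]
    n_signature_genes: int = 25
    signature_log_fc: float = 1.8


@dataclass(frozen=True)
class EffectSpec:
    """Planted per-gene fixed effects on the log-expression scale.

    ``time_log_fc`` is the log-scale change accrued over the full 24 h
    (the time covariate is scaled to [0, 1]); ``glucose_log_fc`` the shift of
    the high arm; ``interaction_log_fc`` the additional high-arm slope.
    Signs are randomized per gene.  ``detection_coupling`` propagates a
    fraction of each log-mean shift onto the detection logit, so effects act
    on both hurdle parts.
    """

    n_time_genes: int = 300
    time_log_fc: float = 1.2
    n_glucose_genes: int = 100
    glucose_log_fc: float = 1.0
    n_interaction_genes: int = 60
    interaction_log_fc: float = 1.25
    detection_coupling: float = 0.5


# temporal profile shapes for planted modules; x = phase time / 24 h in [0,1]
MODULE_SHAPES: dict[str, tuple] = {
    "flat": (lambda x: 0.0 * x, lambda x: 0.0 * x),
    "ramp_both": (lambda x: x, lambda x: x),
    "ramp_down_both": (lambda x: -x, lambda x: -x),
    "ramp_high_only": (lambda x: 0.0 * x, lambda x: x),
    "late_divergence": (lambda x: 0.0 * x, lambda x: np.clip(2.0 * (x - 0.5), 0.0, None)),
    "pulse_both": (lambda x: 4.0 * x * (1.0 - x), lambda x: 4.0 * x * (1.0 - x)),
}

# effect flags implied by each shape (time, glucose, interaction)
_SHAPE_FLAGS = {
    "flat": (False, False, False),
    "ramp_both": (True, False, False),
    "ramp_down_both": (True, False, False),
    "ramp_high_only": (False, True, True),
    "late_divergence": (False, True, True),
    "pulse_both": (True, False, False),
}


@dataclass(frozen=True)
class ModuleSpec:
    """Planted co-expression modules: sizes and per-arm temporal shapes."""

    sizes: tuple[int, ...] = (20, 20, 20)
    shapes: tuple[str, ...] = ("ramp_both", "ramp_high_only", "late_divergence")
    amplitude: float = 1.5
    amplitude_jitter: float = 0.2  # per-gene uniform spread around amplitude

    def __post_init__(self):
        if len(self.sizes) != len(self.shapes):
            raise ValueError("module sizes and shapes must have equal length")
        unknown = set(self.shapes) - set(MODULE_SHAPES)
        if unknown:
            raise ValueError(f"unknown module shapes: {sorted(unknown)}")


@dataclass(frozen=True)
class HurdleSpec:
    """Detection component: per-gene baseline probability and covariates.

    Baseline detection logits are Normal(logit(mean_detection), logit_sd);
    the logit additionally shifts with library depth (``depth_coupling`` per
    unit of centered log library size) and, via ``EffectSpec
    .detection_coupling``, with the planted log-mean effects.
    """

    mean_detection: float = 0.35
    logit_sd: float = 1.0
    depth_coupling: float = 1.0


@dataclass(frozen=True)
class DepthSpec:
    """Library-size distribution (log-normal) and NB dispersion."""

    log_mean: float = math.log(5000.0)
    log_sd: float = 0.35
    nb_dispersion: float = 8.0  # gamma shape; larger = closer to Poisson
    lognormal_sd: float = 0.35  # residual SD of the log-normal count mode


def _default_cell_types() -> tuple[CellTypeSpec, ...]:
    return (
        CellTypeSpec("alpha", 0.32, ("GCG",)),
        CellTypeSpec("beta", 0.30, ("INS",)),
        CellTypeSpec("delta", 0.08, ("SST",)),
        CellTypeSpec("gamma", 0.06, ("PPY",)),
        CellTypeSpec("acinar", 0.14, ("PRSS1",)),
        CellTypeSpec("ductal", 0.10, ("KRT19",)),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Full study design for one simulated dataset."""

    n_donors: int = 2
    n_replicates_per_donor: int = 2
    time_points_h: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0)
    cell_types: tuple[CellTypeSpec, ...] = field(default_factory=_default_cell_types)
    n_genes: int = 2000
    n_cells_per_well: int = 96
    effect_spec: EffectSpec = field(default_factory=EffectSpec)
    module_spec: ModuleSpec = field(default_factory=ModuleSpec)
    hurdle_spec: HurdleSpec = field(default_factory=HurdleSpec)
    depth_spec: DepthSpec = field(default_factory=DepthSpec)
    count_mode: str = "nb"  # "nb" | "lognormal"
    # response-phase asynchrony: SD of the truncated-normal phase offset as a
    # fraction of the sampled time, support [0.1 t, min(2.5 t, 24)] — cells
    # can lag or lead their sampled time substantially (free parameter; not
    # an estimate from real data)
    phase_sd_frac: float = 0.7
    marker_log_fc: float = 3.0
    base_log_sd: float = 1.2
    donor_log_sd: float = 0.15
    # metadata-only nuisance values
    mito_fraction_beta: tuple[float, float] = (2.0, 18.0)
    dying_cell_frac: float = 0.02
    dying_mito_beta: tuple[float, float] = (12.0, 6.0)
    contamination_beta: tuple[float, float] = (1.5, 28.0)
    doublet_rate: float = 0.02
    donor_sexes: tuple[str, ...] = ("male", "male")
    # effector labels: fraction of first module / of remaining eligible genes
    effector_module_frac: float = 0.6
    effector_background_frac: float = 0.05
    n_mito_genes: int = 10
    n_ribo_genes: int = 20
    n_chry_genes: int = 5

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_cells_per_well <= 0:
            raise ValueError("n_genes and n_cells_per_well must be positive")
        if self.n_donors <= 0 or self.n_replicates_per_donor <= 0:
            raise ValueError("need at least one donor and replicate")
        props = [ct.proportion for ct in self.cell_types]
        if not self.cell_types:
            raise ValueError("at least one cell type required")
        if abs(sum(props) - 1.0) > 1e-6:
            raise ValueError(f"cell type proportions sum to {sum(props)}, not 1")
        if len(self.donor_sexes) != self.n_donors:
            raise ValueError("donor_sexes must have one entry per donor")
        if not all(t >= 0 for t in self.time_points_h):
            raise ValueError("time points must be nonnegative")
        es = self.effect_spec
        for v in (es.time_log_fc, es.glucose_log_fc, es.interaction_log_fc,
                  self.module_spec.amplitude):
            if not np.isfinite(v):
                raise ValueError("effect magnitudes must be finite")
        if self.count_mode not in ("nb", "lognormal"):
            raise ValueError(f"unknown count_mode {self.count_mode!r}")
        n_special = (len(self.cell_types)
                     + sum(ct.n_signature_genes for ct in self.cell_types)
                     + sum(self.module_spec.sizes)
                     + es.n_time_genes + es.n_glucose_genes + es.n_interaction_genes
                     + self.n_mito_genes + self.n_ribo_genes + self.n_chry_genes + 1)
        if self.n_genes < n_special:
            raise ValueError(
                f"n_genes={self.n_genes} too small for the configured "
                f"markers/signatures/modules/effects ({n_special} required)")


@dataclass
class GroundTruth:
    """Per-gene and per-cell truth records for one simulated dataset."""

    genes: pd.DataFrame  # indexed by gene symbol
    cells: pd.DataFrame  # indexed by cell barcode

    def module_labels(self) -> pd.Series:
        """Planted module id per gene (NaN for unassigned genes)."""
        return self.genes["module_id"]


def default_marker_table(config: SimulationConfig | None = None) -> pd.DataFrame:
    """Marker table (cell_type, gene_symbol) for annotation, from the config."""
    config = config or SimulationConfig()
    rows = [(ct.name, m) for ct in config.cell_types for m in ct.markers]
    return pd.DataFrame(rows, columns=["cell_type", "gene_symbol"])


# ---------------------------------------------------------------------------
# gene panel layout
# ---------------------------------------------------------------------------

def _build_gene_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    es, ms = config.effect_spec, config.module_spec
    names: list[str] = []
    rows: list[dict] = []

    def add(name, **kw):
        names.append(name)
        base = dict(signature_type="", time_effect=False, glucose_effect=False,
                    interaction_effect=False, time_slope=0.0, glucose_shift=0.0,
                    interaction_coef=0.0, module_id=np.nan, module_shape="",
                    module_amplitude=0.0, is_mito=False, is_ribo=False,
                    chromosome="", is_effector=False)
        base.update(kw)
        rows.append(base)

    for ct in config.cell_types:
        for m in ct.markers:
            add(m, signature_type=ct.name)
    for ct in config.cell_types:
        for j in range(ct.n_signature_genes):
            add(f"SIG-{ct.name.upper()}-{j + 1}", signature_type=ct.name)

    for mod_idx, (size, shape) in enumerate(zip(ms.sizes, ms.shapes)):
        tf, gf, intf = _SHAPE_FLAGS[shape]
        for j in range(size):
            amp = ms.amplitude * rng.uniform(1.0 - ms.amplitude_jitter,
                                             1.0 + ms.amplitude_jitter)
            add(f"MOD{mod_idx + 1}-{j + 1}", module_id=float(mod_idx + 1),
                module_shape=shape, module_amplitude=amp,
                time_effect=tf, glucose_effect=gf, interaction_effect=intf)

    for j in range(es.n_time_genes):
        s = es.time_log_fc * rng.choice([-1.0, 1.0])
        add(f"TME-{j + 1}", time_effect=True, time_slope=s)
    for j in range(es.n_glucose_genes):
        s = es.glucose_log_fc * rng.choice([-1.0, 1.0])
        add(f"GLC-{j + 1}", glucose_effect=True, glucose_shift=s)
    for j in range(es.n_interaction_genes):
        s = es.interaction_log_fc * rng.choice([-1.0, 1.0])
        add(f"IXN-{j + 1}", interaction_effect=True, interaction_coef=s)

    for j in range(config.n_mito_genes):
        add(f"MT-ND{j + 1}", is_mito=True, chromosome="MT")
    for j in range(config.n_ribo_genes):
        prefix = "RPS" if j % 2 == 0 else "RPL"
        add(f"{prefix}{j // 2 + 1}", is_ribo=True)
    chry = ["DDX3Y", "UTY", "USP9Y", "KDM5D", "EIF1AY", "NLGN4Y", "ZFY", "TMSB4Y"]
    for j in range(config.n_chry_genes):
        add(chry[j % len(chry)] if j < len(chry) else f"CHRY-{j + 1}", chromosome="Y")
    add("XIST", chromosome="X")

    n_fill = config.n_genes - len(names)
    for j in range(n_fill):
        add(f"GENE-{j + 1:05d}")

    genes = pd.DataFrame(rows, index=pd.Index(names, name="gene"))
    autos = genes["chromosome"] == ""
    genes.loc[autos, "chromosome"] = [
        f"chr{1 + i % 22}" for i in range(int(autos.sum()))]

    # effector labels: most of the first module plus sparse background
    eligible = genes.index[~(genes["is_mito"] | genes["is_ribo"]
                             | (genes["chromosome"].isin(["Y", "X", "MT"])))]
    mod1 = genes.index[genes["module_id"] == 1.0]
    n_mod_eff = int(round(config.effector_module_frac * len(mod1)))
    eff = set(rng.choice(mod1, size=n_mod_eff, replace=False)) if len(mod1) else set()
    background = [g for g in eligible if g not in set(mod1)]
    n_bg = int(round(config.effector_background_frac * len(background)))
    eff |= set(rng.choice(background, size=n_bg, replace=False))
    genes["is_effector"] = genes.index.isin(eff)
    return genes


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _phase_times(t: np.ndarray, frac: float, rng: np.random.Generator) -> np.ndarray:
    """Truncated-normal response-phase jitter around each sampled time."""
    out = np.zeros_like(t, dtype=float)
    pos = t > 0
    if frac <= 0 or not pos.any():
        out[pos] = t[pos]
        return out
    mu, sd = t[pos], frac * t[pos]
    lo, hi = 0.1 * mu, np.minimum(2.5 * mu, 24.0)
    a, b = (lo - mu) / sd, (hi - mu) / sd
    out[pos] = truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng)
    return out


def simulate_dataset(config: SimulationConfig, seed: int) -> tuple[ad.AnnData, GroundTruth]:
    """Simulate one glucose time-course dataset.

    Returns an AnnData of integer counts (cells × genes, sparse CSR) with the
    study metadata in ``.obs``/``.var``, and the :class:`GroundTruth`.
    Identical ``(config, seed)`` reproduce the output bit for bit.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    genes = _build_gene_table(config, rng)
    G = len(genes)
    es, hs, ds = config.effect_spec, config.hurdle_spec, config.depth_spec

    # ---- cell design table ------------------------------------------------
    type_names = [ct.name for ct in config.cell_types]
    props = np.array([ct.proportion for ct in config.cell_types])
    recs = []
    for d in range(config.n_donors):
        for r in range(config.n_replicates_per_donor):
            for t in config.time_points_h:
                arms = ["low"] if t == 0 else ["low", "high"]
                for arm in arms:
                    for _ in range(config.n_cells_per_well):
                        recs.append((f"donor{d + 1}", f"rep{r + 1}", float(t), arm))
    cells = pd.DataFrame(recs, columns=["donor", "replicate", "time_h", "glucose_arm"])
    N = len(cells)
    cells.index = pd.Index(
        [f"CELL{i + 1:06d}" for i in range(N)], name="cell_id")
    cells["cell_type"] = rng.choice(type_names, size=N, p=props)
    cells["phase_time_h"] = _phase_times(
        cells["time_h"].to_numpy(), config.phase_sd_frac, rng)
    cells["is_doublet"] = rng.random(N) < config.doublet_rate

    # ---- log-mean matrix --------------------------------------------------
    base = rng.normal(0.0, config.base_log_sd, G)
    # genes carrying planted effects or module membership sit in the
    # expressed regime, so the planted truth is identifiable at study depth
    planted = (genes["time_effect"] | genes["glucose_effect"]
               | genes["interaction_effect"]
               | genes["module_id"].notna()).to_numpy()
    if planted.any():
        base[planted] = rng.normal(1.2, 0.4, int(planted.sum()))
    sym = genes.index.to_numpy()
    # markers and sex genes: strong fixed baselines
    is_marker = genes["signature_type"].ne("") & ~pd.Index(sym).str.startswith("SIG-")
    base[is_marker.to_numpy()] = 2.0
    base[genes["is_mito"].to_numpy()] = 1.0
    base[genes["is_ribo"].to_numpy()] = 1.5
    chry_mask = (genes["chromosome"] == "Y").to_numpy()
    xist_mask = genes.index.to_numpy() == "XIST"

    sig_fc = np.zeros(G)
    sig_gene_type = genes["signature_type"].to_numpy()
    for ct in config.cell_types:
        in_type = sig_gene_type == ct.name
        fc = np.where(is_marker.to_numpy()[in_type], config.marker_log_fc,
                      rng.normal(ct.signature_log_fc, 0.4, int(in_type.sum())))
        sig_fc[in_type] = np.abs(fc)

    donor_fx = rng.normal(0.0, config.donor_log_sd, (config.n_donors, G))

    x = (cells["phase_time_h"].to_numpy() / 24.0).astype(float)  # [0,1]
    g_high = (cells["glucose_arm"] == "high").to_numpy().astype(float)
    donor_idx = cells["donor"].str.replace("donor", "").astype(int).to_numpy() - 1
    type_idx = pd.Categorical(cells["cell_type"], categories=type_names).codes

    eta = np.tile(base, (N, 1)).astype(np.float32)
    eta += donor_fx[donor_idx].astype(np.float32)
    # cell-type signature boosts
    type_of_gene = pd.Categorical(
        genes["signature_type"], categories=type_names).codes  # -1 for none
    sig_cols = np.where(type_of_gene >= 0)[0]
    if len(sig_cols):
        boost = (type_idx[:, None] == type_of_gene[sig_cols][None, :])
        eta[:, sig_cols] += (boost * sig_fc[sig_cols][None, :]).astype(np.float32)

    # planted effects (delta relative to baseline; reused for detection logit)
    delta = np.zeros((N, G), dtype=np.float32)
    slopes = genes["time_slope"].to_numpy()
    shifts = genes["glucose_shift"].to_numpy()
    inters = genes["interaction_coef"].to_numpy()
    nz = slopes != 0
    if nz.any():
        delta[:, nz] += np.outer(x, slopes[nz]).astype(np.float32)
    nz = shifts != 0
    if nz.any():
        delta[:, nz] += np.outer(g_high, shifts[nz]).astype(np.float32)
    nz = inters != 0
    if nz.any():
        delta[:, nz] += np.outer(x * g_high, inters[nz]).astype(np.float32)
    for shape, (f_lo, f_hi) in MODULE_SHAPES.items():
        cols = np.where((genes["module_shape"] == shape).to_numpy())[0]
        if not len(cols):
            continue
        prof = np.where(g_high > 0, f_hi(x), f_lo(x))
        delta[:, cols] += np.outer(
            prof, genes["module_amplitude"].to_numpy()[cols]).astype(np.float32)
    eta += delta

    # sex profile (both donors male by default: XIST silent, chrY expressed)
    sexes = np.array([config.donor_sexes[i] for i in donor_idx])
    male = (sexes == "male")[:, None]
    if chry_mask.any():
        eta[:, chry_mask] = np.where(male, 0.5, -8.0).astype(np.float32)
    eta[:, xist_mask] = np.where(male, -8.0, 2.0).astype(np.float32)

    # ---- detection component ---------------------------------------------
    depth = np.exp(rng.normal(ds.log_mean, ds.log_sd, N))
    a_g = rng.normal(logit(hs.mean_detection), hs.logit_sd, G).astype(np.float32)
    genes["detection_prob"] = expit(a_g.astype(float))
    logit_p = (a_g[None, :]
               + es.detection_coupling * (eta - base[None, :].astype(np.float32))
               + hs.depth_coupling
               * (np.log(depth) - ds.log_mean)[:, None].astype(np.float32))
    z = (rng.random((N, G), dtype=np.float32) < expit(logit_p))
    # markers/sex baseline genes always eligible so structure is visible
    z[:, is_marker.to_numpy()] |= rng.random((N, int(is_marker.sum()))) < 0.9

    # ---- counts ------------------------------------------------------------
    rel = np.exp(eta, dtype=np.float32) * z
    # mitochondrial load: scale MT genes so the realized fraction tracks the
    # drawn per-cell target (a small "dying" subpopulation exceeds 50%)
    mito_cols = np.where(genes["is_mito"].to_numpy())[0]
    a_m, b_m = config.mito_fraction_beta
    f_target = rng.beta(a_m, b_m, N)
    dying = rng.random(N) < config.dying_cell_frac
    if dying.any():
        a_d, b_d = config.dying_mito_beta
        f_target[dying] = rng.beta(a_d, b_d, int(dying.sum()))
    if len(mito_cols):
        z[:, mito_cols] = True
        nonmito_sum = rel.sum(axis=1) - rel[:, mito_cols].sum(axis=1)
        per_gene = (nonmito_sum * f_target / (1 - f_target) / len(mito_cols))
        rel[:, mito_cols] = per_gene[:, None].astype(np.float32)

    if config.count_mode == "nb":
        p_rel = rel / rel.sum(axis=1, keepdims=True)
        mu = depth[:, None] * p_rel
        theta = np.maximum(ds.nb_dispersion * np.exp(rng.normal(0, 0.2, G)), 0.5)
        lam = np.zeros_like(mu)
        nzm = mu > 0
        lam[nzm] = rng.gamma(
            np.broadcast_to(theta[None, :], mu.shape)[nzm],
            (mu / theta[None, :])[nzm])
        counts = rng.poisson(lam).astype(np.int32)
    else:  # lognormal mode: log counts Gaussian given detection
        log_s = np.log(rel.sum(axis=1))
        noise = rng.normal(0.0, ds.lognormal_sd, (N, G)).astype(np.float32)
        log_c = eta - log_s[:, None].astype(np.float32) + \
            np.log(depth)[:, None].astype(np.float32) + noise
        counts = np.rint(np.exp(log_c)).astype(np.int32)
        counts[~z] = 0

    X = sparse.csr_matrix(counts)
    X.eliminate_zeros()

    # ---- metadata -----------------------------------------------------------
    n_umi = np.asarray(X.sum(axis=1)).ravel()
    n_det = X.getnnz(axis=1)
    mito_counts = (np.asarray(X[:, mito_cols].sum(axis=1)).ravel()
                   if len(mito_cols) else np.zeros(N))
    with np.errstate(invalid="ignore"):
        mito_frac = np.where(n_umi > 0, mito_counts / np.maximum(n_umi, 1), 0.0)
    contam = rng.beta(*config.contamination_beta, N)

    obs = cells.copy()
    obs["sample"] = obs["donor"] + "_" + obs["replicate"]
    obs["contamination_frac"] = contam
    obs["mito_frac"] = mito_frac
    obs["n_umi"] = n_umi.astype(int)
    obs["n_genes_detected"] = n_det.astype(int)

    var = pd.DataFrame(index=genes.index)
    var["gene_id"] = [f"ENSG{i:011d}" for i in range(G)]
    var["symbol"] = genes.index
    var["chromosome"] = genes["chromosome"]
    var["is_mito"] = genes["is_mito"]
    var["is_ribo"] = genes["is_ribo"]

    truth_cells = obs[["donor", "replicate", "time_h", "glucose_arm", "cell_type",
                       "phase_time_h", "is_doublet", "contamination_frac"]].copy()
    adata = ad.AnnData(
        X=X,
        obs=obs.drop(columns=["cell_type", "phase_time_h", "is_doublet"]),
        var=var)
    return adata, GroundTruth(genes=genes, cells=truth_cells)
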