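# isletime

Analysis pipeline for 24-hour glucose-exposure time courses of human
pancreatic islets profiled by single-cell RNA-seq — for researchers asking
how islet cell types respond transcriptionally to hyperglycemic exposure
over time, and which responding genes are candidate effectors of type 2
diabetes-related traits.

The experimental design it models: islets held at low (2.8 mM) or high
(15 mM) glucose, sampled for scRNA-seq at 0, 1, 2, 4, 8, 12 and 24 hours
(no high arm at 0 h), with multiple donors and replicate wells. The package
ships a seeded synthetic-data generator that emulates this design with
planted effects, so every stage is tested end to end against known truth
without any external download.

## What it computes

**QC and normalization** — fixed-order filters (ambient contamination
> 10%, mitochondrial fraction > 50%, UMI outliers, rarely expressed genes,
mito/ribo genes), ln(CP10K+1) normalization, pseudobulk sex checks and
replicate correlations.

**Cell-type annotation** — variable genes by cross-sample voting, PCA with
a knee rule, Leiden clustering with the resolution chosen by a held-out
classifier: the largest resolution whose worst cluster still exceeds
Matthews correlation coefficient (MCC) 0.75, then marker-based labels
(GCG → alpha, INS → beta, SST → delta, PPY → gamma, PRSS1 → acinar,
KRT19 → ductal).

**Interpolated time** — cells at one sampled time point sit at different
response phases; per cell type × glucose arm,

```
t̂ = t·w + [ Σᵢ tᵢ/dᵢ / Σᵢ 1/dᵢ ] · (1 − w)
```

blends the sampled time t with the inverse-distance-weighted mean time of
the n nearest expression-space neighbors (defaults n = 75, w = 0.25), then
standardizes to [0, 1] within the stratum.

**Hurdle differential expression** — per gene, a logistic model for
detection and a Gaussian model for the level when detected:

```
logit Pr(Z = 1 | X) = Xβ        Y | Z = 1 ~ N(Xβ′, σ²)
```

tested by the summed-χ² likelihood ratio across both parts, with cell
complexity and donor covariates, a median-CP10K ≥ 1 prefilter and BH
adjustment per (cell type, design). Designs: basal-vs-high (BvH),
basal-vs-low (BvL, isolates time in culture), low-vs-high (LvH, isolates
glucose) at each time point, plus continuous time, glucose and
time:glucose-interaction models on interpolated time.

**Co-expression modules** — lowess-smoothed profiles over interpolated
time (one per arm, 21-point grid) clustered by a Dirichlet-process mixture
of Gaussian processes; a consensus matrix over 45 (alpha, auxiliary-
cluster) configurations is cut by iterative k-means into modules with
within-module co-clustering ≥ 0.75 and ≥ 5 genes.

**Enrichment and prioritization** — upper-tail hypergeometric tests of
modules against effector/GO-style gene sets (GMT), and a polygenic
priority score: gene-level association scores regressed on single-cell-
derived features (PC loadings, Welch marker statistics, mean expression,
specificity, DGE statistics) by GCV-tuned ridge, with significance from
10,000 gene-identifier permutations, empirical p = (r+1)/(n+1) on the
pooled null, and BH across genes.

## Worked example

`examples/05_hurdle_dge.py` simulates a beta-cell population with 40
planted glucose-shift genes (log fold change 1.0 in the high arm) and runs
three designs:

```
LvH     : planted glucose genes recovered 40/40  |  null-gene p<0.05 rate 0.093
BvL     : planted glucose genes recovered 0/40   |  null-gene p<0.05 rate 0.065
glucose : planted glucose genes recovered 40/40  |  null-gene p<0.05 rate 0.322

top LvH genes at 24 h:
  gene  coef_cont    chisq  df   p   q
 GLC-3    -1.0398 559.1404   2 0.0 0.0
GLC-34     0.9838 463.2235   2 0.0 0.0
 GLC-6     0.9226 437.9416   2 0.0 0.0
```

Reading this: the low-vs-high contrast and the continuous glucose model
recover every planted gene at FDR < 5% with continuous-part coefficients
near the planted ±1.0, while basal-vs-low — which never sees the high
arm — recovers none, confirming the designs isolate what they claim to.
The elevated null-gene rates of the same-axis contrasts are the CP10K
compositional artifact (strongly shifted genes move everyone else's
relative abundance slightly); the orthogonal contrast is immune.

`examples/07_enrichment.py` seeds one of five 20-gene modules with 60%
effector genes against a 5% background and prints

```
 module  k  K  m   N        p   q
      1 12 31 20 400 0.000000 0.0
      2  1 31 20 400 0.808845 1.0
...
modules enriched at FDR<5%: [1]
```

— only the seeded module survives the hypergeometric test with BH
adjustment.

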