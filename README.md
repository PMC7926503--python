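# claudinlow

Claudin-low (CL) tumors are a rare, biologically aggressive subtype first
described in breast cancer and since reported in other epithelial cancers,
including high-grade serous ovarian carcinoma (HGSOC). They are defined
transcriptionally: coordinated loss of tight/adherens-junction and epithelial
differentiation genes (claudins 3/4/7, E-cadherin, occludin, EPCAM, MUC1,
CD24) together with gain of EMT and stemness markers (vimentin, SNAI1/2,
TWIST1/2, ZEB1/2, CD44, ALDH1A1), and they carry a worse prognosis.

This package implements, as a tested and reusable pipeline, the
computational procedure used to find and characterize such a subpopulation
in bulk expression cohorts:

1. **Preprocessing** — log2 transform and within-cohort quantile
   normalization.
2. **Subtype calling**, two ways:
   * a **nearest-centroid predictor**: per-group mean expression vectors
     (centroids) over a fixed gene list are trained on a labeled reference
     panel (e.g. 9 CL + 43 other cell lines) and each profile is assigned to
     the nearer centroid in Euclidean distance;
   * **signature clustering**: Ward/Euclidean hierarchical clustering of
     samples on a packaged 17-gene CL marker signature, followed by an
     explicit CL-cluster score (mean z of up-markers minus mean z of
     down-markers, averaged within cluster) with an abstention threshold.
3. **Differential expression** — empirical-Bayes moderated t-statistics:
   per-gene pooled variances `s_g^2` (df `d_g`) are shrunk toward a prior
   `s_0^2` with df `d_0` fitted across genes,
   `s~_g^2 = (d_0 s_0^2 + d_g s_g^2)/(d_0 + d_g)`, and
   `t~_g = log2FC / (s~_g sqrt(1/n_1 + 1/n_2))` on `d_0 + d_g` df, with
   BH-FDR control and both published DEG filters as named modes.
4. **Preranked gene-set enrichment** — weighted Kolmogorov–Smirnov running
   sum on the moderated-t ranking, gene-label permutation null, NES, nominal
   p and sign-stratified FDR q.
5. **Survival** — per-cohort Cox proportional-hazards fits of the CL
   contrast (Efron ties) pooled by inverse-variance meta-analysis, both
   fixed-effect and DerSimonian–Laird random-effects, with Q, I² and τ².

A synthetic-data module generates multi-cohort studies with a planted CL
subpopulation (block-correlated signature shifts, exponential survival with
elevated CL hazard, calibrated uniform censoring), so the whole pipeline is
exercisable and testable offline.

The statistical cores are exposed as scikit-learn-style estimators
(`QuantileNormalizer`, `CentroidSubtypeClassifier`, `WardSubtypeClusterer`,
`ModeratedTTest`) that compose with sklearn pipelines; the module-level
functions are thin wrappers over them operating on the domain containers
(`ExpressionMatrix`, `MarkerSignature`, `LabeledReference`).

## Worked example

```python
import claudinlow as cl

config = cl.SimulationConfig(n_genes=120, n_samples=200, n_cohorts=2, seed=3)
study = cl.simulate_study(config)          # panel (9 CL + 43 other) + cohorts
cohort = study.cohorts[0]

# centroid predictor trained on the labeled panel
model = cl.build_centroids(study.panel)
calls = cl.assign_subtype(model, cohort.expression)
print((calls["label"] == cohort.labels).mean())      # 1.0

# signature clustering with the packaged 17-gene CL signature
sig = cl.load_cl_signature()
result = cl.ward_cluster(cohort.expression, sig)
print(result.cluster_scores)   # {1: 4.71, 2: -0.52} -> cluster 1 is CL
print((result.calls == cohort.labels).mean())        # 1.0

# moderated-t DE and DEG filtering
de = cl.moderated_t(cohort.expression, result.calls)
print(len(cl.filter_degs(de, mode="results")))       # 17 (the planted genes)

# survival meta-analysis across cohorts
fits = [cl.cox_fit(c.clinical, c.labels, cohort=c.name) for c in study.cohorts]
meta = cl.meta_pool(fits, model="random")
print(round(meta.hr(), 2), [round(x, 2) for x in meta.ci()])  # 1.96 [1.35, 2.85]
```

With the default planted effect (4 log2 units on the signature genes, 10%
CL fraction) both callers label every sample correctly, the DEG filter
recovers exactly the planted signature genes, and the pooled hazard ratio
is elevated for the CL group (planted log HR 0.9, i.e. HR ≈ 2.5).

A `claudinlow` command-line interface wraps the same stages
(`simulate`, `preprocess`, `subtype classify`, `subtype cluster`, `de`,
`gsea`, `survival`, `run-all`); `run-all` writes per-stage TSVs plus a
`manifest.json` with the resolved config, seed, and a checksum of every
output, and is bit-reproducible for a fixed seed.

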