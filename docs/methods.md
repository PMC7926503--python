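# Methods

This note documents the models, defaults and numerical choices behind the
package, what the synthetic-data generator does and does not emulate, and the
design decisions taken where the analysis recipe leaves the choice open.

## The claudin-low signature and its two callers

The packaged signature has 17 genes: 8 expected **down** in claudin-low (CL)
tumors (CLDN3, CLDN4, CLDN7, CDH1, OCLN, CD24, EPCAM, MUC1) and 9 expected
**up** (VIM, SNAI1, SNAI2, TWIST1, TWIST2, ZEB1, ZEB2, CD44, ALDH1A1).
Gene symbols are matched case-insensitively after uppercasing, with a single
packaged alias (TACSTD1 → EPCAM). There is no fuzzy matching: a silent
mismatch is worse than a reported miss. Duplicate gene rows are collapsed by
arithmetic mean on the log2 scale.

**Nearest-centroid predictor.** A centroid is the per-gene arithmetic mean
of a reference group's expression over a fixed gene list; a profile is
assigned to the nearer centroid in Euclidean distance, using raw log2 values
(no per-gene standardization — the predictor is defined on the expression
scale of its training panel). Genes absent from the query matrix are dropped
from both the sample vectors and the centroids, so distances stay
comparable; the model proceeds on the intersection, warns, and hard-fails
only below 50% gene coverage (configurable). An exact distance tie is
assigned "other": for a rare-subtype caller the conservative error is to
miss a borderline case, not to invent one.

**Signature clustering.** Samples are clustered on the 17 signature genes
with Ward's minimum-variance criterion and Euclidean distances, genes
standardized across samples first (standard heat-map practice for signatures
of mixed dynamic range; the toggle is exposed). The classic Ward criterion
on within-cluster sum-of-squares increments is used, as implemented by the
Lance–Williams recursion in scipy: for two singletons the merge cost is
`||a − b||² / 2`, and in general `cost = height² / 2` for the reported
linkage heights. The tree is cut into k clusters (default k = 2).

Because "identify the CL cluster on the dendrogram" is otherwise a human
judgment, the package makes it explicit with a **CL concordance score**:
z-score each signature gene across all samples of the cohort, score each
sample as `mean z(up genes) − mean z(down genes)`, and score each cluster by
the mean over its samples. The top-scoring cluster is called CL only if its
score reaches a threshold, default 1.0 pooled-z units — roughly "the cluster
sits a full standard deviation in the CL direction". Under null cohorts
(no planted subtype) this abstains in ~95% of runs while a planted shift of
4 log2 units yields scores near 4–5; the threshold and k are configurable.

## Synthetic cohorts

The generator plants the structure the analysis assumes, nothing more:

* background genes: `baseline_g + σ·N(0,1)`, i.i.d. across samples, with
  per-gene baselines ~ N(7, 1) (mid-range log2 microarray intensities);
* signature genes: two equicorrelated blocks (up-genes and down-genes) with
  within-block correlation ρ (default 0.3), emulating the co-regulation that
  makes the signature cluster visually coherent;
* planted CL samples (fraction π, default 0.1) receive ±δ on the signature
  genes (default δ = 4 log2 units, a "extremely low / extremely high"
  expression shift that separates cleanly; harder regimes are a parameter
  away);
* survival: exponential with hazard `exp(λ0 + β_CL·1[CL])`, defaults
  λ0 = −2 and β_CL = 0.9, with independent Uniform(0, c) censoring where c
  is solved numerically (Brent) so the expected censored fraction matches
  the requested rate (default 0.3);
* the reference panel defaults to 9 CL + 43 other samples and shares
  per-gene baselines with the cohorts of the same study, making it a
  matching training panel for the centroid predictor.

All randomness flows from one seeded `numpy.random.default_rng` (PCG64,
recorded in the output metadata); identical configs are bit-identical.

What this does **not** emulate: probe-level artifacts, platform or batch
effects beyond per-cohort baselines, non-proportional hazards, informative
censoring, or a CL "continuum". Passing tests therefore demonstrate that the
pipeline's machinery is correct and calibrated under its own assumptions —
not that real cohorts satisfy those assumptions.

Tests and the acceptance script run the generator at reduced gene counts
(17–500 genes rather than the 2 000-gene default) — the package's own choice
of problem size: every planted structure is preserved and all statistics
(which are per-gene or signature-restricted) are unaffected.

## Preprocessing

Values are log2-transformed with a pseudocount (default 1) unless already
logged; negative inputs raise with a hint that the data are probably already
on the log scale. Quantile normalization maps every sample to the reference
distribution of row means of the column-sorted matrix; ties receive the mean
of the reference values at their tied ranks, so tied inputs stay tied and
the transform is idempotent on tie-free data. Normalization is strictly
per cohort — cohorts are analyzed separately and only unit-free summaries
(subtype calls, log hazard ratios) are ever pooled.

## Moderated t

The empirical-Bayes prior (d₀, s₀²) is fitted by method of moments on
`log s_g²` using digamma/trigamma moment identities of the scaled-F model,
with d₀ found by monotone root-finding (Brent) on the trigamma equation.
If the empirical spread of `log s_g²` does not exceed what finite-df chi²
sampling alone explains, d₀ = ∞ (full shrinkage); a fully degenerate,
dispersion-free variance vector returns a point-mass prior at the common
value. d₀ = 0 reproduces the ordinary pooled two-sample t exactly (verified
to 1e-12 in tests), and type-I error at n = 3 vs 3 stays within
[0.04, 0.06] over 200 null simulations.

Both published DEG filters are exposed as named modes rather than silently
choosing one, since they genuinely differ: `"methods"` (|log2FC| > 2 and raw
p < 0.01) and `"results"` (BH q ≤ 0.01 and linear fold change > 2 or < 0.5,
i.e. |log2FC| > 1). `"results"` is the default. No minimum-expression
prefilter is applied.

## Preranked enrichment

Enrichment uses the weighted KS running sum (weight p = 1 on |t|): hits
increment by `|r_i| / Σ_hits |r|`, misses decrement by `1/(N − N_hits)`;
ES is the extremum of largest magnitude (an exact magnitude tie goes
positive). The null is gene-label permutation — random sets of matching size
from the ranked list — because the ranking, not the expression matrix, is
the input at this stage; n_perm defaults to 1000. NES divides ES by the mean
magnitude of same-sign null scores; the nominal p uses the
(1 + more-extreme)/(1 + same-sign) small-sample convention; FDR q follows
the sign-stratified pooled-NES procedure. For efficiency the running-sum
extremum is evaluated only at the 2·|S| candidate points where it can occur
(immediately after a hit for the maximum, immediately before one for the
minimum); tests verify exact agreement with a term-by-term O(N·|S|)
recomputation. Ranking ties are broken by gene symbol so output is
deterministic across platforms. The packaged 5-set toy GMT (built from the
CL signature) supports tests and demos; real collections (e.g. Hallmark)
are user-supplied GMT inputs.

## Survival meta-analysis

Each cohort contributes a univariate Cox fit of overall survival on the CL
indicator — Newton–Raphson maximization of the partial likelihood with Efron
tie handling (via lifelines, convergence tightened to 1e-9) — with the
standard error from the observed information. Fits with no events in a
group, a single subtype, or separation are returned flagged and excluded
from pooling with a warning: explicit over silent. Only Efron tie handling
is exposed; under the generator's continuous event times ties are
measure-zero anyway.

Pooling is inverse-variance on the log-HR scale (unit-free, so cohorts may
use different time units): fixed-effect, plus DerSimonian–Laird τ²
(clipped at zero) for random effects, with Cochran Q and
I² = max(0, (Q − (k − 1))/Q)·100. Both estimates are always computed;
random effects is the headline default, appropriate for heterogeneous
cohorts and platforms. With k = 1, τ² is defined as 0 and the two coincide.

## Pipeline

`run_pipeline` executes simulate/load → preprocess → subtype → DE →
enrichment → survival, one cohort at a time with a final cross-cohort meta
stage. When both subtype callers run, downstream stages use the
cluster-based calls (the patient-cohort procedure) while centroid calls and
a concordance report are also written; on default synthetic effect sizes the
two agree on ≥ 90% of samples. Configuration is plain YAML with no hidden
defaults — the resolved config, the seed, the package version and a SHA-256
checksum of every output file go into `manifest.json`, and a fixed seed
reproduces every output bit-for-bit. A stage failure halts the run naming
the stage; partial outputs are retained. Cohorts where a caller finds fewer
than two CL samples skip DE/enrichment (noted in the stage log) and their
Cox fit is flagged rather than fitted degenerately.

## Known limitations

* The centroid predictor assumes query profiles share the training panel's
  expression scale; no cross-dataset rescaling is applied beyond per-cohort
  quantile normalization.
* The cluster caller's k (default 2) and score threshold (default 1.0) are
  explicit stand-ins for a judgment made visually in practice; cohorts with
  several rare subpopulations may need larger k.
* The moderated-t model is a two-group contrast without covariates; the
  survival model is unadjusted (no stage/grade/debulking covariates) and
  assumes proportional hazards.
* Real-data headline figures (subtype prevalences, DEG totals on public
  cohorts) depend on external downloads and probe-level processing outside
  this package's scope; the package's guarantees are the calibration and
  recovery properties its tests and acceptance script compute.
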