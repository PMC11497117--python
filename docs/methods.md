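# Methods

This note documents the models and procedures `spatialniche` implements,
the parameter defaults and why they were chosen, what the synthetic tissue
generator does and does not emulate, and the numerical conventions that
make results exactly reproducible.

## Phenotyping

Input is a segmented-cell table: `cell_id, sample_id, x_um, y_um` plus one
intensity column per marker (NOS2, COX2, CD8; further markers pass
through).  Intensities are quantized per marker into four ordinal levels by
three thresholds (`negative < t_weak <= weak < t_moderate <= moderate <
t_strong <= strong`), all boundaries lower-inclusive.  Absolute thresholds
are instrument-dependent, so the default rule derives them as per-cohort
intensity quantiles (0.5/0.75/0.9), with explicit thresholds available via
JSON config.

Levels collapse to a ± call per marker through a positivity set that must
be upward-closed in level order.  Defaults: CD8⁺ at any signal (lineage
marker), NOS2⁺ and COX2⁺ at moderate-or-above (graded functional markers).
Whether strong COX2 should count toward COX2⁺ is genuinely ambiguous in
visually scored data; both behaviors are expressible through the
positivity set, and moderate-or-above is the default.  The three calls pack
into `code = 4·CD8 + 2·NOS2 + COX2`; the NOS2 level is kept alongside the
code because several analyses single out strong-NOS2 ("NOS2s") cells.

## Neighborhood census

For each cell, neighbors are counted per phenotype in five annuli with
edges 0, 25, 50, 100, 150, 200 μm and divided by the exact annulus area in
mm², yielding a 40-value profile (phenotype-major layout, columns
`d<p>_b<b>`).  Conventions, fixed because they change third-decimal
results: intervals are half-open `[lo, hi)`; the focal cell is excluded;
densities are per annulus (not per cumulative disk); censuses never mix
cells of different samples.  The production path uses a k-d tree with
fixed-radius pair queries; an O(n²) all-pairs oracle with the same
contract exists purely for testing, and the two agree to 1e-9 on random
instances.  Conservation holds exactly: density × annulus area returns the
integer neighbor count.

Cells whose 200 μm disk crosses the tissue bounding box see truncated
annuli.  The census does not correct annulus areas; instead an edge policy
(`keep`/`flag`/`exclude`, default `flag`) marks or removes such cells, so
the edge-exclusion behavior used in curated imaging analyses is available
without discarding data by default.

## Niche discovery

The profile matrix of all samples is embedded to 2D with UMAP
(`n_neighbors=30, min_dist=0.1`, Euclidean, fixed seed; profiles unscaled
by default, column z-scoring optional).  These hyperparameters are package
defaults, not claims about any particular dataset.  Both outcome groups'
cells are binned on a shared 100×100 grid spanning the joint embedding
extent; each group's histogram is normalized by its own cell total, so
group size does not bias the contrast.  The contrast field is
log₁₀((f_D + ε)/(f_A + ε)) with ε defaulting to the smallest nonzero bin
frequency (one count in the larger group), which bounds empty-bin ratios
without drowning real signal.  Cells of the deceased group in bins with
field > +0.01, and alive-group cells in bins with field < −0.01, form the
two enriched sets; the two bin sets are disjoint by construction and the
field negates exactly under group swap.

Each enriched set is clustered by k-means (k-means++ init, 10 restarts,
fixed seed) on the 2D embedding coordinates for k = 2…10; the k minimizing
the Davies–Bouldin index is kept, ties broken toward smaller k.  Clusters
are renamed by descending size (D1…Dk, A1…Ak) and characterized by the
mean ± SEM (sd/√n, ddof 1) of their member cells' 40-value profiles, their
prevalence (cluster size / all group cells), and per-phenotype ratio
profiles between clusters, with a 1 cells/mm² denominator floor to keep
ratios finite where a phenotype is absent (floor=0 raises instead).

A practical caveat established on synthetic cohorts: the Davies–Bouldin
criterion over a UMAP layout is a coarse model-selection tool.  At some
seeds it merges a small, well-separated niche island into a larger
cluster (underestimating its enrichment) or slices it (overestimating it);
cluster-level ratio estimates of a planted 10× niche ranged roughly 7–14
across seeds.  The census-level ground truth is stable (≈10.3×), so
cluster ratios should be read as semi-quantitative.

## Survival analysis

Per-sample covariates are ratios: strong-NOS2 cell count / CD8⁺ cell count
and COX2⁺ cell count / CD8⁺ cell count for imaging cohorts, or NOS2/CD8A
and COX2(PTGS2)/CD8A expression for transcriptomic cohorts (a minimal GEO
series-matrix text reader is included; `geo_ratio_survival` itself
consumes plain expression + survival tables).  Samples split at the median
ratio, ties to "low"; an all-tied covariate cannot be split and raises.

Events beyond the analysis horizon (default 5 years) are administratively
censored at the horizon — truncation rather than exclusion, so late
survivors still contribute risk time.  Kaplan–Meier curves come from
lifelines.  The log-rank (Mantel–Cox) statistic and the Mantel–Haenszel
hazard ratio are computed from one pooled tabulation over distinct event
times: with n_gj at risk and d_gj events in stratum g at time t_j,
E_gj = d_j n_gj/n_j and V_j the hypergeometric variance,
χ² = (O₁−E₁)²/ΣV_j (1 df), HR = (O_h/E_h)/(O_l/E_l), and
CI = exp(log HR ± 1.96·√(1/E_h + 1/E_l)).  Orientation is high vs low:
HR > 1 means high-ratio samples fare worse.  The O/E ("Pike") estimator is
known to attenuate large hazard ratios when nearly all subjects experience
events; under the package's cohort conditions (baseline hazard 0.05/yr,
5-year horizon) the attenuation is small (planted 5.67 recovered at ≈5.4
on average), but users analyzing fully-observed data should expect it.
When a covariate separates outcomes perfectly (one stratum has no events)
the MH hazard ratio is undefined; the pipeline reports a structured error
for that covariate rather than a number.

## Synthetic tissue generator

A sample is a rectangular field (μm, origin bottom-left, y-up) with a disk
`tumor_core`, a `stroma_margin` annulus (default width 300 μm), and
`stroma`.  Cells are homogeneous Poisson within each region at per-region,
per-phenotype intensities (cells/mm²).  Three archetypes:

* `immune_desert` (deceased): COX2⁺ core at 1,000 cells/mm² with zero CD8;
  sparse CD8⁺ lymphoid aggregates placed 500–1,000 μm beyond the edge.
* `inflamed_margin` (deceased): COX2⁺ core, CD8⁻NOS2⁺COX2⁺ satellite
  clusters on the tumor edge, a dense stroma-restricted CD8⁺ band offset
  from the edge by `cd8_gap_um` (default 50 μm), and distal aggregates.
  All CD8⁺ placements respect the gap, so the planted gap invariant is
  exact by construction.
* `fully_inflamed` (alive): diffuse CD8⁺NOS2⁻COX2⁻ infiltration through
  core (800/mm²) and stroma, plus a uniform 320 cells/mm² baseline of the
  satellite phenotype that serves as the reference density for niche
  enrichment ratios.

Satellite clusters are Thomas-type — Poisson offspring counts (mean 40)
with isotropic Gaussian dispersion (σ = 30 μm) — but their parents are
placed evenly spaced (jittered) on the edge circle rather than as a
Poisson line process.  Non-overlapping satellites keep the planted local
density analytically predictable: the size-biased expected sibling density
within radius R of a member cell is μ(1 − e^{−R²/4σ²})/πR² ≈ 3,250
cells/mm² at R = 25 μm, i.e. ≈10× the alive-group baseline.  Densities
for aggregates and satellites are not measurements of any real cohort;
they are chosen so that planted niches are separable by the analysis and
are fully config-exposed.

Marker intensities are synthesized as level means placed midway between
the canonical thresholds (1, 2, 3) — negative 0.5, weak 1.5, moderate 2.5,
strong 3.5 — plus Gaussian noise (sd 0.15 by default, ≈3σ from the nearest
boundary).  At sd = 0 quantization is exactly invertible, giving the
round-trip identity used in tests.  NOS2⁺ cells are synthesized at strong
level so NOS2s analyses see them; CD8⁺/COX2⁺ at moderate.

Cohorts alternate deceased samples between the two deceased archetypes and
draw alive samples from `fully_inflamed`; per-sample seeds derive from the
master seed via a counter-based `SeedSequence` split, so any sample can be
regenerated independently.  Deceased samples get event times uniform in
0.5–4.5 years; alive samples are censored at 5 years.  The survival-only
generator draws exponential event times at baseline hazard 0.05/yr (low
stratum; ≈22% five-year mortality, a realistic cohort regime) and
baseline × HR for the high stratum, with optional random censoring and an
optional administrative horizon.

What the generator does **not** emulate: imaging noise and segmentation
error, cell-size exclusion effects (points may lie arbitrarily close),
marker spillover, irregular tumor geometry, intra-tumor heterogeneity
beyond the three-region model, and covariation between marker levels.
Passing tests therefore demonstrate correctness of the computations and
recoverability of planted structure, not performance on clinical images.

## Numerical conventions and scale choices

* Coordinates μm; densities cells/mm²; times years.
* All randomness flows from explicit integer seeds; fixed seed + config ⇒
  byte-identical outputs, recorded in a run manifest (seeds, parameters,
  input digest).  File writes are atomic (temp + rename).
* Overlapping region annotations resolve by a documented priority
  (lymphoid_aggregate > satellite > edge > nest > core > desert > stroma);
  boundary points count as inside; empty regions report missing (NaN), not
  0%.
* Nearest-neighbor gap distances are cell-center to cell-center.
* Immune-desert threshold: CD8⁺ density strictly below 100 cells/mm².
* Test and acceptance problem sizes — cohorts of 5+5 samples at ~2,000–
  5,000 cells/sample (~35k profiles), 20 census/oracle instances of
  500–1,000 cells, 500 null log-rank replicates, 200 hazard-ratio
  replicates at n = 600 — were chosen as the smallest scales at which the
  Monte-Carlo bands in the tests are stable.
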