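# Methods

This note documents the statistical procedures implemented in
`soilcore`, the choices made where the design was genuinely open, and
what the synthetic-data validation does and does not demonstrate.

## Study design and data model

The pipeline targets a paired design: two sites, each sampled in two
microhabitats — *understory* (soil beneath a shrub's canopy) and *gap*
(nearby open soil) — with ~10 replicate samples per site×microhabitat
group. Inputs are a feature-by-sample integer count table (ASVs or
genera), a ranked taxonomy per feature, and per-sample metadata.
Features that cannot be classified at the phylum level are removed
before analysis; counts are then agglomerated to genus by summing
features with identical genus labels. Features lacking a genus are
pooled under an `unclassified:<lowest named rank>` sentinel: the pool
contributes to relative-abundance denominators (it is real sequencing
mass) but is never a core candidate, since an unclassified pool is not a
genus. Agglomeration conserves per-sample totals exactly.

## Normalization

**Relative abundance** divides each sample column by its total.

**Prevalence filter**: a feature is retained iff present (count > 0) in
at least `ceil(f·n)` of the `n` samples, default `f = 0.10`. Equivalently
the removed set is exactly the features whose presence fraction is below
10%. `ceil` is computed with a 1e-9 guard against float artifacts
(`0.1 × 20` is not exactly 2 in binary floating point).

**CSS (cumulative sum scaling)**: for sample *j*, let *q₍j₎* be the
`quantile`-th value of the sample's *positive* counts under the
lower-interpolation rule, and *s₍j₎* the sum of all counts ≤ *q₍j₎*. The
normalized value is `c′ = c / s₍j₎ × N` with the global constant *N*
defaulting to the median of the *s₍j₎*. Choices made here:

- the quantile is **fixed at 0.5** and exposed as a parameter, rather
  than selected adaptively by the original CSS instability criterion;
  the fixed quantile is reproducible and sufficient for the analyses in
  scope;
- the quantile is taken over positive counts only — including zeros
  would collapse *q₍j₎* to 0 for sparse samples and make the factor
  degenerate;
- zero cells are exactly preserved (the transform is per-sample linear).

## Diversity

**Chao1** richness, per sample, on integer counts *after* the prevalence
filter but *before* CSS — the estimator extrapolates unseen taxa from
singleton (F₁) and doubleton (F₂) counts, which only exist on the raw
count scale. Bias-corrected form `S_obs + F₁(F₁−1)/(2(F₂+1))` by
default; the classic `S_obs + F₁²/(2F₂)` falls back to the
bias-corrected form when F₂ = 0, and both return `S_obs` when F₁ = 0.
Group differences are tested with tie-corrected Kruskal–Wallis
(chi-square reference, k−1 df); a fully tied vector returns H = 0 with a
degenerate-data flag rather than an error. Multiple contrasts are
corrected with Benjamini–Hochberg step-up.

**Bray–Curtis** dissimilarity `Σ|x−y| / Σ(x+y)` is computed on the
CSS-normalized table (normalization precedes all β-diversity analysis).

**PCoA** is classical scaling: double-center `−D²/2`, eigendecompose,
coordinates are eigenvectors scaled by √eigenvalue. Negative eigenvalues
(Bray–Curtis is non-Euclidean) are reported and their axes dropped;
proportions explained are taken over the positive eigenvalues only. No
Cailliez/Lingoes correction is applied — the conclusions in scope
(grouping structure, PERMANOVA) do not depend on it.

**PERMANOVA** is one-way on the 4-level site×microhabitat grouping:
`SS_total = Σ_{i<j} d²ᵢⱼ / N`, `SS_within` the analogous per-group sum,
`F = (SS_between/(k−1)) / (SS_within/(N−k))`, `R² = SS_between/SS_total`.
The p-value counts label permutations with F ≥ F_obs under the add-one
convention `(hits+1)/(n_perm+1)`, so p is never 0 and is floored at
`1/(n_perm+1)`. Pairwise contrasts run one PERMANOVA per unordered group
pair on the restricted submatrix, BH-adjusted; per-pair seeds are
spawned from the given seed via `numpy.random.SeedSequence`, so every
p-value is reproducible and the seed is recorded in the result. A
two-factor (site × microhabitat interaction) design is deliberately out
of scope; the one-way grouping plus pairwise contrasts reproduces the
group-level comparisons of interest.

## Core identification

At threshold *t* (percent):

1. **group abundance sets** — per site×microhabitat group, the genera
   whose group-level summary of per-sample relative abundances is
   ≥ *t*/100. The summary statistic defaults to the **mean** across the
   group's samples (the most common reading of a group-level abundance
   threshold); **max** is exposed as an option. The comparison is
   inclusive (≥).
2. **gap exclusion** — from each site's understory set, remove every
   genus with any raw presence in any gap sample of *either* site
   (pooled exclusion, matching a null model of complete absence from
   uninfluenced soil). A per-site exclusion variant is available for
   per-site views.
3. **cross-site core** — intersect the two sites' exclusive sets and
   keep genera with occupancy 1.0 over the pooled understory samples of
   both sites and 0.0 over all gap samples. Pooled 100% occupancy is
   equivalent to 100% at each site separately.

Presence is always raw count > 0: CSS cannot create or destroy zeros,
but raw counts are the unambiguous basis for occupancy. Because every
predicate is monotone or threshold-free, group sets, exclusive sets and
core sets all nest as the threshold increases; `threshold_sweep` checks
a grid (default 0.2, 0.5, 1, 5%) and `venn_partition` decomposes the
four group sets into their 15 label-combination regions by direct
membership testing.

## Differential abundance

A deliberately simple negative-binomial Wald test stands in for heavier
packaged machinery; its outputs are validated by simulation (below), not
by numerical agreement with any packaged tool. Empirical-Bayes
dispersion shrinkage, outlier (Cook's distance) filtering, and
independent filtering are non-goals.

- **Size factors**: median-of-ratios against a geometric-mean reference
  over features positive in all samples; when no feature is all-positive
  a zero-tolerant variant uses per-feature geometric means over positive
  counts only. Factors are renormalized to geometric mean 1.
- **Dispersion**: per-genus method-of-moments on normalized counts,
  `α = max(0, (var − mean)/mean²)` with the within-group pooled variance
  (group means removed) and the grand mean; floored at 1e-8.
- **Wald test**: group means on the normalized scale with a +0.5
  pseudo-count (prevents infinite fold changes at structural zeros; the
  pseudo-count is recorded in the result), `log2FC =
  log2(m_understory/m_gap)` — positive means understory-enriched — with
  a delta-method SE from the NB variance `μ + αμ²` of each group mean
  and a two-sided normal reference. No t-correction is applied: at
  n = 10 per group the null simulation shows the normal reference is
  adequately calibrated (KS distance to uniform ≈ 0.03–0.05 at 500
  genera; BH discoveries under the null ≤ 0.5%). Genera with zero counts
  in both groups are dropped before testing.
- The +0.5 pseudo-count makes fold-change estimates *approximately*
  (not exactly) invariant to uniform rescaling of one sample's counts:
  the geometric-mean-1 renormalization shifts the normalized scale by
  `c^(1/n)`, which perturbs the pseudo-counted means in the third
  decimal. Sign antisymmetry under group relabeling is exact.

Functional tallies count significant genera per user-supplied category
(exact genus-name match after case-folding; a genus with several
categories contributes to each; unmapped genera are counted separately),
split by enrichment direction.

## Synthetic data generator

The generator emulates the paired design: 2 sites × 2 microhabitats ×
10 samples (default), per-sample depth uniform on 20 000–60 000 reads
(exercising normalization without modeling run-level effects), and
counts drawn Dirichlet-multinomial — mixing proportions ~
Dirichlet(concentration × group proportions), counts ~
Multinomial(depth, mixing) — with a single concentration scalar
(default 200) producing the overdispersion typical of amplicon data.
Background genus abundances are log-normal with σ = 1.5 decades, giving
a realistic rank-abundance curve; 200 background genera by default.

Planted structure:

- **core genera** (3 prokaryote-like + 2 fungal-like) are assigned a
  fixed proportion (default 1% each) of understory mass, with the
  remaining genera rescaled, and exactly zero probability in gap
  groups. Structural absence is exact: zero-probability genera never
  receive reads. Presence in every understory sample is guaranteed by
  redrawing a sample whose Dirichlet-multinomial draw happens to zero a
  core genus (probability ~1e-4 per sample at defaults, so the
  conditioning bias on abundances is negligible);
- **site-specific genera** (5 per site) have zero probability at the
  other site;
- **differential genera** (10) are shared by both microhabitats with
  their understory proportions multiplied by 2^(log2FC), default
  log2FC = 2.

The recorded truth (core set, site-specific sets, per-genus fold
changes, group mean proportions) is written alongside the TSV bundle
with a JSON manifest (format version, seed, config echo, checksums).

What the generator does **not** emulate: taxonomic mis-assignment,
chimeras and contamination, compositional correlation structure between
genera, run/batch effects on depth or composition, and spatial
autocorrelation between replicates. Passing the recovery tests therefore
shows the pipeline's logic is correct under its stated model, not that
field data of any particular quality will yield a clean core.

## Validation and problem sizes

The test suite validates each stage against hand-computed closed forms
and independent oracles (a brute-force predicate enumerator for the core
caller, a double-loop Bray–Curtis, exhaustive permutation enumeration at
n = 6, scikit-bio's PERMANOVA statistic and PCoA as cross-checks), and
calibrates the stochastic components by simulation: PERMANOVA type-I
error over 500 exchangeable-null datasets (n = 16, 199 permutations;
rejection rate within [0.03, 0.07]), NB Wald null uniformity over 500
genera, and planted-effect recovery over 50 simulations. Simulation
sizes were chosen as the smallest giving stable Monte-Carlo estimates of
the quantities checked; all are seeded and deterministic.

## Reproducibility

A single master seed drives a full pipeline run. Per-stage integer seeds
are derived as
`SeedSequence([master_seed, stage_index]).generate_state(1)[0] mod 2³¹`
with a fixed stage-index table (generator = 0, PERMANOVA = 1, pairwise
PERMANOVA = 2), and recorded in the output manifest. TSV outputs are
written with a fixed float format and deterministic row/column order, so
two runs with the same master seed are byte-identical; the manifest
carries sha256 checksums of every output.

## Known limitations

- The core criterion is strict presence/absence at 100%/0%: a single
  spurious read in one gap sample removes a genus. On real data, apply
  denoising/decontamination first, or relax via the occupancy map that
  `identify_core` records for every candidate.
- The NB Wald test has no dispersion shrinkage; at very small group
  sizes (< 5) its per-genus dispersion estimates are noisy and p-values
  become anti-conservative.
- HDF5 BIOM input is not supported; export tables to TSV (classic BIOM
  TSV dialect is accepted, including an embedded taxonomy column).
- PCoA reports but does not correct negative eigenvalues.
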