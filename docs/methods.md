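# Methods

This note documents the models, conventions and parameter choices behind
`esckit`, the assumptions they make, and what the bundled synthetic cohort
does and does not emulate.

## Data contracts

All analyses consume the in-memory types of `esckit.io`. Expression values
are assumed already normalized and on a log scale; the package never
re-normalizes. Mutation records carry a closed variant-class vocabulary
(`missense`, `nonsense`, `frameshift`, `splice_site`, `inframe_indel`,
`synonymous`, `other`); MAF-style inputs are mapped through a documented
synonym table (e.g. `Missense_Mutation → missense`, `Silent → synonymous`).
"Non-silent" means every class except `synonymous` and `other`. Copy-number
segments use 1-based inclusive coordinates (a converter to half-open is
provided) and require a per-sample mean ploidy. Readers validate on load
and never silently drop rows.

## Transcriptomic subtyping

**Variable genes.** Genes are ranked by unscaled median absolute deviation
(median |x − median(x)|) across samples; ties break lexicographically by
gene id. The 1.4826 consistency constant is omitted — selection is
rank-based, so only the fixed convention matters. The conventional depth is
the top 1,500 genes.

**Non-negativity.** Log-scale values can be negative; the default transform
subtracts each gene's minimum (`shift`). The alternative convention of
row-stacking positive and negative parts (`posneg`) is available. Optional
per-gene z-scoring before the transform is off by default; both conventions
are supported because neither is canonical for this procedure.

**Consensus NMF.** Each restart runs Lee–Seung multiplicative updates
minimizing the Frobenius reconstruction error, which is non-increasing
under these updates (asserted in the test suite per restart). Defaults:
50 restarts, 2,000 max iterations, relative tolerance 1e-6, mandatory seed.
Non-convergent restarts are kept best-so-far with a warning. Sample labels
per restart are the argmax metagene; the consensus matrix is the mean
connectivity. The cophenetic correlation is the Pearson correlation between
the condensed `1 − consensus` dissimilarities and the cophenetic distances
of their average-linkage dendrogram; when all dissimilarities are equal
(exactly binary consensus) it is defined as 1. The rank *k* stays a user
choice: `cophenetic_profile` prints the rank-stability table and flags the
maximum as a rule of thumb, since a domain override toward finer resolution
is often the right call.

**Markers.** One-vs-rest Welch t-tests on the log-scale values, log2FC =
mean(target) − mean(rest), BH within each comparison, and cutoffs
adj. p < 0.05, log2FC > 1 with per-subtype overrides (a relaxed 0.8 cutoff
is a legitimate override for a subtype with few markers). Welch t replaces
moderated (empirical-Bayes) statistics; the replacement is validated by
planted-marker simulation, not by reproducing any particular cohort's gene
lists.

## Enrichment statistics

- **ORA**: upper-tail hypergeometric `P[X ≥ k]`, sets intersected with the
  universe first; the universe defaults to all genes in the filtered
  expression matrix (an explicit background beats an opaque internal one).
  BH across all sets tested in one call.
- **BH**: statsmodels step-up, order-preserving. Note BH is *not*
  idempotent in general — re-adjusting adjusted values can only move them
  up; the test suite asserts exactly this weaker property.
- **Pre-ranked GSEA**: weighted running-sum ES (weight p = 1 by default),
  gene-label permutation null (1,000 draws), NES = ES / mean |null ES| of
  matching sign, FDR q pooled per sign by default (`pooled` exposed as a
  flag, since the pooling variant is a genuine degree of freedom).
  Ranking ties break stably by gene id.
- **Single-sample pathway score**: each gene z-scored across samples
  (population sd, ddof = 0; zero-variance genes score 0 with a warning),
  pathway score = mean z of member genes present. This is a deliberately
  transparent single-sample activity score; it is not GSVA and is validated
  for sign/ordering behaviour on synthetic data, not value equality with
  kernel-based scores.

## Immune profiling

Cell abundance is the arithmetic mean of marker-gene expression per cell
type (marker-mean estimation); bundled signatures cover 13 cell types with
a provenance note in the data file. The four-part benchmark computes (1)
estimate–purity correlations (negative expected: more tumour means less
immune tissue), (2) estimate–copy-number correlations at each marker locus
(non-significant expected; the gene's segment is matched by midpoint,
length-weighted mean across segments), (3) cross-method concordance per
cell type, (4) estimate–IHC-count correlations. Pearson is reported by
default and Spearman is available, since the appropriate correlation is a
judgement call. A method summary (count of negative purity correlations,
count of CN confounds, mean IHC r) supports best-method ranking.

Immune subtypes come from resampled consensus clustering: 50 resamples of
80% of samples (the common default for the resampling fraction),
agglomerative average linkage on 1 − Pearson distance, consensus =
co-clustering frequency normalized by co-sampling frequency, final cut at
*k* with per-cluster consensus values to guide the choice of *k*.

## Pathway functional-mutation enrichment

`score(s, g) = (F_sg / N_g) / max(T_s, 1)`: per-gene-set density of
non-silent mutations, normalized per mutation of total burden. Design
choices: division by burden (transparent and scale-invariant) rather than
regression residualization; multiple mutations in one gene each count;
*T_s* counts non-silent mutations by default with a flag to count all
records; the adjustment is pluggable and logged. Per-set Kruskal–Wallis
compares scores across subtypes, and per-set score–purity correlations are
reported alongside. Deleteriousness (e.g. SIFT/PolyPhen-style calls) is
consumed as an optional annotation column, never computed.

## Copy-number event classes

`log2_ratio = log2(copy_value / mean_ploidy)`; amplification at ratio ≥ 1,
deletion at ≤ −1, gain at > log2(1.25), loss at < log2(0.75), else neutral.
Boundary ownership follows the comparison symbols exactly and is covered by
explicit boundary tests.

## Intratumour heterogeneity

VAF bins are `[0, 0.1), [0.1, 0.2), …, [0.9, 1.0]` — half-open with a
closed top, a convention fixed here because "0–10%, 10–20%" leaves boundary
ownership open. H′ uses natural log (nats), so the 10-bin maximum is
ln 10 ≈ 2.3026. All mutation classes with usable allele counts enter by
default (`non_silent_only` restricts). Records with zero depth are excluded
and tallied; a sample with zero usable records is an error (H′ undefined),
distinct from the advisory path. Caveat: H′ depends on the number of
mutations; samples are not rarefied to equal counts, and raw VAFs are
binned without purity scaling (a purity-scaling option exists but no
equivalence is claimed).

## Histology meta-features

Tiles with background fraction strictly above 0.20 are removed; 50 tiles
per slide are then sampled without replacement (slides with fewer pass all,
with a warning — dropping them would waste patients). The discovery/test
split is at the patient level (65%/35% of tiles): one random patient per
group is seeded into each half, the remainder fills discovery greedily to
the tile target; the split is re-drawn up to a retry limit if a group is
missing from either half, and a group with a single patient is an error.
Selection: Mann–Whitney U per (group, feature) pair, BH across **all**
pairs jointly (a per-group adjustment is a different, wrong family — a test
asserts the difference on constructed input), candidates must be
significant at FDR < 0.01, higher in the target group by mean ("higher" by
median is a flag), and significant-and-higher in exactly one group. The top
five rank by smallest adjusted p (largest standardized effect as an
option), ties by |effect| then feature name — fully specified so the
selection is deterministic. The meta-feature is the plain sum of the
selected features; validation re-tests both the meta-feature and the
per-feature directions on the held-out half and reports concordance.

## Survival

KM estimation and Cox fitting delegate to lifelines (Efron tie handling;
categorical covariates dummy-encoded, first level dropped; rank-deficient
or constant designs rejected before fitting). The standardized two-sample
log-rank statistic `U/√V` is implemented in-package and cross-checked
against lifelines. The optimal cutpoint scans unique values subject to a
minimum group proportion (default 0.10) and maximizes the absolute
standardized log-rank statistic, ties toward the lower threshold. The
p-value at the selected cutpoint is reported as **exploratory only**: the
selection maximizes the statistic, so the naive p is anti-conservative, and
the selection-bias-adjusted p of maximally selected statistics is
deliberately not implemented.

## The synthetic cohort

The generator (`esckit.simulate`) plants exactly the structure each stage
looks for, with ground truth emitted alongside so recovery tests never
re-derive it. All randomness flows through seeded PCG64 streams (one named
stream per layer), so output is bit-reproducible.

Defaults describe a ~120-tumour cohort: 30 samples per subtype, 2,000
genes with 50 markers per subtype (log-scale shift 2.0 over N(0, 1) noise);
negative-binomial non-silent burden with mean 150 (dispersion 3); variant
classes from a fixed multinomial (~72% non-silent); VAFs from a
clonal/subclonal beta mixture (means 0.45/0.18, weights 0.6/0.4) realized
as binomial counts at Poisson depth 80; 91 slides (one per patient) with 80
raw tiles each and 20% of tiles above the background-QC threshold; 300 tile
features with 5 planted per group (shift 3 sd); exponential survival with
per-subtype log-hazards and an ITH log-hazard of 0.3 under exponential
censoring.

The immune layer draws cell-type fractions from a symmetric Dirichlet and
purity from Beta(8, 3) (mean 0.73, sd 0.13 — typical tumour cellularity);
a marker's expression is `20 · fraction · (1 − 0.8 · purity) + N(0, 0.15)`.
The partial confounding weight (0.8) is a design point: full multiplication
by (1 − purity) caps rank-recovery of 13 Dirichlet fractions at n = 120
below a usable level, while weight 0.8 keeps purity correlations provably
negative *and* planted fractions recoverable (Spearman ≥ 0.8 per cell
type). Recovery tests and the benchmark's sign expectations both rest on
this construction.

What the generator does **not** emulate: gene–gene correlation beyond the
block markers, linkage or copy-number/expression coupling, realistic
mutational signatures, spatial tile structure, informative censoring, or
batch effects. Passing tests therefore demonstrate the statistics recover
the structures they target under clean planted conditions — not that any
particular real cohort will show those structures.

## Problem sizes used by the checks

The verification suite uses scaled cohorts chosen to exercise each property
at well-powered but economical sizes: subtype recovery on 40 samples ×
2,000 genes at a 4-sd marker effect (top 1,500 by MAD, 20 restarts); null
calibration of the pathway Kruskal–Wallis test over 500 independent
cohorts of 40 samples (5 pathways × 30 genes over a 300-gene background,
burden mean 150) with a Kolmogorov–Smirnov uniformity check; power over
200 such cohorts with a 5× planted factor; meta-feature recovery on 50
slides × 50 sampled tiles × 300 features; hazard-ratio recovery as the
mean Cox estimate over 50 cohorts of n = 300; cutpoint recovery over 20
cohorts of n = 200 with a hazard step (HR 3) at value 5 on a 0–10 scale,
"recovered" meaning the selected threshold lands within 1.5 units of the
step — the sampling spread of the maximally selected statistic at this n
and effect size, not a tolerance on the arithmetic.

## Known limitations

- The NMF consensus is O(restarts × iterations × genes × samples); very
  large cohorts should reduce restarts or genes first.
- The mean-z single-sample score is sensitive to cohort composition (z
  across samples), like any cohort-referenced activity score.
- The cutpoint p-value is exploratory (see above); report it as such.
- Marker-mean immune estimates are relative within a cohort, not absolute
  fractions, and shared markers across cell types are flagged but not
  deconvolved.
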