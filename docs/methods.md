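# Methods

This note documents the models and procedures the package implements, the
assumptions behind them, the synthetic-data generators used to exercise
them, and the numerical choices that were genuinely open.

## Signature registry

The registry holds 20 named gene signatures in three tiers.

**Clinico-pathological signatures** (GGO/lepidic, solid/micropapillary,
metastasis) are derived by two-group differential expression on log2-scale
matrices. The default test is Welch's t per gene (a moderated linear-model
test is a reasonable alternative; at the effect sizes these signatures are
built from, the threshold pair — log2FC ≥ 1 and p < 0.05 — determines the
gene list, not the test family). The GGO/lepidic and metastasis signatures
filter on raw p, the solid/micropapillary signature on BH-adjusted p; both
switches are exposed (`use_adjusted`). An exclusion list (e.g. histone
genes unrelated to progression) is removed after thresholding; genes are
ordered by descending log2FC with lexicographic tie-breaking so a registry
build is bit-reproducible.

**Voted TME signatures.** A gene enters a cell-type signature when its
vote count over a source pool meets an inclusive boundary: ≥4 of the 9
deconvolution/single-cell sources for the nine major cell types, ≥2
publications for T helper cells, M1 macrophages and dendritic cells, a
single source for myeloid cells, tumor proliferation rate, matrix
remodeling and angiogenesis, and a fractional rule (count / pool size
≥ 1/5, evaluated as an exact fraction, so 17 of 84 papers qualifies and 16
does not) for EMT. Sources that do not define a cell type abstain; they
still count in the fractional denominator, which is the conservative
reading. Per-gene provenance (which sources voted) is retained.

**Single-cell support.** Marker nomination from single-cell data uses the
QC cascade: genes expressed in ≥3 cells; cells expressing ≥200 genes;
cells with ≤5% mitochondrial counts; cells with detected-gene count
strictly below 2500. The order (gene → cell → mito → upper) is fixed; the
steps are near-commutative on realistic data but the fixed order makes the
removed-per-step report well-defined. "n_genes_by_counts < 2500 were
filtered" is ambiguous in the upstream description; cells strictly below
2500 are *retained* here, matching standard doublet-guard practice.

## Single-sample enrichment (ssGSEA)

For a sample's expression column, genes are ranked (average ranks for
ties; higher expression → higher rank N), the ranked list is walked from
top to bottom, and the score is

    ES(S) = Σ_{i=1..N} [ P_in(i) − P_out(i) ],
    P_in(i) = Σ_{j≤i, g_j∈S} |r_j|^α / Σ_{g∈S} |r|^α,
    P_out(i) = #{j≤i, g_j∉S} / (N − |S|),

with α = 0.25. Scores are rank-based, hence invariant to any strictly
monotone transform of the column, and monotone in each in-set gene's
expression. Ties are interleaved deterministically by gene symbol; tied
genes carry equal averaged ranks, so this affects only the interleaving
term, not the weights. Set members absent from the matrix are dropped
(empty intersections score NaN with a warning); missing expression values
fail fast rather than being imputed. Optional normalization divides the
whole score matrix by its global range; clustering uses per-feature
z-scores (population SD; constant features become zero with a warning).

## Consensus clustering and subtype labeling

Clustering runs PAM (k-medoids) on Euclidean distances between z-scored
feature profiles. The k-medoids implementation uses k-medoids++ seeding
from the run's seeded random stream followed by alternating (Voronoi)
assignment/medoid updates to a fixed point — the variant sklearn-extra
calls `method="alternate"` — which is orders of magnitude faster than full
swap-search PAM and equally reliable on 20-feature profiles. Each of
`reps` repetitions subsamples ⌊0.8·n⌋ samples (and optionally features);
consensus(i, j) = co-clustered count / co-sampled count. Final per-k
labels come from PAM on (1 − consensus) as a distance, keeping one
clustering family throughout.

**Choosing k.** The area under the consensus CDF is computed exactly as
A_k = 1 − mean(off-diagonal entries) (the integral of a CDF on [0, 1]).
delta(2) = A_2 and delta(k) = (A_k − A_{k−1})/A_{k−1} for k ≥ 3. The
baseline rule keeps the largest k with delta ≥ 0.1. One refinement: the
CDF area grows whenever clusters fragment, whether the fragmentation is
stable or not, so on sharply separated data the delta alone over-counts
forced splits. When any delta-eligible k has an essentially unambiguous
consensus matrix (PAC — the fraction of off-diagonal entries in
(0.1, 0.9) — at most 0.05), the largest such k is preferred. On realistic
cohorts no k reaches that crispness and the plain delta rule applies. The
number of subtypes is ultimately a judgment call, so `override` pins k
explicitly.

**Labeling.** At k = 4, per-cluster mean z-scores are reduced to three
axes: aggression (solid/micropapillary, metastasis, tumor proliferation,
matrix remodeling), indolence (GGO/lepidic) and immunity (CD8 T, NK,
B cells). HPI is the aggression argmax; LPI the indolence argmax among the
rest; of the final two, IME has the higher immunity. Exact ties raise an
error demanding a manual map — they indicate the clustering did not
produce four biologically distinct groups.

**External cohorts** are scored on the same registry, z-scaled, and
assigned to the nearest training centroid by Spearman correlation
(Euclidean optional), with the winner-minus-runner-up margin reported.
Ties resolve in the fixed order LPI < IMD < IME < HPI with a warning.

## Genomic layer

**Hotspot engine.** Rules are codon rules (gene, position, reference AA,
optional alternate AA, optional exon), exon-class rules (gene, exon,
variant class) and fusion rules (gene, either partner). The default set is
the NCCN v5.2022 LUAD list. Protein changes are parsed only as
single-letter `p.<ref><pos><alt>` short forms; anything else is skipped
with a warning, never silently matched. ERBB2 "exon 20" is matched as
in-frame insertions; MET appears as a fusion partner only (exon-14
skipping is deliberately not added). A sample is positive iff at least one
rule matches; matched-rule provenance is returned.

**Association testing.** The two-sided Fisher p sums, over the
hypergeometric support with fixed margins, the probabilities of all tables
at most as probable as the observed one (relative slack 1 + 1e-7 against
floating-point ties — the standard guard). This is implemented directly on
`scipy.stats.hypergeom` pmf vectors because all-pairs scans need it to be
fast; it agrees with exact integer enumeration to < 1e-12 on every table
with n ≤ 40. Odds ratios are the raw cross-product ratio with ∞ and 0
representable (no Haldane correction). Direction (co-occurrent /
exclusive) is called from the odds ratio at p < 0.05; constant events are
reported as `none` with a note. BH adjustment runs across all tested
pairs; raw and adjusted p are always both reported.

**SV taxonomy.** DEL/DUP/INV are binned by size into [0, 10 Kb),
[10 Kb, 100 Kb), [100 Kb, 1 Mb), [1 Mb, 10 Mb), [10 Mb, ∞) — sub-1 Kb
events fold into the smallest bin so catalogs conserve counts — and TRA is
unbinned, giving (3 × 5 + 1) × 2 = 32 categories with the clustered split.
The clustered rule is adaptive per sample: τ = (mean same-chromosome
inter-breakpoint gap, pooled over chromosomes) / 10, and a record is
clustered iff any of its breakpoints lies within τ of a breakpoint of a
*different* record on the same chromosome (a record's own two breakpoints
never cluster it; isolated records are non-clustered). The /10 factor is a
package choice (`factor` parameter): the upstream tooling's exact rule is
not public, and generator and classifier must share one rule for
round-trip testing.

**NMF signature extraction.** KL-objective NMF by multiplicative updates,
with the generalized KL divergence checked non-increasing every iteration.
For each candidate rank, replicate runs from random starts are pooled; the
replicate signature vectors are clustered by k-medoids on cosine distance
and the mean silhouette is the rank's stability, while reconstruction is
the best run's mean per-sample cosine distance. The chosen rank is the
largest that is both stable (≥ 0.8) and worth its extra signature (it must
reduce the mean cosine distance by ≥ 2% of the rank-1 distance). The
improvement gate exists because stability alone over-selects: a consistent
split of a true signature stays stable while buying almost no
reconstruction. Signatures are column-normalized; exposures absorb the
scale. Refitting a catalog onto known signatures is plain NNLS
(`scipy.optimize.nnls`), with the residual norm reported.

## Survival analysis

KM estimation and log-rank tests wrap lifelines (Greenwood variance is
computed from the event table; censors at an event time count in the
at-risk set). The Cox model is an in-package Newton maximization of the
Breslow partial likelihood, run to gradient norm < 1e-8 with step-halving,
because (a) the tie convention should be explicit and (b) Breslow keeps
the classical identity between the single-binary-covariate score test and
the two-group log-rank statistic, which the tests verify numerically.
Zero-variance covariates are rejected; coefficients exceeding 20 in
absolute value flag monotone likelihood (complete separation). Lifelines'
Cox fit (Efron ties) is used as an independent oracle on tie-free data,
where the two conventions coincide.

The hotspot-cohort filter drops pre/minimally invasive cases (AAH, AIS,
MIA) and relapse-free pathological stage I patients without adjuvant
therapy; everything else is retained. Median splits put strictly-above-
median samples in "high" (ties at the median go low) and reject constant
vectors. `compare_groups` bundles per-endpoint KM curves, the k-group
log-rank test and a Cox fit on group dummies against an explicit
reference.

## Synthetic cohorts: what they emulate, and what they do not

All generators are pure functions of (config, seed); per-table substreams
come from fixed spawn keys of one master seed, so adding a table never
perturbs another.

* **Expression** is generated directly on the log2 scale: signature genes
  of feature f are Gaussian around baseline + effect_size ×
  profile.feature_means[f] for the sample's subtype (background genes at
  baseline), SD = noise_sd. Defaults: n = 400 samples, 2000 genes, 10
  genes/signature, effect size 1.5 SD, equal subtype proportions — strong,
  clean profiles under which consensus clustering recovers k = 4 reliably.
  The default subtype profiles encode the intended phenotypes: LPI high
  GGO/lepidic and low proliferation with mildly active immunity; IMD an
  immune desert; IME high CD8 T/NK/B; HPI high solid/micropapillary,
  metastasis, proliferation, matrix remodeling.
* **Survival** times are exponential with rate base_rate × subtype hazard
  multiplier (defaults 0.4 / 0.8 / 1.2 / 2.5 for OS from LPI to HPI) and
  independent exponential censoring whose single global rate is set to hit
  the target censored fraction at the mean hazard. censor_rate 1 returns
  all-censored data by construction.
* **Alterations** are Bernoulli at baseline rates (defaults 5–20%,
  configurable — recurrent-event frequencies in this range are typical);
  a planted co-occurring pair has its 2×2 joint law solved in closed form
  (Plackett) for the stated odds multiplier with marginals held fixed, so
  frequencies stay interpretable. Hotspot-positive samples (default rate
  0.7, near the ~72% observed in resected East-Asian LUAD) draw one
  variant uniformly from the rule list with well-formed fields.
* **SVs**: per-sample category counts are Poisson(signatures × exposures).
  Breakpoints are placed to respect the classifier's own adaptive rule:
  non-clustered breakpoints on an even per-chromosome grid with mild
  jitter (gaps ≈ the chromosome mean ≫ τ), clustered events in tight
  multi-event clusters (1 Kb spacing), two clusters per chromosome
  separated by a wide gap so τ stays well above the intra-cluster spacing.
  Limitation: in the > 10 Mb size bins at high per-sample counts, events
  are comparable to chromosome lengths and cannot all be placed without
  interacting, so round-trip category purity there is ~0.7–0.85 rather
  than ~1.0; round-trip tests use small/medium bins. Real SV position
  statistics (fragile sites, replication timing) are not modeled.
* **Single cell**: negative-binomial counts (dispersion 2), markers
  over-expressed 8-fold in their own type, and controllable fractions of
  QC failures: library-collapsed cells (detected genes < 200) and
  high-mito cells (fraction ≫ 5%).

Passing tests on these cohorts demonstrates that the machinery recovers
exactly the structure it assumes — planted mean shifts, exponential
hazards, odds-multiplied 2×2 laws, Poisson catalogs. They do not
demonstrate robustness to batch effects, non-Gaussian expression noise,
subtype imbalance, informative censoring, or mutational processes that
violate the signature model; conclusions about real cohorts need the real
data.

## Problem sizes and numerical choices

* Consensus tests and recovery rates run at reps = 200 (production default
  1000), 20 replicate cohorts; NMF rank search over 1–6 with 8 replicates
  in tests (API default 1–30, 20 replicates). These sizes keep the full
  suite within a couple of minutes while leaving the recovery criteria
  comfortably met.
* NMF runs 400 multiplicative updates (relative tolerance 1e-6) per
  replicate; the rank-selection thresholds are stability ≥ 0.8 and
  improvement ≥ 2% of the rank-1 cosine distance.
* Cox Newton: gradient norm < 1e-8, max 50 iterations, step-halving;
  covariates are centered internally for exp() stability (coefficients are
  unaffected).
* Fisher two-sided tie slack: 1 + 1e-7 relative, matching common practice;
  verified against exact integer enumeration.
* Degenerate inputs: zero-variance genes with equal means get p = 1 (not
  NaN); constant features z-scale to zero with a warning; empty QC results
  and empty derived signatures are returned (with a warning), not raised;
  constant events and events absent from both groups are reported with
  notes rather than dropped silently.
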