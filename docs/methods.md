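# Methods

## Scope and data model

The pipeline operates on a gene-by-sample abundance matrix on a log-like
scale with a per-sample group design (one healthy control group, one
disease-model group, optional drug-treatment groups), a gene-set collection
(GMT), a scored regulator→target interaction table labelled by regulator
class (ncRNA or TF), and a scored undirected PPI edge list. No
normalization is performed: inputs are taken as already normalized, and
genes with missing values are dropped (and counted in the log) rather than
imputed, because the correlation stage requires complete rows.

Score filters honour the conventions of the source databases: interaction
tables are filtered inclusively (`score >= 0.5` on a 0–1 scale keeps the
boundary), PPI edges strictly (`score > 950` on a 0–1000 scale drops it).
Both thresholds apply on the file's native scale and are configurable.

## Co-expression modules

Pearson correlation → soft-thresholded adjacency → topological overlap →
average-linkage clustering of `1 − TOM` → static cut → size filters.

* **Network signedness.** Unsigned by default (`a = |r|^β`); the signed
  transform `((1+r)/2)^β` is available by flag. Unsigned adjacency is
  invariant to flipping the sign of any single gene profile.
* **Soft power.** The scale-free topology criterion (smallest power whose
  signed fit R² of the binned log–log connectivity distribution reaches
  0.85 over candidates 1–20; sign negated when the regression slope is
  positive) is implemented and reported in the soft-threshold scan, but it
  is *not* the default selector. With few samples the correlation noise
  floor is high and block-structured data are not scale-free at low
  powers; the criterion then drifts to degenerate powers (≥ 13) where all
  adjacencies are near zero and downstream clustering destabilizes — on
  the reference synthetic study it cut planted-module recovery from an
  adjusted Rand index of ~0.94 to ~0.61 on average. The default power
  instead follows the widely used sample-size table for unsigned networks
  (10, 9, 8, 6 for < 20, < 30, < 40, ≥ 40 samples; doubled for signed),
  selectable explicitly via `power="scalefree"` or any fixed integer.
* **Tree cut.** `cut_height` is a fraction (default 0.95) of the
  merge-height range, i.e. the tree is cut at
  `h_min + 0.95 (h_max − h_min)` — the static-cut convention of the
  standard tree-cutting tools. Interpreting the cut relative to the
  realized height range keeps it meaningful whatever absolute TOM scale
  the chosen power produces; an absolute cut at 0.99 of `1 − TOM` is only
  appropriate for one narrow band of powers. Clusters below
  `min_module_size` (default 30) become `unassigned`.
* **Labels and size screen.** Surviving modules are labelled `M1, M2, …`
  in decreasing size order, ties broken by the lexicographically smallest
  member gene; colors are presentation, not identity. Modules with ≥
  `max_module_size` genes (default 500) are screened out as
  non-specific aggregates and their genes relabelled `unassigned` — the
  reading of "modules below 500 genes are retained" consistent with a
  22 → 21 module screen; the bound is configurable.
* The dynamic hybrid tree cut, module eigengenes and eigengene-based
  module merging are deliberately out of scope: no downstream stage needs
  them.

## Enrichment

Flat over-representation per (module, term) pair with overlap ≥ 1:
exact hypergeometric upper tail `P(X ≥ k)` for `X ~ HG(N, K, n)`, BH
adjustment within each module's family of tested terms, rows kept when
`p ≤ p_cutoff` and `q ≤ q_cutoff` (defaults 0.01/0.01, GO-style; KEGG-style
runs use 0.05/0.2). The universe defaults to the partition's genes
(assigned plus unassigned) intersected with the collection's annotated
genes — the dominant convention of ORA tools — and can be set explicitly.
Term sizes are measured inside the universe and bounded to [10, 500] by
default. "q" means BH FDR, not Storey's q. Gene sets are flat: no
ontology-graph propagation is performed. A cross-module summary counts,
per term, the number of distinct modules in which it survives.

## Pivot analysis

For each regulator class separately, the background `N` is the set of
distinct target genes of that class present in the loaded table — the
database's target space, not the genome — because the interaction database
itself is the sampling frame for a regulator's targets. For regulator
targets `T` and module overlap `M` (both inside the background), `k = |T ∩
M|` is tested with the same exact hypergeometric tail; rows need `k ≥ 2`
("at least two interacting pairs") and raw `p < 0.01`. No multiplicity
correction is applied by default, matching the original procedure's raw
threshold; BH across the class scan is available behind `adjust=True`.
Self-targeting pairs are dropped. Core regulators are ranked by the number
of distinct modules driven, ties by ID.

## Differential expression and drug reversal

Contrasts are fixed as (model vs healthy) for disease and (treated vs
model) per drug; `log2FC = mean(a) − mean(b)` on the stored (log-like)
scale. The default test is a moderated t: per-feature residual variance is
taken from the one-way fit over all study groups (df = N − G) and shrunk
toward a scaled-F prior fitted across features by method of moments on
`log s²` (digamma/trigamma identities, trigamma inverted by Newton), with
`p` from a t distribution on `df + d0` degrees of freedom. At the small
group sizes these designs use (n ≈ 5), an unmoderated Welch test spends
most of its power estimating 600 variances on ~4 degrees of freedom each;
sharing variance information across features is the standard remedy and
raised joint two-contrast recovery of planted reversed genes from ~0.78 to
~0.96 without inflating the null (zero false calls at defaults in a
no-effect simulation). Plain `student` and `welch` tests remain available.
Features constant in both groups at equal means receive `p = 1` by
convention. Calls combine `q ≤ 0.05` with `|log2FC| ≥ 1`.

Reversal: `inhibited = up(disease) ∩ down(treatment)`, `promoted =
down(disease) ∩ up(treatment)`. The two sets are disjoint by construction
(a feature has one direction per contrast) and their sizes always sum to
the drug's total target count. Targets are then located in the module
partition (`unassigned` never counts as a hit) and intersected with the
reported pivot regulators. Proteome tables run through the identical
machinery; upstream acquisition-specific statistics are not reproduced.

## PPI stage

Edges above the strict score threshold, optionally restricted to a node
subset (e.g. a drug's differential proteins) with subset isolates retained
at degree 0. Hubs are ranked by degree (ties by ID); "network clusters"
are connected components of size ≥ 3 — the minimal reading absent any
named clustering algorithm; density-based clustering is out of scope.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
any particular biology (no strain effects, no mass-spec error model, no
real regulator names):

* **Modules** are latent-factor blocks: `x = baseline + λ f_m + ε`,
  `f_m ~ N(0,1)` per sample, `ε ~ N(0, σ)`, with
  `λ = σ √(r/(1−r))` so the expected within-module correlation is exactly
  `r` (default 0.7; σ = 0.5; baseline 8 on the log2-like scale). Factor
  blocks scale to thousands of genes without dense covariance factorization.
  Defaults: 600 genes, five 100-gene modules, 100 background genes,
  4 groups × 5 samples. `module_size` may list one size per module (used to
  plant an oversized 600-gene block for the size-screen check).
* **Disease and reversal.** 50 disease genes (half up, half down,
  ±2 log2 units) shifted in every non-control group; per drug group, a
  60% fraction of them has the shift cancelled exactly — the simplest
  structure making "up in disease, down after drug" well defined. Disease
  genes are drawn from the background pool by default
  (`disease_in_module_fraction = 0`): planting them inside factor modules
  would add factor variance to their per-gene noise (total sd ≈ 0.91
  instead of the configured 0.5 at r = 0.7), so recovery rates would
  measure module correlation rather than the differential test.
* **Regulators.** Planted regulators (alternating ncRNA/TF) are assigned
  to modules round-robin and draw 80% of their 20 targets from their
  module, the rest uniformly; optional null regulators draw uniformly.
  Scores are drawn at or above the 0.5 filter so default loading keeps all
  rows.
* **PPI.** Erdős–Rényi background at mean degree 4 over 200 nodes with 5
  hubs each wired to 50 random partners; scores above the strict 950
  threshold.
* **Gene sets.** One term per planted module (module genes plus 20 random
  background genes) plus 20 random null terms of size 10–50.

All generators are pure functions of `(config, seed)` via independent
numpy `SeedSequence` streams; ground truth (module membership, disease and
reversed gene sets, regulator assignments, hubs) is returned for scoring.
What passing tests on these fixtures do *not* show: robustness to
heteroscedastic noise, correlated module factors, batch effects, count
overdispersion, or annotation incompleteness — real-data behaviour beyond
the planted model is out of scope.

## Numerical and engineering choices

* Exact hypergeometric tails via the survival function of
  `scipy.stats.hypergeom`; validated against integer-combinatorics
  enumeration for every parameter combination with N ≤ 25 (max abs error
  ~3e-16).
* TOM computed vectorized; validated against explicit triple loops to
  1e-10. Symmetry is enforced by averaging; values clipped to [0, 1];
  unit diagonal by convention.
* Average linkage via `scipy.cluster.hierarchy` on the condensed
  dissimilarity; merge heights validated against a naive agglomerative
  reference.
* BH via `statsmodels.multipletests("fdr_bh")`, validated against a
  literal quadratic-time step-up.
* All output tables are written with sorted rows, fixed float formatting,
  UTF-8 and `\n` endings; the pipeline manifest stores a SHA-256 per data
  file, and a rerun under the same config and inputs is byte-identical.
  The run log is excluded from the manifest because it carries wall-clock
  timings.
* Degenerate inputs: zero-variance genes are a hard error before
  correlation (they have no defined correlation); an all-equal
  connectivity vector is a hard error in the scale-free fit; empty
  universes, disjoint backgrounds and impossible hypergeometric counts
  raise immediately with a named cause.

## Problem sizes

The reference study used throughout tests and the acceptance script is
600 genes × 20 samples (with a 900-gene variant for the size screen and a
200-regulator null panel for calibration) — large enough that every
planted-structure statistic is stable across seeds, small enough that the
whole suite and the acceptance script each complete in well under a
minute on one CPU.

## Known limitations

* The static relative-height cut handles well-separated planted modules;
  deeply nested real dendrograms are better served by dynamic tree cutting,
  which is deliberately not implemented.
* The moderated test assumes exchangeable variances across features after
  shrinkage; strong mean–variance trends (counts) would need a trend fit.
* Pivot analysis treats the interaction table as a fixed background; it
  does not model database ascertainment bias.
* GO term relationships are ignored (flat sets); parent-term enrichment
  driven by child overlap is not deduplicated.
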