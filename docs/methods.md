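# Methods

This note documents the statistical procedures `ploidysig` implements, the
choices made where the design was genuinely open, and what the synthetic
generator does and does not emulate.

## The reciprocal cross-species design

Polyploidy's transcriptional effect is weak (most genes are dosage
compensated), so a single polyploid-vs-diploid comparison is dominated by
tissue- and species-specific expression. The design exploits the fact that in
human the heart is polyploid and the liver diploid, while in mouse the roles
are reversed. Writing a gene's log2 expression as

    x = μ_g + τ_g·T + σ_g·S + δ_g·P + ε,

with ±1 codings T (tissue), S (species), P (ploidy class), the heart
comparison (human − mouse) estimates 2(δ_g + σ_g) and the liver comparison
(mouse − human) estimates 2(δ_g − σ_g): the tissue term cancels exactly within
each comparison and the species term enters the two comparisons with opposite
signs. Requiring the same significant direction in both therefore cancels
species effects in expectation and rejects genes whose apparent change is
species-driven. This is also why the concordance intersection is much cleaner
than either comparison alone, and why sensitivity degrades when the per-gene
species spread approaches the planted ploidy effect (see generator defaults).

## Differential expression

- **Quantile normalization** maps each sample's order statistics onto their
  across-sample mean; ties receive the mean of the reference values at the
  tied ranks, so ties remain ties. It is applied to the full matrix of a
  dataset before any contrast.
- **Moderated t.** Pooled two-group variances s²_g (d_g df) are modeled as
  s²_g ~ s₀²·F(d_g, d₀). Taking logs, E and Var are available in closed form
  through digamma/trigamma, so (d₀, s₀²) follow from moment matching; d₀
  solves trigamma(d₀/2) = excess dispersion by Newton iteration. Excess
  dispersion ≤ 0 yields d₀ = ∞ (pure prior; the test becomes a z-statistic
  with SD s₀). Degenerate corner: when all variances are literally equal there
  is no chi-square sampling signature to correct for, and the common value is
  returned as s₀² directly. d₀ ≥ 1e8 is treated as infinite.
- **Posterior variance** s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g); t = Δ/(s̃·√(1/n₁+1/n₂))
  on d₀ + d_g df. p-values are two-sided and clipped into (0, 1].
- **Change filter**: linear ratio ≥ 1.15 (up) or ≤ 1/1.15 (down), boundary
  inclusive; the reciprocal form keeps the filter symmetric in direction.
  The 15% threshold targets the small amplitudes typical of transcriptional
  regulators; it is configurable.
- **Gene-list gates**: membership requires the change filter *and* p < 0.01
  per comparison by default. Because published procedures sometimes apply the
  fold filter alone, `require_p=False` disables the significance gate; the
  gated mode is the default.
- **Tiers**: tier B = concordant heart ∩ liver (ortholog group ids); tier A =
  tier B ∩ the concordant 2n/4n (decidua-like) result mapped through the
  one-to-one ortholog table; tier C = the intra-species 2n/4n result on its
  native gene ids, keeping genes without orthologs (it is an intra-species
  list; mapping happens only where cross-species intersection demands it).

## Ploidy component (correlation PCA)

Variables are condition profiles (replicate means); statistical units are
genes. The correlation matrix (not covariance) is decomposed because the
construction equates loadings with variable–component correlations; this gives
the identities Σ_k loading²_jk = 1 per variable and mean_j loading²_jk =
variance fraction of component k, both enforced to 1e−9 in tests. As many
components as variables are kept — a pure rotation, so standardized profiles
are exactly reconstructible from scores and loadings. Scores are standardized
to zero mean and unit SD per component (rather than carrying eigenvalue
scale), making the ±2/±3 SD selection thresholds meaningful across components.

Labeling uses only the loading sign pattern: all-one-sign = shared (size)
component; otherwise the pattern is compared, up to a global flip (eigenvector
sign is arbitrary), with each factor's ±1 coding; no match = unassigned.
Designs in which two factor codings coincide are rejected as confounded. The
ploidy component is re-oriented so polyploid conditions load negatively —
consequently *low* scores mark genes induced by polyploidy — and other labeled
components are oriented first-variable-positive, preventing seed-dependent
sign flips. Selection thresholds are strict inequalities.

Pearson kurtosis m₄/m₂² (Gaussian reference 3) and the 99th percentile of
|score| diagnose whether a small component is noise or signal: a sparse
planted effect concentrates the component's variance in few outliers, pushing
kurtosis far above 3 while the bulk 99% percentile stays *below* the Gaussian
2.58.

## Enrichment statistics

- **Binomial**: exact one-sided upper tail P(X ≥ k | n, p₀), delegated to the
  regularized incomplete beta (verified in tests against exhaustive summation
  for every instance with n ≤ 12, and against exact rational arithmetic at the
  reference contingency). The one-sided exact form is the variant consistent
  with the reference proportions; two-sided and normal-approximation variants
  are materially different in the far tail. p₀ is taken from the supplied
  universe unless explicitly overridden — published analyses often report a
  rounded background proportion, and the override reproduces such values
  exactly. Note that at the reference contingency (k=242, n=828, p₀=0.19) the
  exact tail is 8.519e−13 while the reference prints 7.798e−13; no standard
  test variant reproduces that printed value, and this package reports the
  exact computation.
- **Hypergeometric ORA**: upper tail after intersecting term and selection
  with the background; backgrounds smaller than 2 are rejected.
- **Storey q-values**: π₀ estimated on the λ-grid 0.05…0.95 (step 0.05) with a
  cubic smoothing spline evaluated at the last grid point (the λ→1
  extrapolation); families below 100 tests fall back to the fixed λ = 0.5
  estimator; π₀ clipped into [1/m, 1]. q is the usual step-up minimum of
  π₀·m·p₍ᵢ₎/i, clipped at 1. π₀ may also be forced (π₀ = 1 gives
  Benjamini–Hochberg).
- **Double background**: every term is tested against the ortholog universe
  and the interactant universe; q-values are computed within each background's
  family (not pooled across runs or lists); significance requires p < 0.01 and
  q < 0.15 in both. Terms with identical member sets are united beforehand
  (ids joined with `|`). Ontology rollup is delegated to the input gene-set
  files, which must be pre-rolled-up; the tool does not traverse the GO graph.
- **Group summaries**: geometric mean of q per module group and background;
  q = 0 is floored at 1e−300 with a warning.

## Network clustering

Edges survive strictly above the stringency (default 0.9, following the
"high confidence" convention literally as an open bound). MCL runs on the
dense adjacency with self-loops at each node's maximum incident weight
(standard practice; isolated nodes self-loop at 1), column normalization,
expansion 2, inflation 2 (configurable), pruning at 1e−5 and convergence
tolerance 1e−6. The algorithm is deterministic; overlapping attractor systems
are merged, and nodes claimed by several clusters go to the largest one (ties:
lexicographically smallest attractor). Non-convergence within 200 iterations
returns the current partition flagged with a warning. Clusters cannot span
connected components.

## Synthetic data generator

The generator *is* the study condition for all recovery tests. It emulates:
log2-additive expression with a dominant shared baseline (μ ~ N(8, 2²)),
per-gene tissue and species effects (τ ~ N(0, 1), σ ~ N(0, 0.25²)), a planted
±1.0 log2 ploidy effect on 2.5% + 2.5% of genes, i.i.d. Gaussian noise
(SD 0.5) over 4 replicates per condition, an interactome with background rate
0.19 and odds ratio 4 for planted genes, gene sets of 40 with 5 planted terms
(≥80% planted members), and an interaction graph of two 5-cliques at weight
0.95 plus 200 noise edges on [0.4, 0.9].

Default rationale: the shared > tissue > species > ploidy variance ordering
reproduces the expected component hierarchy, while the species SD must sit
well below the planted effect because the species term enters the two
reciprocal comparisons with opposite signs — with σ-spread comparable to δ the
concordance design (correctly) rejects most planted genes. 0.25 represents
the evolutionary divergence remaining *after* one-to-one ortholog matching of
conserved, expressed genes. The background interactome rate 0.19 matches the
reference decidua background. Replicate counts in the source designs are not
published; 3–4 is typical of bulk transcriptome studies and is the default.

Each artifact (baselines, planted truth, noise, interactome, terms, edges)
draws from its own RNG stream spawned from the master seed, so outputs are
bit-identical under a fixed seed and adding an artifact never perturbs the
others. The planted truth stream is shared between the cross-species and the
two-condition generators so tier-A concordance is exercisable end to end.

Not emulated: count-based (negative-binomial) sequencing noise and library
size effects (the pipeline operates on normalized log values), batch
structure, correlated gene modules outside the planted terms, dosage
compensation gradients, and missing values. Passing recovery tests therefore
demonstrate correctness of the procedure under its own model assumptions, not
performance on raw sequencing data.

## Problem sizes and numerical choices

Recovery runs use 5,000 genes × 4 replicates (cross-species) and 2,000 genes ×
3 replicates (two-condition); the tier-invariant sweep uses 100 datasets of
150 genes; null calibrations use 500 binomial replicates and families of
2,000 p-values. These sizes give stable estimates (binomial SE of a 0.05
rejection rate over 500 replicates ≈ 0.01) while keeping the full suite in a
few seconds. Other numerics: p-values clipped into (0, 1]; d₀ capped at 1e8;
trigamma inversion by Newton with closed-form asymptotic starts; PCA uses
`eigh` on the symmetric correlation matrix with eigenvalues clipped at 0;
zero-variance profiles and confounded designs are errors, not warnings.

## Known limitations

- The eBayes fit assumes a common residual df across genes when estimating
  the prior from a single comparison (true for complete two-group designs).
- The π₀ spline follows the common smoothing-spline recipe but is not a
  bootstrap estimator; for tiny families the fixed-λ fallback is conservative.
- MCL is dense (O(n³) per iteration) — intended for the post-filter graphs of
  at most a few thousand nodes this pipeline produces, not genome-scale
  interactomes.
- The CLI covers the pipeline stages; plotting is intentionally absent
  (tables and exports only).
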