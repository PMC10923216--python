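# Methods

This note documents the statistical procedures implemented in `gillnet`,
the conventions and numerical choices behind them, what the
synthetic-community generator does and does not emulate, and the known
limitations.

## Filtering and normalization

Raw feature × sample counts are filtered in two stages: samples whose
total count falls below `min_sample_total` (default 10,000 — a common
sequencing-depth floor for amplicon surveys) are removed first; features
whose *mean relative activity* across the retained samples falls below
`min_mean_relative` (default 1e-5) are removed second.  Mean relative
activity is the mean of per-sample proportions, so it is defined over the
retained sample set; this motivates the samples-first default order (the
opposite order is available via `order="features_first"`).  Filtering is
idempotent on realistic tables; a pathological table in which removing
sub-1e-5 features pushes a sample just below the depth floor would need a
second pass, which the function deliberately does not do (one pass, stated
semantics).

Relative activity (closure to proportions) is the only normalization
offered.  Rarefaction and model-based normalizations are out of scope.

## Group comparisons

All cross-site univariate comparisons share one routine: Kruskal–Wallis
(tie-corrected, χ² approximation, df = groups − 1) followed by all
pairwise two-sided Wilcoxon rank-sum tests with Benjamini–Hochberg
adjustment.  Rank-sum p-values are exact (full enumeration) when both
groups have ≤ 20 observations and no ties occur, and otherwise use the
normal approximation with continuity and tie correction.  Groups with
fewer than two observations are excluded with a warning.

## Alpha diversity

Shannon entropy uses the natural logarithm — so Pielou evenness
J = H/ln S_obs is dimensionless in [0, 1] and undefined (NaN) for
single-taxon samples.  Chao1 defaults to the bias-corrected estimator
S_obs + F₁(F₁−1)/(2(F₂+1)), which is finite even without doubletons; the
classic F₁²/(2F₂) variant is available via `bias_corrected=False`.  Chao1
requires integer counts and refuses proportions.

Faith's PD follows the *rooted* convention: the branch path connecting the
root to the spanning subtree of the present taxa is included, so a
single-taxon sample has PD equal to its root-to-leaf path length.
Conventions differ between implementations; this one is stated explicitly
and enforced by a branch-enumeration oracle in the tests.

Neighbor joining is the classical Saitou–Nei agglomeration: join the pair
minimizing Q(i,j) = (n−2)d(i,j) − r_i − r_j, branch lengths from the
two-point formulas, distances to the new node by the reduction formula.
Negative branch-length estimates (possible on non-additive inputs) are
clamped to zero with the deficit moved to the sister branch, preserving
path lengths through the join; `clamp_negative=False` disables this.  The
tree is rooted at the final (trifurcating) join; optional midpoint
rooting.  On additive matrices the algorithm reproduces every pairwise
distance to machine precision (verified against the simulator's
path-metric trees).

## Beta diversity

**UniFrac.** For each branch b with length ℓ_b, let p_X(b) be the fraction
of sample X's total count descending b.  Unweighted UniFrac is
Σ ℓ_b·[presence differs] / Σ ℓ_b over branches leading to taxa observed in
either sample.  Weighted raw is Σ ℓ_b·|p_A(b) − p_B(b)|; the normalized
variant divides by Σ ℓ_b·(p_A(b) + p_B(b)), bounding it by 1.  On a star
tree the weighted raw distance reduces to the L1 distance between
relative-abundance vectors.  The implementation vectorizes over a
branch × feature incidence matrix and is checked to 1e-12 against a
per-branch oracle and against scikit-bio.

**PCoA.** Gower double-centering of −½D², symmetric eigendecomposition,
coordinates scaled by √λ for positive eigenvalues.  Weighted UniFrac is
not guaranteed Euclidean, so negative eigenvalues occur; the default
policy reports and drops them, computing proportion explained over the
positive spectrum (Lingoes correction available).

**PERMANOVA.** SS_total = Σ_{i<j} d²/N; within-group SS analogously per
group; pseudo-F = (SS_between/(a−1))/(SS_within/(N−a)).  p-values use the
(1 + #{F_perm ≥ F_obs})/(1 + B) estimator — the attainable floor is
1/(B+1) — under whole-sample label permutation.  The permutation stream is
generated after sorting samples by identifier, making results independent
of input row order for a fixed seed.  Pairwise PERMANOVA runs on each
group pair's submatrix with BH adjustment across pairs.

**betadisper.** Samples are embedded by PCoA keeping both positive and
negative axes; squared distance to the group centroid is the positive-axis
part minus the negative-axis part (the standard reduction for
non-Euclidean dissimilarities), clamped at zero.  Group centroids (not
spatial medians) are used.  A one-way F on the centroid distances is
tested by permuting the distance values' group labels.

**NMDS.** Kruskal stress-1 is minimized by SMACOF: at each iteration,
disparities are the isotonic (pool-adjacent-violators) regression of
configuration distances on the input dissimilarities — ties handled by the
primary approach (stable sort by dissimilarity, then configuration
distance) — followed by a Guttman transform.  The raw stress
Σ(d − d̂)², logged after each isotonic fit, is non-increasing by
construction and is the monotone trace the tests assert on; the reported
stress is Kruskal stress-1 √(Σ(d−d̂)²/Σd²).  The best of `n_starts` seeded
random initializations is returned, centered and rotated to principal
axes.

**envfit.** Per environmental variable (complete cases only): OLS of the
centered variable on the centered ordination axes; R² is the squared
multiple correlation and the direction the unit coefficient vector;
permutation p by shuffling the variable; Bonferroni across the tested
(non-constant) variables.

## Indicator taxa (IndVal)

For taxon t and site g: specificity A = mean relative activity of t in
g divided by the sum over sites of its site-mean activities, and
sensitivity B = fraction of g's samples containing t; IndVal = √(A·B).
Using site *means* rather than sums is the group-size-corrected
convention — material here because the motivating design is strongly
unbalanced (site n from 13 to 63).  Each taxon is assigned the site (or,
optionally, combination of sites) maximizing IndVal, ties resolved toward
the smaller combination then lexicographically; significance comes from
permuting sample-to-site labels and recomputing the maximized statistic,
with the conventional reporting filter IndVal > 0.5 and p < 0.05.  No
correction across taxa is applied by default (matching common practice of
reporting raw permutation p-values); `benjamini_hochberg` can be applied
to the output.  A perfect indicator's p-value reaches the 1/(B+1) floor
only when the chance of a permutation reproducing the exact partition is
negligible; with small balanced groups the tie term is real and the
implementation counts it.

## Co-activity networks

Per site, Spearman ρ (average ranks; p from the t approximation, matching
standard correlation tooling) between all genus pairs across that site's
samples; constant genera are excluded with a warning and at least 4
samples are required.  BH-FDR is applied per site over all defined pairs;
an edge requires |ρ| > 0.4 (strict) *and* adjusted p < 0.05, and carries
the correlation's sign.  Isolated genera remain nodes — they carry
activity even when unconnected.  Topology per node: degree DG;
neighborhood connectivity NC = mean degree of neighbors (NaN for isolated
nodes); closeness centrality CC = reciprocal mean shortest-path length to
the nodes reachable from the node (within-component convention; 0 for
isolated nodes).  Metrics are computed on the full per-site network; the
top-50-by-activity subgraph is an export/visualization filter only.
Cross-site comparisons treat nodes as observations (Kruskal–Wallis +
pairwise Wilcoxon per metric); this follows field practice but is
pseudo-replication — nodes within a network are not independent — so the
p-values characterize the observed networks, not a sampling distribution
over surveys.

## Synthetic communities

Per sample, the latent log-abundance of taxon i at site s is

    x_i = e_s · (μ_i + β·g_s·v_i + ln(fold)·[planted indicator at s] + σ·u_i)

with softmax closure to proportions and a multinomial draw at lognormal
depth.  The ingredients:

- μ_i ~ N(0, base_log_sd): heavy-tailed taxon baselines.  Default 1.2, at
  which the most active taxon holds roughly 5–10% mean relative activity —
  the dominance scale reported for active gill communities.
- g_s: the site's position on a latitude-like composition gradient
  (default evenly spaced in [−1.5, 1.5]); β = `site_effect_size`.
- v_i: gradient loadings modeling congeneric strain turnover — within each
  background genus the loadings are bounded, sign-alternating and
  *abundance-weighted zero-sum*, so sequence-level composition turns over
  along the gradient (mesophile/psychrophile-style replacement) while
  genus-level site means stay flat.  Planted indicator and module taxa do
  not load on the gradient, keeping plants orthogonal to the background.
- u_i: unit-variance deviation; for taxa in a correlation module active at
  the site, u = (±λf + ε)/√(λ²+1) with a shared factor f per module.  The
  module's `target_rho` is the pairwise *Spearman* correlation of latent
  log-abundances; λ is calibrated through ρ_Pearson = 2 sin(πρ_S/6).
  Opposite loading signs plant negative correlations.  Softmax closure
  adds weak spurious correlation between unrelated taxa; scenario sizes
  keep the module mass share small enough that closure stays well below
  the 0.4 edge threshold.
- e_s: per-site evenness factor; values above 1 stretch the log-abundance
  spread, lowering Pielou evenness — the dysbiosis plant.
- Depth: lognormal (default mean log 20,000–30,000, sd 0.3–0.4).  When
  `fraction_low_depth` > 0, exactly that fraction of samples is forced
  under the 10,000 floor (conditioned draws), emulating failed libraries.
- Environment: each variable is offset + scale·(loading·g_s + noise),
  i.e., a site-level signal on the gradient with per-sample noise; fish
  weight/length are drawn so the Fulton condition factor centers on 1.13.
- Indicators: ln(fold_change) added to the target site's mean and presence
  forced in a `prevalence` fraction of the target samples (a zero count
  becomes 1); other sites are left as drawn, so realized sensitivity can
  exceed the nominal prevalence.

Every component draws from its own sub-stream of the single root seed, so
identical configs give byte-identical datasets and adding a component
never perturbs another's draws.

Three presets are documented study conditions: `null` (5 × 10 samples, no
effects — permutation-test calibration), `biogeography` (the unbalanced
design n = 63/24/13/25/15, a diffuse gradient β = 0.45 with σ = 0.5 and
six background strains per genus, twelve planted indicators at fold-change
4 and prevalence 0.9, gradient-loaded environment), and `dysbiosis` (same
design; ten 10-taxon modules of rank-ρ 0.9 — eight shared by the four
healthy sites, two exclusive to the resilient site — module taxa boosted
to be the active guilds, and an evenness factor 1.7 on the planted
dysbiotic site).  `network_recovery_config` is a single-site benchmark
(two 8-taxon modules at rank-ρ 0.7, 30 samples, 240 taxa with 28 strains
per background genus).  Module tightness and coverage in the dysbiosis
preset are set so that even the smallest healthy site (n = 13) retains
FDR-adjusted power to recover module edges — that is what makes "the
dysbiotic site has the sparsest network" a statement about the community
rather than about sample size.

What the generator does *not* emulate: sequencing error and chimeras, PCR
amplification bias, taxonomic misassignment, phylogenetic signal in
abundances (the tree is independent of the abundance model), overdispersed
(non-multinomial) count noise, and real taxon names.  Passing recovery
tests therefore demonstrates statistical correctness of the chain under a
clean compositional model — not robustness to upstream artifacts.

## Fish condition

The Fulton condition factor is K = 100·W/L³ (W in g, fork length L in cm),
the standard allometric form under which a healthy salmonid sits near
K ≈ 1.1.  A variant K = 100·(W/L)³ that appears in some reports is
available behind `cubed_ratio=True`; it is not the conventional quantity
and yields values far from 1 for realistic fish.

## Numerical choices and degenerate inputs

- Permutation p-values: always (1 + count)/(1 + B); seeds are explicit
  arguments and sub-seeds derive from `numpy.random.SeedSequence`.
- Kruskal–Wallis on identical pooled values returns χ² = 0, p = 1.
- Distance matrices are symmetrized and clipped at 0 after validation
  (tolerance 1e-8); UniFrac fills only the upper triangle and mirrors.
- PCoA eigenvalue cutoff: |λ| ≤ max|λ|·1e-12 counts as zero.
- NMDS convergence: relative stress-1 change < 1e-9, max 500 iterations,
  default 20 random starts; non-convergence returns the best configuration
  with a warning.
- IndVal permutation exceedance uses a 1e-15 tolerance so ties count as
  exceedances (conservative).
- Zero-total samples: errors in normalization and UniFrac; PD 0 with a
  warning in Faith's PD; NaN indices in the alpha table.

## Problem sizes used in validation

The test-suite and acceptance-script runs use the generator at the study's
own design scale (140 samples across five unbalanced sites, 140–240 taxa)
for end-to-end checks, 500 replicates for type-I-error calibration
(B = 199 permutations for PERMANOVA, 99 for envfit), 20 replicates for
recovery rates, and 50–100 random instances for oracle-equivalence checks.
These sizes give Monte-Carlo standard errors comfortably inside the
asserted bands while keeping a full validation run around a minute.

## Known limitations

- PERMANOVA is one-way only (site or water type); no multi-factor designs,
  strata, or distance-based RDA.
- The Spearman edge p-values use the t approximation; for very small sites
  (n close to the minimum of 4) an exact permutation p would be more
  accurate.
- Node-level network comparisons inherit the pseudo-replication caveat
  above.
- The NMDS implementation targets the two-axis, few-hundred-sample regime;
  it is O(n² · iterations · starts).
- Chao1 assumes counts are true sequence tallies; it is biased under
  denoising pipelines that remove singletons.
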