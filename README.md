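# gillnet

Statistical analysis of fish gill microbiota from 16S rRNA transcript
(amplicon) surveys: compositional filtering, alpha/beta diversity,
permutation inference, indicator taxa, and per-site co-activity networks
whose topology serves as a dysbiosis signature.

## Who this is for

Microbial ecologists studying host-associated communities sampled across
geographic sites — the motivating setting is gill microbiota of wild
salmonids caught at a handful of Arctic sites with very unbalanced sample
sizes — who want the full analysis chain from a feature (ASV) count table
to site-level biological conclusions, with every statistical step
reproducible, seeded, and testable against planted ground truth.

## What it computes

Given a feature × sample count table, a taxonomy, sample metadata, and a
rooted phylogeny over the features:

- **Filtering** — samples under a total-count floor (default 10,000) and
  features under a mean relative-activity floor (default 1e-5) are removed;
  counts are closed to per-sample proportions ("relative activity").
- **Alpha diversity** — Shannon H (nats), Pielou evenness J = H/ln S,
  bias-corrected Chao1 S + F₁(F₁−1)/(2(F₂+1)), and Faith's phylogenetic
  diversity (rooted convention), with Kruskal–Wallis tests across sites and
  BH-adjusted pairwise Wilcoxon rank-sum comparisons.  A Saitou–Nei
  neighbor-joining builder turns any taxa distance matrix into the
  phylogeny Faith's PD needs.
- **Beta diversity** — unweighted, raw-weighted and normalized-weighted
  UniFrac; PCoA (with negative-eigenvalue reporting); NMDS minimizing
  Kruskal stress-1 by majorization with monotone (PAVA) regression;
  one-way PERMANOVA (pseudo-F on distance sums of squares, whole-sample
  label permutation, p = (1+exceedances)/(1+B)); pairwise PERMANOVA with
  BH adjustment; multivariate dispersion homogeneity (betadisper); and
  environmental vector fitting (envfit) with Bonferroni correction.
- **Indicator taxa** — IndVal = √(A·B) per taxon and site, where
  specificity A uses group *means* (so the unbalanced design does not favor
  large sites) and sensitivity B is within-site prevalence; permutation
  p-values; the conventional IndVal > 0.5 and p < 0.05 reporting filter.
- **Co-activity networks** — per site, Spearman correlations between
  genus-level activities; edges where |ρ| > 0.4 and BH-FDR p < 0.05, signed
  by correlation; node topology as degree (DG), neighborhood connectivity
  (NC) and closeness centrality (CC); cross-site Kruskal–Wallis comparisons
  of node metrics.  A sparse, fragmented network together with low
  evenness is the operational dysbiosis signature.
- **Synthetic communities** — a seeded logistic-normal/multinomial
  generator with planted site gradients, indicator taxa, latent-factor
  correlation modules and environmental covariates, emitting ground truth
  so that every stage above is verifiable without sequence data.

## Worked example

```python
import gillnet as g

# simulate the unbalanced five-site survey with one planted dysbiotic site
ds = g.simulate_communities(g.scenario_presets("dysbiosis", seed=42))
table, report = g.filter_dataset(ds.table)   # 10,000-count & 1e-5 floors
print(f"retained {table.n_features} features x {table.n_samples} samples "
      f"({len(report.removed_samples)} low-depth samples dropped)")

meta = ds.metadata.select(table.sample_ids)
alpha, tests = g.alpha_pipeline(table, ds.tree, meta)
kw = tests["pielou"]
print(f"Pielou evenness Kruskal-Wallis: chi2 = {kw.statistic:.2f}, "
      f"df = {kw.df}, p = {kw.p_value:.3g}")

dm = g.unifrac(table, ds.tree, weighted=True)
res = g.permanova(dm, meta.communities, n_permutations=999, seed=0)
print(f"PERMANOVA: F = {res.pseudo_F:.2f}, R2 = {res.R2:.2f}, p = {res.p_value:.3g}")

genus = g.aggregate_by_rank(g.to_relative_activity(table), ds.taxonomy, "genus")
nets = g.site_networks(genus, meta.communities)
net_tests, summary = g.compare_networks(nets)
print(summary[["n_edges", "negative_edges", "median_DG"]])
print(f"degree Kruskal-Wallis p = {net_tests['DG'].p_value:.3g}")
```

prints

```
retained 140 features x 136 samples (4 low-depth samples dropped)
Pielou evenness Kruskal-Wallis: chi2 = 53.82, df = 4, p = 5.75e-11
PERMANOVA: F = 3.76, R2 = 0.10, p = 0.001
       n_edges  negative_edges  median_DG
site
site1      513              68        9.0
site2        2               0        0.0
site3      203              14        3.0
site4      376              19        9.0
site5      295              24        6.0
degree Kruskal-Wallis p = 3.29e-56
```

Reading the output: 4 of 140 simulated samples fell below the 10,000-count
sequencing floor and were discarded.  Composition differs across sites
(PERMANOVA p at the permutation floor, R² = 0.10 of distance variance
explained by site).  The planted dysbiotic site (`site2`) stands out
exactly as a disturbed community would: evenness is significantly
heterogeneous across sites (Kruskal–Wallis on Pielou J), and its
co-activity network has almost no edges and a median node degree of 0,
against 3–9 at the healthy sites — the resilient site (`site1`) being the
most densely connected.

## Command line

```bash
gillnet simulate --preset dysbiosis --seed 7 --out data/
gillnet run-all --config run.yml            # full pipeline, fixed layout
gillnet alpha  --table data/feature_table.tsv --tree data/tree.nwk \
               --metadata data/metadata.tsv --out out/
```

`run.yml` carries input paths, thresholds, permutation counts and one seed;
all defaults match the reference parameterization (10,000; 1e-5; Spearman
±0.4; FDR 0.05; 9,999 permutations; IndVal 0.5).  Every run writes a
`manifest.json` with the config hash, input checksums, per-stage timings
and surfaced warnings.

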