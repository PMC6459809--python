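# Methods

## The analysis model

`braincoex` analyzes a two-genotype (selectively bred line vs founder
stock), multi-brain-region expression study on a log-like intensity scale.
The pipeline assumes:

- expression values are approximately Gaussian within each genotype ×
  region group after normalization;
- differential expression is a per-gene mean shift between genotypes
  within a region, tested with equal-variance pooled statistics;
- coexpression structure is block-like: groups of genes share latent
  drivers (cell-type abundance, regional identity, pathway activity), which
  is exactly the structure a signed weighted network with topological
  overlap clustering is designed to recover;
- module membership is comparable across networks through one-to-one
  ortholog pairs, so conservation can be read from membership overlap
  alone.

### Preprocessing

Order: transform + quantile-normalize → remove region-level outlier
samples → re-normalize the survivors from raw data → detection filter →
Grubbs masking.

- **Transform.** `log2(x + 1)` stands in for a bead-level
  variance-stabilizing transform; a plain expression matrix carries no
  per-bead variance information, and the log achieves the same
  variance-stabilizing intent. Data already on a log scale skip it
  (`log2_transform=False`).
- **Quantile normalization** equalizes full sample distributions; ties map
  through average ranks (linear interpolation at fractional ranks). It is
  idempotent on tie-free data.
- **Sample outliers.** Within each region, Euclidean distance of each
  sample to the region mean profile; strict threshold at 2 × median
  distance, single pass. The distance metric is a choice (only "distance
  to the sample average" is inherent to the rule); Euclidean on normalized
  values is the simplest defensible reading.
- **Detection filter.** A gene is kept in a region if detected (p < 0.05)
  in at least 75% of that region's samples, boundary inclusive. The
  network universe is the intersection over all regions; per-region lists
  drive per-region DE.
- **Grubbs masking.** Per gene, per genotype × region group: the
  one-outlier Grubbs test with
  G_crit = ((N−1)/√N)·√(t²/(N−2+t²)), t the upper α/(2N) t-quantile on
  N−2 df, iterated until no outlier remains; iteration stops below group
  size 6 and never removes more than half a group. Zero-variance groups
  are not tested. Worked example: the group (1, 2, 3, 4, 100) has
  G = 1.788 > G_crit(5, 0.05) = 1.715, so 100 is masked.

### Moderated t

Smyth's method-of-moments empirical Bayes, implemented from the
digamma/trigamma relations with Newton inversion of the trigamma function
(tolerance 1e−8, d₀ capped at 1e6 and treated as infinite beyond). Per-gene
degrees of freedom vary when Grubbs masking removed values; both the
hyperparameter estimation and the posterior formula use the per-gene d_g.
Forcing d₀ = 0 reproduces the ordinary pooled t exactly (tested at relative
error < 1e−10); the implementation also matches Bioconductor limma's
`eBayes` on shared inputs to ~1e−8 (cross-checked in the test suite).
BH q-values implement the literal step-up definition,
q_(i) = min_{j≥i} min(1, n·p_(j)/j).

The excess-DEG test compares the DEG count in a region with the α·n
expectation via a 1-df two-cell chi-square without continuity correction.
K-means clustering of per-gene t-value profiles (genes with p < 0.001 in at
least one region; default k = 6, seed 0, 25 restarts) summarizes
region-specificity of regulation.

### Network construction

Signed similarity S_ij = (1 + cor)/2 with Pearson correlation,
pairwise-complete over masked values; zero-variance genes get correlation
0 with a warning. Adjacency a_ij = S_ij^β. Soft-power selection computes
the scale-free fit index (R² × sign(−slope) of log10 p(k) vs log10 k over
10 equal-width connectivity bins) for each candidate power (default 1–10,
12–20) and returns the smallest power reaching 0.8. When no candidate
reaches the target — typical for strongly block-structured data, whose
degree distribution is bimodal rather than scale-free — the fit profile is
a noisy plateau, and the fallback returns the largest power within 0.1 of
the maximum index, with a warning: among statistically indistinguishable
fits, stronger soft-thresholding gives the sharpest intra-/inter-module
contrast in a signed network. The study default β = 12 is the command-line
default; `--pick-beta` opts into the data-driven choice.

TOM_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij) with shared-neighbor sums
l and connectivities k taken over the zero-diagonal adjacency; TOM is
clipped to [0,1] and symmetrized against floating-point drift.

**Module detection** is a dynamic tree cut on the average-linkage
dendrogram of 1 − TOM, in three deterministic stages:

1. *Static cut* at height 0.995 → candidate branches (maximal subtrees
   below the cut).
2. *Deep split*: a branch is recursively split at its root merge when that
   merge is higher than the branch's median merge height and both children
   have at least the minimum module size (default 80) leaves.
3. *Gap trimming*: loosely attached genes can join a tight branch core
   through chains of late merges just below the static cut. Each branch is
   re-cut just below the widest gap in the upper half of its merge-height
   distribution, when that gap is pronounced (≥ max(0.01, 15% of the
   height range)); the cut is rejected if no component of minimum module
   size survives, so a homogeneous branch is never fragmented. Trimming
   recurses into components because accretion can be layered.

Branches below the minimum size become "grey" (unassigned); modules are
named by the conventional size-ranked color palette (turquoise, blue,
brown, …). Exact equivalence with the published dynamic hybrid tree cut is
a non-goal; recovery of planted modules is the correctness surface, and on
the standard benchmark the planted partition is recovered with adjusted
Rand index 1.0 across generator seeds.

Module eigengenes are the first right singular vector of the
gene-standardized module submatrix (unit norm, sign-oriented to correlate
non-negatively with the module mean profile); masked values enter as zeros
after standardization. K_in sums within-module adjacencies; hub genes are
the top ⌈20%⌉ by K_in with lexicographic tie-breaks. Hub-module scores
count retained edges (adjacency above the (1−density)-quantile, default
density 1%) with exactly one endpoint in the module, normalized by module
size; a top-quartile-weight variant is also reported.

### Enrichment machinery

One upper-tail hypergeometric test, p = P(X ≥ k), everywhere: DEG lists
per (region, direction), cell-type markers, generic GMT collections, and
internetwork module overlap. The universe is the gene set used to build
the network; query sets are intersected with it. BH correction is applied
once per analysis family (all module × set tests jointly), never per
module. DEG lists default to raw p < 0.05 (a `use_q` flag switches to
q-based lists). The grey module is excluded by default.

### Cross-species comparison

Ortholog tables are resolved to one-to-one pairs (sources or targets
appearing more than once are dropped and counted). The shared universe is
the intersection of the mapped first network with the second network's
genes; every module pair is tested on it, edges with raw p < 0.001 are
kept with weight −log10 p (no multiplicity correction by default, exposed
as a flag), and a module is conserved if it keeps at least one edge. The
four-criteria prioritization requires selection-responsiveness,
conservation, cell-type specificity, and at least one partner edge to a
module flagged both alcohol-related and cell-type-specific; knowledgebase
upstream-regulator evidence is out of scope, and the hypothesis record
carries a free-text slot for manual annotation instead.

### Circuit hypotheses

Per module and region, the regulation call is the direction whose
enrichment q is significant (< 0.05); the more significant direction wins
when both are, and an exact tie gives "mixed". For neuron-flagged,
selection-responsive modules, each ordered pair of regulated regions with
a directed edge in the connectivity table yields a hypothesis scored
−log10 q(r₁) − log10 q(r₂) — a simple monotone evidence combination chosen
because no quantitative rule is inherent to the procedure. Co-regulated
pairs with no edge in either direction are reported once (unordered) as
common-upstream candidates. A default editable connectivity table for the
seven study regions ships with the package
(`braincoex/data/connectivity_default.tsv`); it is data, not code, with
free-text annotation and citation tags.

## The synthetic-data generator

`generate_dataset` draws, for gene g in module m and sample s,

    x_gs = baseline + gene_offset_g + baseline_m(region_s)
           + effect_m(region_s)·[genotype_s = selected]
           + loading_m·F_m(s) + noise_sd·ε_gs

with per-module latent factors F and iid Gaussian noise. The expected
within-module correlation is loading²/(loading² + noise_sd²) — 0.64 at the
benchmark's loading 0.8 and noise 0.6. Per-gene baseline offsets (sd 1.5)
reproduce the large abundance spread of real log-scale data; they are
constant across samples, so correlations and group contrasts are
untouched, but they make sample ranks stable — which is what lets
rank-scrambled outlier samples (planted as per-gene noise of sd 3) survive
quantile normalization and be caught by the distance rule. Detection
p-values are Beta(0.1, 10) for present genes and Uniform(0, 1) for genes
simulated as absent in a region. One stream is seeded per dataset;
per-module factor streams are derived deterministically, so identical
configurations are byte-identical.

Two deliberate deviations from the plainest factor model:

- **Balanced factors.** Factors are mean-centered within each genotype ×
  region cell and rescaled to unit sd. A raw iid factor's group means
  differ by ~0.41 sd at n = 12/group, which at loading 0.8 shifts every
  module gene coherently and masquerades as a genotype effect — module
  flags and region calls then reflect factor sampling noise rather than
  planted biology. Balancing defines the factor as non-genotype biological
  variation, orthogonal to the design in-sample. *Real data enjoys no such
  orthogonality*: coherent within-module sampling noise is a genuine
  limitation of module-level DEG enrichment at small n, and passing tests
  on balanced data say nothing about it. A consequence of balancing is
  that DE p-values for module genes are conservative (the factor inflates
  the variance estimate but not the group-mean difference); calibration
  statements (type-I error ≈ 5%) apply to independent-noise genes.
- **Balanced effect directions.** The benchmark plants equal numbers of
  up- and down-shifted genes within each affected region. Quantile
  normalization forces identical sample distributions, so a large
  one-sided planted shift would be partially redistributed onto unaffected
  genes (rank-local compensation); balancing matches real transcriptomes,
  where regulation is bidirectional and modest in extent.

### Standard configurations

- `benchmark_config` — the module-recovery benchmark: 168 samples, 3,000
  genes, 8 modules of 100–400 genes, loading 0.8, noise sd 0.6, three
  cell-type-tagged modules (neuron/astrocyte/oligodendrocyte) with region
  baselines, genotype effects of |log2| = 1 restricted to region subsets
  (the neuron module up in BLA, CeA, AcbSh), 5% of genes undetected
  somewhere.
- `de_power_config` — DE power and flagging: 1,200 genes, ten 60-gene
  modules, four carrying a |log2| = 1 effect in one region each, noise sd
  0.5 and loading 0.3. The loading is modest by design: the per-gene
  residual sd is then dominated by the stated noise level (total ≈ 0.58,
  standardized effect ≈ 1.7 ⇒ per-gene power ≈ 98% at n = 12/group).
- `null_config` — background genes only, for type-I calibration.
- `bridge_config` — hub-module scoring: 6 modules of 60 genes in 2,000,
  one mixing 95% of its factor variance from the other modules' shared
  signal. Modules are small relative to the universe so intra-module pairs
  occupy well under 1% of all gene pairs — under the default edge rule
  (top 1% of adjacencies) inter-module edges can then enter the retained
  set at all; with large modules the retention threshold lands inside the
  intra-module adjacency range and every module's cross-module edge count
  is zero.

### What the generator does not emulate

Bead-level noise, probe sequence effects and SNP-in-probe artifacts;
correlated noise between modules (except through explicit region baselines
and the bridge construction); heavy-tailed or skewed expression noise;
batch effects; factor–genotype confounding (see balanced factors above).
Passing tests therefore demonstrate correctness of the algorithms under
the stated model, not robustness to these real-data phenomena.

## Numerical choices

- Trigamma inversion: Newton, tolerance 1e−8; prior df above 1e6 treated
  as infinite (statistic referred to a normal distribution).
- Quantile normalization ties: average ranks, linear interpolation.
- Strict inequalities at both outlier thresholds; "at least 75%" detection
  boundary inclusive.
- Hypergeometric upper tail includes the observed overlap.
- Hub tie-breaks: lexicographic gene id; module naming: size-ranked color
  palette with "grey" reserved for unassigned genes.
- Degenerate inputs: zero-variance genes get similarity 0.5 with a
  warning; a constant eigengene yields ANOVA F = 0, p = 1; an all-equal
  adjacency makes the hub-edge threshold degenerate and raises.
- Dense gene × gene matrices: the CLI caps the network at 20,000 genes
  (top variance kept) and warns.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on generated data
at the study's design size (168 samples) with gene counts of 1,000–3,000,
20 replicates for rate estimates, and 20,000+ gene-tests for calibration —
sizes at which every statistic of interest is stable while a full run
completes in minutes on one CPU.

## Known limitations

- The dynamic tree cut is a reimplementation (static cut + deep split +
  gap trimming), not the published dynamic hybrid algorithm; partitions
  can differ on real data even where planted-structure recovery is
  perfect.
- The scale-free criterion is uninformative on strongly block-structured
  data; the fallback prefers high powers, which is correct for the
  synthetic regime but should be overridden (`--beta`) when the fit table
  clearly indicates otherwise.
- Module-level DEG enrichment inherits the correlated-gene caveat above:
  on real data, coherent module-level sampling noise can produce
  selection-responsive flags that balanced-factor simulations cannot
  reveal.
- Cross-species comparison assumes one-to-one orthology; dropped
  many-to-many families are counted but their information is discarded.
- The shipped connectivity table is a convenience fixture: edges carry
  citation *tags*, not verified references, and users should replace it
  with their own curated table for scientific use.
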