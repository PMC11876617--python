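# Methods

This note documents the models, the defaults and why they are set where
they are, the numerical choices, what the synthetic-data generators do and
do not emulate, and the known limitations.

## Expression normalization and trajectory staging

Counts are scaled by **median-of-ratios size factors** (the reference is
the per-gene geometric mean over samples; only genes expressed in every
sample contribute) and transformed as `log2(count/sf + 1)`.  This is a
deliberate substitution for a full variance-stabilizing transformation:
the downstream network stages consume correlations, which are robust to
the difference, and the simple transform is exactly invertible and
dependency-free.  Expressed genes are those with row-mean count strictly
greater than 5; replicate QC iteratively drops the sample with the lowest
mean within-group Pearson correlation until all pairs reach r >= 0.92 (a
group never shrinks below its best pair).

"Dynamically expressed" is operationalized as the **variance of per-stage
mean expression** — per-stage averaging suppresses replicate noise so the
ranking reflects trajectory amplitude; ties break lexicographically on
gene id.  The trajectory model runs PCA (two components, genes centered
and unit-scaled) on the dynamic genes of the reference series, assigns
each reference sample a provisional time equal to its **stage rank**
(replicates share a rank), and least-squares fits a cubic B-spline with
3 degrees of freedom per PC coordinate.  ET units are therefore stage
ranks; the anchoring convention is a package choice since a continuous
developmental axis has no canonical unit.  New samples are projected onto
the stored loadings and ET is the arg-min of squared PC-space distance to
the curve on a 1000-point grid (grid-halving changes ET by less than one
grid step; samples landing on a grid endpoint are flagged extrapolated).
Triad shares divide each genotype's TPM by the triad total; zero-total
genes yield missing values rather than 0/0.

## Co-expression networks

Biweight midcorrelation uses the standard tuning constant of 9 MADs;
genes with zero MAD cannot be midweighted and fall back to their
standardized (Pearson) vector for all their pairs, with a warning.  The
signed adjacency is `((1+cor)/2)^beta`; beta defaults to 6 (7 is the
conventional choice when heterogeneous tissue panels are combined) and a
scale-free-fit diagnostic is deliberately *not* used for automatic
selection — beta is a declared parameter of the analysis.

Module detection is a documented simplification of hybrid dynamic tree
cutting: average-linkage clustering on `1 - TOM`, an initial cut at 0.99
of the tallest merge height (a *relative* cut — TOM dissimilarities
concentrate near 1, so an absolute cut is uninformative), then a top-down
recursive split of each branch while both children hold at least
`min_size` (30) genes, and finally iterative merging of modules whose
eigengenes correlate above `1 - merge_cut` (0.75).  The merging step is
the corrective for over-splitting, so recovery of planted block structure
— not label-for-label agreement with any particular reference
implementation — is the accuracy contract, and it is what the tests
check (mean adjusted Rand index >= 0.9 over 20 seeded panels).

The module eigengene is the first PC of standardized member expression,
unit norm, with the sign fixed so the mean correlation with members is
positive.  Preservation between two networks uses a two-component
composite — within-module mean adjacency in the test network (density)
plus the ref/test correlation of intramodular connectivity — normalized
by a permutation null of size-matched random gene sets (default 1000
permutations); the one-sided p assumes normality of the null, as is
conventional for composite preservation Z scores.  A full multi-statistic
Zsummary is out of scope; the two components capture the density and
connectivity axes that the preservation claims rest on.

## Regulatory networks and motifs

GRN inference is a tree-ensemble importance scheme: each target's
variance-normalized expression is regressed on all TF expressions
(excluding itself) with a random forest (default 1000 trees,
sqrt-features); the TF->target weight is the forest importance, and edges
below 0.005 are dropped.  Each target derives its own RNG stream from the
base seed, so inference is deterministic and order-independent.  Binding
validation reports `|predicted ∩ gold| / |predicted|` against the 95th
percentile of accuracies on size-matched random target sets drawn from
the network's target universe.

Triads are classified by canonicalizing the 6-bit arc mask of a node
triple over all 6 permutations; grouping the 64 labeled 3-node digraphs
this way yields the 16 standard classes, of which exactly ten carry at
least three arcs (a mutual pair counts as two).  The census iterates over
connected triples only (edge-anchored enumeration), not all C(n,3).  The
null model resamples arc sets uniformly with fixed node and edge counts;
degree-preserving rewiring is intentionally not the default since the
stated constraint is node/edge counts only.  Enrichment flags require
Z > 20 *and* class concentration >= 10% of the >= 3-arc census.  "Fully
connected three-node subgraphs" for TF ranking means triples whose
underlying undirected graph is a triangle (clique mode, the default); a
census mode restricted to >= 3-arc classes is exposed because the two
readings give different counts.  FFL enumeration lists every (X,Y,Z) with
arcs X->Y, X->Z, Y->Z, including sub-patterns of denser triads — this
inflates counts relative to an FFL-class census and is the documented
convention here.

## Genotypes, kinship and heritability

MAF filtering removes SNPs strictly below the cutoff (0.01); a SNP at
exactly the boundary is retained.  Missing-call imputation takes, per
missing cell, the individual's genotype at the non-missing SNP with the
highest complete-case r² (nearest neighbor in LD space); neighbors below
r² = 0.2 are not trusted and the SNP's modal genotype is used instead.
LD pruning slides a 50-**SNP** window advanced by 5 SNPs and greedily
drops the later SNP of any pair at r² >= 0.7; the window is measured in
SNP count because 50 bp windows essentially never contain two markers on
real maps (a bp mode is exposed).  Nucleotide diversity treats lines as
haploid calls (inbred-panel convention; a heterozygous dosage contributes
allele value 0.5) and reports the mean pairwise call difference per site.

Gene windows are strand-aware closed intervals in 1-based coordinates:
[start − up, end + down] on +, [start − down, end + up] on −, clamped at
1; defaults ±2 kb (±10 kb for species with long LD blocks, set by
parameter).  Partition assignment is the union over gene windows (a SNP
in two overlapping windows counts once).  Kinship standardizes dosage
columns to mean 0 / variance 1 via allele frequency (center 2p, scale
sqrt(2p(1−p))), drops monomorphic columns with a warning, and returns
`XX'/n_p`.

REML uses the eigendecomposition of K and a 1-D profile of the restricted
likelihood over the variance ratio `r = sigma_G²/sigma_e²` on the log
scale, bounded to [1e−6, 1e6]; the intercept (or covariate block) and
sigma_e² solve in closed form at each r.  Bounded Brent terminates at
xatol 1e−10 and both boundary values are checked explicitly; a fit at the
lower bound reports sigma_G² = 0.  Permutation nulls draw size-matched
gene sets from the universe with the tested partition's genes removed,
rebuild windows, prune, recompute kinship and re-fit REML per replicate
(prune-then-kinship order).  Module selection requires all three
conditions: module-trait p below 0.05, observed h² above the null mean,
and observed h² at least 80% of genome-wide h².

## Association and epistasis

The replicated-field model fits year as fixed and genotype plus
block-within-year as random effects by EM-REML on the mixed-model
equations (tolerance 1e−8 on variance-component change, cap 500
iterations; blocks are keyed (year, block) so labels never collide across
years).  PhPCs are PCA of centered, unit-variance trait BLUPs; for two
traits the PhPC1 share is exactly `(1+|r|)/2`.  GBLUP estimates variance
components on the training block and predicts
`sigma_G² K[:,train] V⁻¹ (y − mu)` for all individuals.

Scans estimate variance components once under the covariate-only null
(the standard efficiency convention) and test each SNP by GLS on the
whitened model.  Single-trait engines are a GLM F-test and this MLM;
iterative marker-selection algorithms are intentionally not
re-implemented.  The multivariate LRT absorbs kinship approximately:
each trait is whitened by its own null-model variance ratio (shared
eigenvectors), then the LRT compares multivariate regressions with and
without the SNP against chi² with t degrees of freedom.  At t = 1 this
reduces exactly to the single-trait likelihood ratio, and its null
calibration under population structure is itself a test (KS p > 0.01 at
500 replicates).  The epistasis model adds peak-SNP, test-SNP and
interaction terms; the random effect carries covariance `2K sigma_G²`
(the factor 2 is folded into the fitted ratio), and the reported p is the
Wald test of the interaction.  Test SNPs equal to the peak or collinear
with the main effects are flagged and skipped.

## SV presence/absence

The printed region coordinates are treated as a 1-based inclusive display
whose length is computed end-exclusive — the convention that reproduces
the printed 969-bp bin width exactly; an integer-division remainder goes
to the last bin and is flagged.  A bin is depleted when its ratio falls
below `depletion_factor × 1/n_bins` (default 0.5); a line is absent when
a majority of bins are depleted, present when at most one is, ambiguous
otherwise.  A line whose region total falls below `min_total` is called
**absent** outright: when the variant spans the whole binned region,
uniform depletion leaves the ratio profile flat and the negligible total
is the only absence signal.  `min_total` should scale with expected
carrier coverage — analyses of the synthetic panels use half the expected
per-bin carrier depth (50 at 100× per-bin coverage), set from the
coverage model, with the generic default at 20.  Ratio-based calls are
invariant to scaling a line's counts as long as the scaled total stays at
or above the floor.  Group tests use the one-sided Wilcoxon rank-sum with
exact small-sample p-values and mid-rank tie handling.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of their configs (seed included).
Expression panels place dynamic genes on smooth functions of latent time
with per-genotype heterochronic offsets; module genes share a latent
factor that varies across (genotype, stage) groups — not across
replicates, so zero-noise replicates are byte-identical — and the factor
realization is standardized so the planted within-module correlation is
unbiased.  A consequence: with few sample groups two independent module
factors can correlate by chance, so block-recovery analyses use designs
with ~20+ groups.  Regulatory truth plants motifs on disjoint node
triples; `edge_noise` is the relative sd of expression noise given the
true parents (at 0, a single-parent target is an exact copy of its
regulator).  Mutual-edge pairs are generated with one node as driver and
its partner as a near-copy, since cyclic truth cannot be sampled
ancestrally.  Genotypes combine Balding–Nichols subpopulation divergence
with first-order Markov haplotype copying (probability `ld_rho` of
copying the previous allele); phenotypes draw effect pairs from a
common-factor construction whose genetic correlation is exact (including
|rho| = 1) and rescale genetic values so the genetic-value h² matches the
target exactly, then layer year, block-within-year and plant noise.

Not emulated: sequence-level reads, recombination maps, multi-chromosome
pedigrees, dominance/epistatic architecture beyond the planted pairwise
interaction, expression-genotype coupling (eQTL), and realistic LD decay
shapes.  Passing tests therefore demonstrate the estimators' correctness
and calibration under the assumed generative models, not robustness to
everything real panels contain.

## Problem sizes

Defaults in the test and acceptance suites are desk-scale by design: REML
recovery uses n = 500 individuals × 2000 SNPs × 20 seeds per planted h²;
scan calibrations use 300–500 replicates over a 200-line structured panel
with a precomputed eigendecomposition; permutation-null calibration uses
a 100-line panel with 40-permutation nulls over 60 draws; module recovery
uses 110-gene panels over 20 seeds.  The library APIs keep the full-size
defaults (1000 trees, 1000 permutations) for real analyses.

## Known limitations

* Module labels are deterministic (size order) but not comparable across
  runs with different gene sets; cross-network claims should go through
  the preservation test or explicit overlap tests, not label identity.
* The multivariate LRT is an approximation to a full multivariate kinship
  mixed model; it is calibrated under the simulated structure but can
  drift when per-trait variance ratios are extreme and traits are highly
  correlated.
* The preservation composite equally weights density and connectivity;
  modules preserved in only one aspect score intermediate Z.
* `empirical_null_h2` re-fits REML per replicate; with 1000 permutations
  on large panels this is the pipeline's slowest step (it parallelizes
  trivially by seed if needed).
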