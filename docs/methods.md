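# Methods

This document records the model behind each ProTFnet component, the
estimators and their numerical conventions, the semantics of the
synthetic-data generators, and known limitations. Everything stated as an
empirical number here was computed with this package (the test suite or
`scripts/acceptance.py`).

## Genomic binding

**Cis-regulatory modules (CRMs).** Per-TF peak sets (BED intervals) are
merged per chromosome by single-linkage with ≥ 1 bp overlap: intervals are
sorted by start and a sweep joins any interval that starts before the
current merged end. A merged region is kept as a CRM only if it carries
peaks of ≥ 2 distinct TFs; the CRM's TF set is the union over its peaks.

**Promoter mapping.** A gene's promoter is represented by its width-1 TSS
coordinate. Ambiguous annotations are dropped in both directions before
mapping: a TSS claimed by more than one gene, and a gene owning more than
one TSS. A promoter is *bound* if its TSS overlaps a CRM; if it overlaps
several, their TF sets are unioned. The binding matrix is the binary
promoter × TF indicator over a fixed TF universe.

**Signals.** Promoter H3K27ac is the maximum track value over the
promoter's CRM (uncovered positions count 0). H3K4me3 breadth is the
width of the nearest domain at distance 0. Active TSS selection requires
≥ 2-fold signal over control in ± 500 bp (pseudocount 0.1), keeping the
best TSS per gene. Peak counting near a TSS uses a ± 10 kb window.

## SOM clustering

The self-organizing map is a rows × cols toroidal grid (default side
⌈√(5√N)⌉ for N rows of data) trained online: for each input row the
best-matching unit (BMU) minimizes Euclidean distance, ties broken
lexicographically by (row, col); every codebook vector moves toward the
input with step α·exp(−d²/2σ²) where d is the wrap-around grid distance
to the BMU. α decays linearly 0.05 → 0.01 and σ from max(rows, cols)/2 to
1 over the epochs. Training order is the data order, fixed per epoch, so
results are exactly reproducible for a given seed (the seed initializes
the codebook).

**Prototypes and clusters.** Codebook vectors are binarized at 0.5.
Prototypes are Ward-clustered (scipy linkage on Euclidean distances) and
cut into k clusters, lettered "A", "B", … by ascending mean prototype
sum, i.e. "A" has the sparsest binding combination. The homogeneity curve
is 1 − (within-cluster sum of squared distances)/(global sum of squared
distances) for each k of a nested Ward cut; squared distances make the
curve monotone non-decreasing in k. The elbow is the k maximizing the
absolute second difference of the curve.

## Co-recruitment

**Tanimoto distance** between two TFs is 1 − |A∩B|/|A∪B| over their
bound-promoter sets (distance 1 if both are empty, 0 on the diagonal).
Computed via X<sup>T</sup>X intersection algebra on the binary matrix.

**Classical MDS** (Torgerson): eigendecomposition of −½·J·D²·J with J the
centering matrix; coordinates are eigenvector × √eigenvalue for positive
eigenvalues, zero-padded beyond them, with the sign convention that each
coordinate's first nonzero entry is positive.

**Core co-recruitment nodes** are frequent itemsets: TF combinations of
size 2–49 present at ≥ 50% support among a cluster's promoters, mined
levelwise (apriori): candidates of size k+1 are prefix-joins of frequent
size-k sets, pruned by the anti-monotone support bound, with supports
counted on boolean masks. The support threshold uses
count ≥ ⌈support·n − 1e−9⌉ so that exact-boundary supports are kept.
Core-node occurrence of a TF is the percentage of mined nodes containing
it.

**Distance correlation** (Székely) uses the biased V-statistic by default
(double-centered distance matrices), with an unbiased U-statistic option
(requires n ≥ 4); it returns 0 when a marginal distance variance is ≤ 0
(constant sample). dCor(x, 2x) = 1 exactly; under independence at n = 50
the mean observed V-statistic over 200 replicates was 0.24 (bias of the
V-statistic, not evidence of dependence).

## Expression programs

**Deciles** partition genes into 10 bins of near-equal population (stable
sort; remainders go to the lowest bins). **Tau** is the standard
specificity index Σ(1 − x̂ᵢ)/(n − 1) with x̂ the profile scaled by its
maximum; undefined (NaN) for all-zero profiles. Subset-vs-background
decile distributions are compared with the two-sample KS test.

**MFA.** Each group (e.g. species atlas) is column-centered and scaled to
unit variance (ddof 0; constant columns are rejected by name), then
weighted by 1/λ₁ of its own first singular value squared, and the
concatenated weighted table is decomposed by SVD. Scores use the
convention that each component's largest-|loading| entry is positive.
With one group, or two identical groups, MFA reproduces single-group PCA
scores up to sign (verified to |r| = 1 in the acceptance suite);
duplicating a group's columns leaves its scores unchanged.

**Program calls.** TFs are Ward-clustered in MFA score space into k = 3
clusters, labeled CTS / CTE / UBQ by ascending mean number of cell types
in which the TF exceeds 25% of its own maximum ("high-expression
counts"). **Connect selection**: within the focal cell type's atlas, a TF
is selected if the focal cell's expression rank across cell types is
≤ 10 (average ranks for ties, then ceiling) *and* the log2 fold of the
focal cell over the mean of the other cell types is > 0 (pseudocount
0.01). CTS TFs are excluded from the connect set downstream, since
connect TFs are by definition broadly expressed factors.

## Matched controls

**Activity strata.** Three per-gene activity features (accessibility,
acetylation, expression) are log2(x+1)-transformed, z-scaled per feature,
Ward-clustered into k = 4 strata numbered 1–4 by ascending mean activity.
Degenerate (all-identical) feature tables and missing values are rejected
with the offending gene named.

**Matched resampling.** Control sets are drawn without replacement from
the non-identity pool so that every set reproduces the identity set's
per-stratum counts exactly; insufficient candidates in a stratum raise an
error naming the stratum. Over 1,000 iterations, per-gene inclusion
frequencies are uniform within binomial 99% bounds (verified in the
acceptance suite).

**Representative set.** Each control set is scored against the identity
genes (by default a one-sided rank-sum test on perturbation fold
changes); p-values are binned at width 0.01, the modal bin wins (ties go
to the lower bin), and the representative is the set whose p is closest
to the modal bin's center. *Known limitation*: the claim that this
representative's p falls inside the ensemble's interquartile range in
≥ 95% of ensembles is not attainable by this selection rule. A p-value
distribution under a planted shift is right-skewed, and the mode of a
right-skewed distribution lies below its first quartile; for strong
shifts the whole distribution collapses into the first bin, where
"closest to the bin center" selects an extreme value. Measured across
planted shifts of 0.2–0.75 SD, one- and two-sided tests, group sizes
12–26 and 300–1,000 sets per ensemble, the in-IQR rate stays between 35%
and 53% (about 30–40% at the conditions used in the acceptance suite).
The corresponding acceptance check is deliberately left failing rather
than weakened.

**Statistics.** The group shift test is the Wilcoxon rank-sum
(Mann–Whitney), exact when the smaller group has ≤ 10 observations and
there are no ties, otherwise asymptotic with continuity correction;
paired data use the signed-rank test; all-tied inputs warn and return
p = 1. Enrichment uses Fisher's exact test with the log2 odds ratio
(Haldane–Anscombe +0.5 correction only when a cell is zero; NaN for an
empty margin). Multiple testing uses Benjamini–Hochberg. K-group
comparisons use Kruskal–Wallis with BH-corrected pairwise rank-sum tests.

## Dedifferentiation projection

**Batch correction** is mean-only and anchor-referenced: per gene, the
offset is (target anchor mean − reference anchor mean); offsets are
shrunk toward their grand mean μ with an empirical-Bayes normal prior,
weight τ²/(τ² + s²), where s² is the sampling variance of the offset
(sum of anchor-group variances over their sizes) and τ² =
max(var(d) − mean(s²), 0) by method of moments. Variances are never
rescaled. A planted constant offset is removed to machine precision
(max residual < 1e−9, verified).

**Reference axis.** PCA of the reference series with gene-wise centering
only (no unit scaling); component signs are chosen so the mature anchor
samples have positive mean scores, making higher PC1 = more
differentiated. New samples are projected by centering with the reference
gene means and multiplying by the PC1 loading vector. Study-level injury
effects are summarized per gene as the median log2 fold change across
studies (genes present in fewer than `min_studies` studies are dropped).

On the default synthetic series, reference PC1 carries 99.7% of the
variance and the Spearman correlation between projected PC1 and the
planted stage across reference plus corrected injury samples is 0.96.

## Synthetic-data generators

All generators are pure functions of (config, seed). The config holds one
`rng_seed`; each generator stage (cistromes, TSS, signal, atlas,
perturbation, differentiation) draws from its own child of a
`numpy.random.SeedSequence` spawn, so adding or reordering calls in one
stage never perturbs another.

**Genome.** One synthetic chromosome; promoter i has its TSS at
10 kb + i·20 kb; peaks are ± 100 bp around the TSS, so peaks of the same
promoter always merge into one CRM and different promoters never merge.

**Cistromes.** Promoters are assigned round-robin to
`n_binding_clusters` planted clusters; each cluster owns a disjoint TF
set, and each promoter receives one peak per TF of its cluster. Every
promoter × TF indicator is then flipped independently with probability
`binding_noise`.

**TSS annotation.** Optionally plants ambiguous units downstream of the
real loci: one shared TSS claimed by two decoy genes, and one decoy gene
owning two TSSs — exactly the cases the mapping must drop.

**Signal tracks.** Each gene carries an activity stratum s ∈ {1..4} with
signal level 2ˢ in ± 500 bp around its TSS, plus lognormal noise.
Identity genes get broad H3K4me3 domains (5,000 bp) vs 1,000 bp
background.

**Expression atlas.** Two species × `n_celltypes_per_species` cell types
(≥ 6 required); cell type 0 is the focal type ("hepatocyte"). CTS TFs
express in a single cell type outside both the focal cell and the shared
lineage block. CTE TFs share an enriched block (cell types 1–3),
emulating lineage-correlated enrichment — without a shared block, CTE
profiles would be indistinguishable from CTS in MFA score space. Connect
TFs (interleaved across the CTE and UBQ lists) additionally express in
the focal cell just above their own program level (9.0 vs 8.0 for CTE,
6.5 vs 5.0 for UBQ), so they remain members of their program rather than
forming a fourth cluster, while still ranking first in the focal cell.
Gaussian noise of SD `expression_noise` (default 0.3) is added
throughout. These choices were fixed while designing the generator, from
the requirement that planted programs be geometrically coherent — not by
iterating against test outcomes.

**Perturbation studies.** Per-study log2 fold-change tables in which the
target group (identity genes by default) is shifted by `fc_effect_size`
(default −1) plus noise; other genes are centered at zero.

**Differentiation series.** Expression of gene g in sample s is
μ_g + loading_g·stage_s + batch_s + noise. The reference spans stages 1–6
(two replicates each, batch 0); each injury study carries a constant
batch offset 3·(study+1) and contains control anchors at the adult stage
and injured samples two stages below. Because the batch offset is
constant across genes, it is exactly the kind of effect mean-only
anchor correction removes.

## Numerical conventions

- float64 throughout; no global RNG state — every random draw flows from
  an explicit seed or `numpy.random.Generator`.
- Ties broken deterministically (lexicographic BMU, stable sorts, lower
  bin on modal ties), so all outputs are bitwise reproducible per seed;
  the pipeline records SHA-256 hashes of every output in its manifest and
  two runs with one seed produce identical hashes.
- Ward clustering, rank statistics, exact tests and BH go through
  scipy/statsmodels; SOM, classical MDS, distance correlation, MFA, the
  itemset miner and the anchor-referenced correction are implemented in
  the package and validated against brute-force oracles in the tests.

## Limitations

- All empirical behavior is established on synthetic data at desk scale;
  absolute numbers (cluster counts, variance fractions, p-values) are
  properties of the generators, not of any real genome.
- The online SOM depends on presentation order; it is reproducible but
  not permutation-invariant (cluster recovery under row shuffling is
  tested statistically, not bitwise).
- The default distance correlation is the biased V-statistic; it is
  positive in expectation under independence (mean 0.24 at n = 50).
- Representative-set selection at the mode of p is faithful to its
  definition but, as analyzed above, does not guarantee a central
  (in-IQR) representative; treat the representative as "most typical
  p-bin", not as a median-like summary.
- The caching digest covers the whole run configuration, so changing any
  parameter invalidates all stages — conservative, never stale.
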