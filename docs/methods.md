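# Methods

This note documents the models, statistics and numerical choices behind
`methyl3c`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where more than one reasonable construction
exists.

## Data model

All coordinates are 0-based half-open; ALLC methylation tables and 4DN
.pairs files (1-based on disk) are converted on read and write. CpG records
on opposite strands of one dinucleotide are merged on read by summing
methylated and total counts, keyed by the + strand cytosine; merging is
idempotent. Interval queries use a binary search over sorted starts with a
running maximum of ends, so overlapping intervals are handled without an
interval-tree dependency; half-open semantics mean a query ending exactly at
an interval start does not overlap it. Blacklist filtering removes a contact
when either end falls in a masked interval.

## Cell QC

Five criteria, all strict inequalities: non-conversion estimate
mCCC < 0.015, global mCG > 0.5, global mCH < 0.15, total contacts strictly
between 100,000 and 500,000, and at least one intra-chromosomal contact on
every autosome after blacklist filtering. Global fractions are
coverage-weighted. mCH covers all non-CG contexts; mCCC is the CCC subset.
A context with zero coverage leaves its criterion vacuously satisfied
(absence of evidence is not a failure), except CG, where zero coverage fails
outright with reason `no_coverage`.

## Hypomethylation scores and LSI

The per-cell, per-5 kb-bin score is the exact binomial lower tail
P[X ≤ mc | Binomial(cov, global mCG)]; the binary indicator thresholds it at
0.05. This is a stand-in for the published pipeline's score, whose exact
formula is not printed in the main text; the construction follows the
ALLCools-style binarized hypomethylation feature. LSI is TF–IDF
(tf = row-normalized indicators, idf = log(1 + n_cells/(1 + df))) followed
by truncated SVD; components whose absolute Spearman correlation with
per-cell total coverage exceeds 0.8 are dropped as depth artifacts.

## Gene-body mCG and markers

Gene-body fractions are Σmc/Σcov over the gene span, divided by the cell's
global mCG and capped at 10 (unbounded ratios in low-mCG cells destabilize
rank tests); entries with coverage < 5 are missing. Genes overlapping the
blacklist, and genes ≤ 200 bp whose span is ≥ 90% covered by other genes,
are excluded. Marker tests are one-vs-rest Wilcoxon rank-sum tests on
normalized fractions (mid-ranks; scipy's exact/asymptotic switch), BH-
corrected within type. Cluster-marker thresholds: hypomethylation difference
≥ 0.15, adjusted p ≤ 0.01, AUROC ≥ 0.75; differentially methylated gene
mode: difference ≥ 0.1 and adjusted p < 0.05. Genes are testable for a type
only when ≥ 10 of its cells carry ≥ 10 methylated or unmethylated counts.
Constant genes get p = 1. Unique markers pass for exactly one type.

## DMS testing

Per site, counts are pooled per cell type; the statistic is the RMS of
standardized residuals r_k = (m_k − n_k p̄)/√(n_k p̄(1 − p̄)) over covered
types. The null resamples each K×2 table with fixed margins by sequential
hypergeometric draws. Permutation statistics from all sites are pooled into
one empirical null: the statistic is standardized and hence comparable
across sites, and pooling gives p-value resolution 1/(n_sites·n_perm + 1),
without which BH-adjusted significance at q < 0.01 is unreachable at any
workable permutation count. For a single-site table the pooled null reduces
to the per-site permutation p, which matches exhaustive fixed-margin
enumeration for small K = 2 tables. Degenerate sites (pooled fraction 0 or
1) get s = 0, p = 1; sites with pooled coverage below K are dropped.

States use the 0.4/0.6 quantiles (linear interpolation) of each type's
residuals across significant DMSs per chromosome, with a genome-wide
fallback below 10 sites. Merging is a deterministic left-to-right pass:
a DMS joins the open region when it is within 250 bp of the previous member
and their per-type fraction vectors correlate above 0.8 (correlation against
the previous member, not the region mean — a single-pass rule that needs no
iteration; constant vectors are not mergeable). Region states are means of
member state codes (−1/0/+1) cut at ∓0.5; single-DMS regions, regions with
no non-neutral state, and blacklist overlaps are excluded.

## Contact imputation

Raw binned counts are convolved with a uniform (2·pad+1)² filter (truncated
and renormalized at chromosome edges), row-normalized, and diffused by a
random walk with restart probability 0.5, iterated to max-change < 1e-6 or
100 iterations (the limit is restart·(I − (1−restart)P)⁻¹). The result is
symmetrized and, at 25 kb and 10 kb, band-limited to 10 Mb. Pad is 1 at
100 kb and 2 at finer resolutions; restart 0.5 and tolerance 1e-6 are the
established single-cell Hi-C defaults.

## Compartments

Pseudobulk maps are sums of imputed per-cell matrices. Observed/expected
divides each diagonal by its mean; the Pearson correlation matrix of O/E
rows (rows without variance excluded) is centered and eigendecomposed; among
the top three components, the one with maximal |correlation| to a density
reference (CpG density on real data; the generator's density track on
synthetic data) is chosen and oriented positive, a standard A/B orientation
practice. Chromosomes where no component reaches |r| ≥ 0.2 are unresolved.

Differential bins: scores are quantile-normalized across types and each
bin's squared Mahalanobis distance from the cross-type mean is computed.
Two p-value routes exist:

* `differential_compartments` — χ²_K upper tail on d², covariance estimated
  iteratively with outlier bins (d² above the χ²_{K,0.99} quantile) removed,
  initialized from a minimum-covariance-determinant estimate. The robust
  initialization matters: when many bins carry flips, a plain starting
  covariance is inflated by the very outliers to be detected and the trim
  loop never engages.
* `differential_compartments_calibrated` — the same d², but the noise
  covariance and the null distribution of d² are estimated from within-type
  split-half score differences: (score_A − score_B)/2 over random half
  splits of each type's cells has exactly the sampling variance of the
  full-type score, including cell-composition fluctuations of heterogeneous
  groups, which a pooled covariance with a χ² tail does not capture (label-
  shuffle experiments show the χ² route anti-conservative for this reason).
  Twenty splits; empirical p with add-one smoothing; BH at FDR < 0.1.

The calibrated route is used wherever the empirical false-discovery claim is
evaluated; the label-shuffle check (`empirical_null_fdr`) rebuilds
pseudobulks under permuted labels and reports the ratio of mean shuffled to
true-label detections.

Lineage dendrograms use average linkage on 1 − Pearson correlation of
type-level feature matrices (compartment scores on differential bins, or
DMR mean methylation fractions), with sorted type order for deterministic
ties.

## Domains, boundaries and loops

The diamond signal at boundary i is the mean of the w×w submatrix
(i−w..i−1)×(i..i+w−1), w = 5 at 25 kb, truncated at edges. Boundaries are
plateau-aware local minima whose diamond entries are lower (one-tailed
rank-sum, p < 0.05) than the entries of the up- and downstream within-region
triangles — comparing against within-region contacts rather than shifted
diamonds avoids flagging noise minima inside uniform blocks. Insulation is
log2 of the window-10 diamond mean over its chromosome average.

Differential boundaries: per 25 kb bin, the K×2 table of cells with/without
a boundary gives a Pearson χ² (df = K−1), z-transformed by the
Wilson–Hilferty cube root. The approximation is accurate (|Δz| ≤ 0.05
against the exact normal transform) in the decision region 0 ≤ z ≤ 3 around
the 1.960 cutoff, and drifts in the far tails; decisions only use the
cutoff region. A bin is differential only if all five criteria hold:
z > 1.960, max−min boundary probability > 0.05, local maximum of the
aggregate boundary probability, local minimum of the mean pseudobulk
insulation, and BH FDR < 0.001.

Loops are called on the imputed raw pseudobulk (summed raw cell maps,
imputed once with pad 2): candidates must exceed 1.5× the per-diagonal
global expectation and 4/3× both local backgrounds (11×11 donut excluding
the central 3×3, and the lower-left 5×5 quadrant towards the diagonal),
within 50 kb–10 Mb. The empirical null circularly shifts each diagonal of
the raw map independently and re-imputes with the same operator, making
observed and null maps exchangeable while destroying loop dots; shifting an
already-imputed matrix instead breaks its smoothness and floods the null
with artifacts. Per-distance-octave empirical q (mean null exceedances per
shift over observed exceedances, monotonized) is thresholded at 0.1;
surviving pixels are 8-connected-clustered and each cluster's maximal
global-fold pixel is the summit. Imputing the summed raw map rather than
summing per-cell imputed maps is a deliberate choice: the null must pass
through the identical smoothing operator for the empirical FDR to be valid.

## Integration

The normalized gene-body mCG matrix is sign-reversed (hypomethylation
tracks expression), both matrices are per-gene standardized on the shared
gene set, and the SVD of the cross-product yields paired canonical scores,
L2-normalized per cell. Overlap between a methylation type A and an RNA
type B is Σ_c min(share of A in cluster c, share of B in c) over joint
Leiden clusters of the k-NN graph (k = 15, resolution 1.0 by default); the
ARI compares neighbor-transferred labels with native labels. RNA markers:
genes with ≥ 3 counts in ≥ 3 cells, library-size log-normalization,
one-vs-rest one-tailed rank-sum, positive log2 fold change ≥ 0.25 (the
conventional default), non-zero expression in ≥ 25% of the tested type or
the rest, Bonferroni p < 0.05.

## Genetics

Clumping is greedy by ascending p (ties by position): a variant is retained
unless within 250 kb of a retained variant with dosage r² > 0.2 (missing
dosages mean-imputed). PRS = Σ β_j·dosage over clumped variants passing the
p threshold (grid 5×10⁻⁸ … 0.5), optionally restricted to regions.
Incremental R² is the squared correlation with the covariate-residualized,
rank-based inverse-normal trait (Blom offsets (r − 3/8)/(n + 1/4), mid-
ranked ties). Enrichment p is one-tailed against 10,000 (configurable)
permuted scores from size-matched draws of the genome-wide clumped,
thresholded pool — sampling from that pool, not MAF-stratified, matches the
"matching genomic background" construction. GWAS-variant overrepresentation
is a one-tailed hypergeometric test on clumped variants; DMR–peak overlap
uses an n = 1,000 interval-shuffling null (lengths and chromosomes
preserved, blacklist avoided, add-one p) plus a hypergeometric test on 1 kb
genome bins. All permutation p-values use add-one smoothing and are
seed-deterministic.

## Synthetic data: what it emulates, and what not

Methylomes: per cell and CpG, coverage is Poisson and methylated counts
Binomial(cov, p); p is the type baseline (default 0.75 for all types, so
planted DMRs are the only cross-type signal) shifted by ±Δ inside planted
regions and clipped to [0.01, 0.99]. `random_dmrs` plants non-overlapping
regions snapped to CpG positions (the truth region is the minimal span of
affected sites), one affected type each, alternating hypo/hyper, default
Δ = 0.4. Low-level CH/CCC sites are added so QC metrics are computable.

Contacts: per cell, pairs are multinomial draws from a per-chromosome
bin-pair map ∝ (d+1)^(−α_type), multiplied by 2 for same-compartment pairs,
by the TAD multiplier inside blocks, and by the loop multiplier on planted
3×3 loop dots (a loop is a tens-of-kb contact dot, not a lone pixel — lone
pixels cannot survive pad-2 smoothing and would make the planted truth
unrecoverable by construction). Positions are jittered uniformly within
bins so one simulation serves 100/25/10 kb analyses. Compartment flips are
planted as contiguous runs of half a plaid block (realistic compartment
switches span regions; isolated one-bin flips are erased by pad-1
smoothing). The density track is the base plaid plus noise, emulating CpG
density's association with A compartments.

Expression: negative-binomial counts whose per-type log-mean decreases
linearly in the type's expected gene-body mCG, yielding the observed
anti-correlation between gene-body methylation and expression.

Genotypes: per LD block, a latent Gaussian AR(1) thresholded at
Hardy–Weinberg genotype quantiles. Thresholding attenuates correlation
(Hermite factor ~0.75–0.85 at common MAFs), so each step's latent
correlation is calibrated numerically (bivariate-normal rectangle
probabilities inverted by Brent's method, grid-cached by MAF pair) to make
realized adjacent dosage correlation match the configured ρ; MAF-mismatched
pairs are capped by the attainable maximum, as in real LD. Causal variants
are drawn with weight `annotation_fold` inside the annotation; the trait is
y = Gβ + ε scaled to h²; marginal least-squares summary statistics come
from an independent "base" individual split, with PRS evaluation on the
"target" split.

Not emulated: bisulfite read-level error, inter-chromosomal contacts,
realistic human LD panels, batch/sample effects, doublets and ambient
contamination, and the genome-scale of real data. Passing tests therefore
demonstrate correctness and calibration of the statistical machinery under
the generative model, not robustness to artifacts absent from it.

## Problem sizes used in the test suite

Chosen to exercise each stage end-to-end at desk scale: DMR recovery uses
four types × 10 cells on 2×400 kb with per-site coverage mean 20 and Δ = 0.4
(five seeds); the compartment-calibration experiment uses five types × 60
cells on 2×40 Mb at 100 kb with 50,000 contacts per cell and 15% flipped
bins at multiplier 2, with ten label shuffles; TAD recovery uses the
strong-contrast setting (within-block multiplier 5, 50,000 contacts);
loop recovery plants ten dots at multiplier 10 on a 10 Mb chromosome at
10 kb; the genetics suite uses 5,000 variants in 20-variant LD blocks
(ρ = 0.8), 2,000 base + 1,000 target individuals, h² = 0.3.

## Known limitations

* The split-half empirical null for differential compartments has
  realization variance: individual label shuffles can leak a few dozen
  flagged bins; the mean over ten shuffles stays well below 2% of
  true-label detections under the tested conditions.
* The loop caller's pseudobulk is the imputation of the summed raw map, not
  the sum of per-cell imputations (see above); at very heterogeneous cell
  depths the two can differ.
* The Wilson–Hilferty z is a tail approximation; far-tail z values are
  biased low, which does not affect the 1.960 cutoff decision.
* Marker AUROC is computed from the rank-sum statistic and is exact only up
  to tie handling.
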