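# methyl3c

Analysis toolkit for jointly profiled single-cell DNA methylomes and
chromatin conformation (snm3C-seq), aimed at cell-type-resolved epigenomics
of heterogeneous tissues such as human subcutaneous adipose tissue: per-cell
QC and embeddings, differentially methylated site/region (DMS/DMR) calling
with per-type methylation states, A/B compartment and differential-
compartment analysis, domain/boundary and loop calling, contact-distance
statistics, methylome–transcriptome co-embedding, and annotation-partitioned
polygenic risk. A synthetic-data generator plants known DMRs, compartment
flips, TADs, loops and causal variants so that every caller can be validated
against recoverable ground truth.

## The methods in brief

**Methylation.** Per cell, strand-merged CpG counts (mc, cov) are summarized
per 5 kb bin by a one-tailed binomial hypomethylation score
P[X ≤ mc | Binomial(cov, m̄CG_cell)], binarized at 0.05 and embedded by LSI
(TF–IDF + truncated SVD). Cell-type DMSs are tested on pooled per-type
counts with the RMS of standardized residuals
r_k = (m_k − n_k p̄)/√(n_k p̄(1−p̄)) against a fixed-margin permutation null
(sequential hypergeometric resampling, pooled across sites), BH-corrected at
q < 0.01. Per-type states (hypo/neutral/hyper) come from the 0.4/0.6
chromosome-wide residual quantiles; DMSs within 250 bp whose cross-type
methylation-fraction vectors correlate at r > 0.8 merge into DMRs.

**Conformation.** Per-cell contact matrices are imputed by convolution
(pad = 1 at 100 kb, pad = 2 at 25/10 kb) followed by a random walk with
restart (restart 0.5). Compartment scores are the density-anchored leading
principal component of the distance-normalized pseudobulk correlation
matrix (A: score > 0). Differential 100 kb bins are flagged by a Mahalanobis
test at BH FDR < 0.1, with the noise covariance and null distribution
calibrated from within-type split-half differences; calibration is verified
by cell-label shuffling. Domains are TopDom-style diamond minima at 25 kb
(insulation window 10 bins); differential boundaries require a
Wilson–Hilferty z > 1.960, probability spread > 0.05, peak/valley
coincidence, and FDR < 0.001. Loops are donut-filter enrichments on 10 kb
pseudobulk maps at an empirical FDR < 0.1 against diagonal-shifted nulls.

**Integration and genetics.** Gene-body mCG (sign-reversed, standardized) is
co-embedded with RNA by cross-product SVD (CCA); agreement is the min-sum
overlap score over joint Leiden clusters and the ARI of neighbor-transferred
labels. Polygenic scores use greedy LD clumping (r² > 0.2 within 250 kb),
p-value thresholds from 5×10⁻⁸ to 0.5, incremental R² against a
covariate-adjusted inverse-normal (Blom) trait, and one-tailed enrichment
p-values from size-matched permutations of the clumped, thresholded pool;
GWAS-variant overrepresentation uses one-tailed hypergeometric tests, and
DMR–peak overlap an interval-shuffling empirical null.

## Worked example

```python
import dataclasses
import numpy as np
from methyl3c import simulate as sim, dmr
from methyl3c.genome import GenomeSpec

cfg = sim.SimulationConfig(seed=1, genome=GenomeSpec.uniform(2, 400_000),
                           n_cell_types=4, cells_per_type=10)
cfg = dataclasses.replace(cfg, methylation=dataclasses.replace(
    cfg.methylation, coverage_mean=20.0, n_ch_sites=0))
cfg = dataclasses.replace(cfg, methylation=dataclasses.replace(
    cfg.methylation, dmrs=sim.random_dmrs(cfg, n=20)))

cells, labels, truth = sim.simulate_methylomes(cfg)
tables = dmr.aggregate_sites(cells, labels)
sites = dmr.assign_states(dmr.test_dms(tables, n_perm=300, fdr=0.01, seed=1))
regions = dmr.merge_dmrs(sites)

planted = {(d.chrom, p) for d in truth.dmrs for p in range(d.start, d.end)}
called = {(r.chrom, p) for r in regions.itertuples() for p in range(r.start, r.end)}
print(len(regions), "DMRs")
print("bp recall", round(len(planted & called) / len(planted), 3),
      "precision", round(len(planted & called) / len(called), 3))
```

Output:

```
21 DMRs
bp recall 0.988 precision 1.0
```

Twenty DMRs of ~400 bp were planted with a methylation shift of ±0.4 in one
of four cell types; the caller recovers 98.8% of the planted base pairs at
q < 0.01 with no false-positive base pairs (one planted region is split into
two called regions, hence 21).

A thin CLI wraps the main stages:
`methyl3c simulate|qc|dmr|compartments|domains|loops|genetics --help`.

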