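"""Annotation-partitioned polygenic risk and variant enrichment.

LD clumping (greedy by p-value, r^2 > 0.2 within 250 kb absorbed),
p-value-thresholded scoring, incremental R^2 against a covariate-adjusted
inverse-normal trait, permutation enrichment against size-matched variant
sets from the genome-wide clumped pool, one-tailed hypergeometric
enrichment of genome-wide-significant variants in regions, and an
interval-shuffling empirical null for peak overlap of DMRs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeSpec, Region, RegionSet

__all__ = [
    "THRESHOLD_GRID",
    "ClumpedSet",
    "clump",
    "inverse_normal_transform",
    "adjusted_trait",
    "PRSResult",
    "build_prs",
    "permutation_enrichment",
    "gwas_overlap_enrichment",
    "peak_overlap_null",
]

THRESHOLD_GRID = (5e-8, 1e-6, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass
class ClumpedSet:
    retained: List[str]  # index-variant ids, in retention order
    absorbed: Dict[str, List[str]]

    def __len__(self) -> int:
        return len(self.retained)


def clump(
    sumstats: pd.DataFrame,
    dosages: pd.DataFrame,
    r2: float = 0.2,
    window: int = 250_000,
) -> ClumpedSet:
    """Greedy LD clumping by ascending p-value.

    A variant is retained unless it lies within ``window`` bp of an
    already-retained variant on the same chromosome *and* its squared
    dosage correlation with that variant exceeds ``r2``. Ties in p are
    broken by position. Missing dosages are mean-imputed per variant.
    """
    ss = sumstats[sumstats["id"].isin(dosages.columns)]
    if len(ss) < len(sumstats):
        import warnings

        warnings.warn(f"{len(sumstats) - len(ss)} variants missing from dosages; excluded")
    ss = ss.sort_values(["p", "chrom", "pos"], kind="mergesort")
    D = dosages[ss["id"]].to_numpy(dtype=float)
    col_mean = np.nanmean(D, axis=0)
    nanmask = np.isnan(D)
    if nanmask.any():
        D[nanmask] = np.take(col_mean, np.where(nanmask)[1])
    D = D - D.mean(axis=0)
    norms = np.linalg.norm(D, axis=0)
    norms[norms == 0] = 1.0
    D = D / norms
    ids = ss["id"].to_numpy()
    chroms = ss["chrom"].to_numpy()
    pos = ss["pos"].to_numpy()
    retained_idx: List[int] = []
    absorbed: Dict[str, List[str]] = {}
    by_chrom: Dict[str, List[int]] = {}
    for i in range(len(ss)):
        hit = None
        for j in by_chrom.get(chroms[i], []):
            if abs(pos[i] - pos[j]) <= window and (D[:, i] @ D[:, j]) ** 2 > r2:
                hit = j
                break
        if hit is None:
            retained_idx.append(i)
            absorbed[ids[i]] = []
            by_chrom.setdefault(chroms[i], []).append(i)
        else:
            absorbed[ids[hit]].append(ids[i])
    return ClumpedSet([ids[i] for i in retained_idx], absorbed)


def inverse_normal_transform(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom offsets, mid-ranked ties."""
    x = np.asarray(x, dtype=float)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 3 / 8) / (len(x) + 1 / 4))


def adjusted_trait(trait: np.ndarray, covariates: Optional[np.ndarray] = None) -> np.ndarray:
    """Residualize the trait on covariates, then inverse-normal transform."""
    y = np.asarray(trait, dtype=float)
    if covariates is not None and np.size(covariates):
        C = np.column_stack([np.ones(len(y)), np.asarray(covariates)])
        beta, *_ = np.linalg.lstsq(C, y, rcond=None)
        y = y - C @ beta
    return inverse_normal_transform(y)


@dataclass
class PRSResult:
    threshold: float
    variant_ids: List[str]
    scores: np.ndarray
    r2: float


def build_prs(
    dosages: pd.DataFrame,
    sumstats: pd.DataFrame,
    clumped: ClumpedSet,
    p_threshold: float,
    trait: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    regions: Optional[RegionSet] = None,
) -> PRSResult:
    """Score individuals on clumped, thresholded (optionally region-restricted)
    variants and report incremental R^2.

    score_i = sum_j beta_j dosage_ij; incremental R^2 is the squared Pearson
    correlation of the score with the covariate-adjusted, inverse-normal
    trait. Zero selected variants give all-zero scores and NaN R^2.
    """
    ss = sumstats.set_index("id")
    sel = [v for v in clumped.retained if ss.loc[v, "p"] <= p_threshold]
    if regions is not None:
        sel = [
            v
            for v in sel
            if regions.overlaps_points(ss.loc[v, "chrom"], int(ss.loc[v, "pos"]))[0]
        ]
    y = adjusted_trait(trait, covariates)
    if not sel:
        return PRSResult(p_threshold, [], np.zeros(len(dosages)), float("nan"))
    betas = ss.loc[sel, "beta"].to_numpy(dtype=float)
    scores = dosages[sel].to_numpy(dtype=float) @ betas
    if np.std(scores) == 0:
        r2 = float("nan")
    else:
        r2 = float(np.corrcoef(scores, y)[0, 1] ** 2)
    return PRSResult(p_threshold, sel, scores, r2)


def permutation_enrichment(
    prs_result: PRSResult,
    pool: Sequence[str],
    dosages: pd.DataFrame,
    sumstats: pd.DataFrame,
    trait: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> Tuple[float, np.ndarray]:
    """One-tailed permutation p for the observed PRS R^2.

    Draws ``n_perm`` size-matched variant sets uniformly from the
    genome-wide clumped+thresholded ``pool``, rebuilding the score and
    incremental R^2 for each; p = (1 + #{R2_perm >= R2_obs}) / (1 + n_perm).
    """
    pool = list(pool)
    m = len(prs_result.variant_ids)
    if m > len(pool):
        raise ValueError("observed set larger than pool")
    y = adjusted_trait(trait, covariates)
    yz = (y - y.mean()) / y.std()
    ss = sumstats.set_index("id")
    betas = ss.loc[pool, "beta"].to_numpy(dtype=float)
    D = dosages[pool].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    n = len(D)
    r2_perm = np.empty(n_perm)
    for t in range(n_perm):
        idx = rng.choice(len(pool), size=m, replace=False)
        s = D[:, idx] @ betas[idx]
        sd = s.std()
        r2_perm[t] = 0.0 if sd == 0 else ((s - s.mean()) @ yz / n / sd) ** 2
    p = (1 + int((r2_perm >= prs_result.r2).sum())) / (1 + n_perm)
    return float(p), r2_perm


def gwas_overlap_enrichment(
    clumped_sumstats: pd.DataFrame,
    significant_ids: Sequence[str],
    regions: RegionSet,
) -> Tuple[float, float]:
    """Fold and one-tailed hypergeometric p for GWAS variants in regions.

    Population = clumped variants (N); successes = genome-wide-significant
    among them (K); sample = clumped variants inside ``regions`` (n);
    hits = significant inside (k). fold = (k/n) / (K/N); p = P[X >= k].
    """
    sig = set(significant_ids)
    cs = clumped_sumstats.reset_index(drop=True)
    in_region = np.zeros(len(cs), dtype=bool)
    for chrom, sub in cs.groupby("chrom", sort=False):
        in_region[sub.index.to_numpy()] = regions.overlaps_points(
            chrom, sub["pos"].to_numpy()
        )
    clumped_sumstats = cs
    is_sig = clumped_sumstats["id"].isin(sig).to_numpy()
    N = len(clumped_sumstats)
    K = int(is_sig.sum())
    n = int(in_region.sum())
    k = int((is_sig & in_region).sum())
    if n == 0:
        return float("nan"), float("nan")
    fold = (k / n) / (K / N) if K > 0 else float("nan")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return fold, p


def peak_overlap_null(
    dmrs: RegionSet,
    peaks: RegionSet,
    genome: GenomeSpec,
    blacklist: Optional[RegionSet] = None,
    n: int = 1000,
    seed: int = 0,
    bin_size: int = 1000,
) -> Dict[str, float]:
    """Empirical and hypergeometric enrichment of peak overlap among DMRs.

    Observed = % of DMRs overlapping >= 1 peak. Null draws re-place the same
    number of intervals with the original lengths uniformly on their own
    chromosomes, avoiding the blacklist; p_emp = (1 + #{null >= obs})/(1+n).
    The hypergeometric p comes from the 2 x 2 of ``bin_size`` genome bins
    cross-classified by DMR and peak overlap.
    """
    rng = np.random.default_rng(seed)
    dmr_list = list(dmrs)
    if len(dmr_list) == 0:
        raise ValueError("no DMRs")
    if len(peaks) == 0:
        return {"observed_pct": 0.0, "p_emp": 1.0, "p_hyper": 1.0, "null_mean": 0.0}

    def pct_overlap(regions: Sequence[Region]) -> float:
        hits = sum(
            1
            for r in regions
            if peaks.overlaps_intervals(r.chrom, r.start, r.end)[0]
        )
        return 100.0 * hits / len(regions)

    observed = pct_overlap(dmr_list)
    null = np.empty(n)
    lengths = {c: genome.length(c) for c in genome.names}
    for t in range(n):
        placed = []
        for r in dmr_list:
            L = len(r)
            hi = lengths[r.chrom] - L
            for _ in range(50):
                s = int(rng.integers(0, max(hi, 1)))
                if blacklist is None or not blacklist.overlaps_intervals(r.chrom, s, s + L)[0]:
                    break
            placed.append(Region(r.chrom, s, s + L))
        null[t] = pct_overlap(placed)
    p_emp = (1 + int((null >= observed).sum())) / (1 + n)
    # hypergeometric on genome bins
    bins = genome.bin_table(bin_size)
    in_peak = np.zeros(len(bins), dtype=bool)
    in_dmr = np.zeros(len(bins), dtype=bool)
    for chrom, sub in bins.groupby("chrom", sort=False):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        in_peak[sub.index] = peaks.overlaps_intervals(chrom, s, e)
        in_dmr[sub.index] = dmrs.overlaps_intervals(chrom, s, e)
    N_b = len(bins)
    K_b = int(in_peak.sum())
    n_b = int(in_dmr.sum())
    k_b = int((in_peak & in_dmr).sum())
    p_hyper = float(stats.hypergeom.sf(k_b - 1, N_b, K_b, n_b))
    return {
        "observed_pct": observed,
        "p_emp": float(p_emp),
        "p_hyper": p_hyper,
        "null_mean": float(null.mean()),
    }
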