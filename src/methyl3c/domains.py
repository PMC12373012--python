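"""Interaction-domain calling, insulation scores and differential boundaries.

Domains are called per cell from band-limited imputed matrices with a
TopDom-style diamond signal: boundaries are significance-tested local minima
of the mean contact intensity crossing each bin boundary. Cell-type boundary
probabilities (fraction of cells with a boundary in a 25 kb bin) feed a
K x 2 chi-squared test, z-transformed with the Wilson-Hilferty cube-root
approximation; differential boundaries must satisfy all five criteria:
z > 1.960, probability spread > 0.05, local boundary-probability peak,
local insulation valley and BH FDR < 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .contacts import ImputedMatrix

__all__ = [
    "Z_CUTOFF",
    "DomainSet",
    "diamond_signal",
    "local_extrema",
    "call_domains",
    "insulation_score",
    "wilson_hilferty_z",
    "differential_boundaries",
]

# 97.5th percentile of the standard normal: the differential-boundary z cutoff
Z_CUTOFF = 1.960


@dataclass
class DomainSet:
    cell_id: str
    chrom: str
    resolution: int
    boundaries: np.ndarray  # boundary positions, in bins
    domains: List[Tuple[int, int]]  # half-open bin intervals
    insulation: np.ndarray  # per-bin insulation score


def diamond_signal(mat: np.ndarray, w: int) -> np.ndarray:
    """Mean of the w x w submatrix (i-w..i-1) x (i..i+w-1) per boundary i.

    Truncated at chromosome edges; entry 0 and n are edges with no diamond
    and get NaN.
    """
    n = mat.shape[0]
    sig = np.full(n + 1, np.nan)
    for i in range(1, n):
        r0, r1 = max(0, i - w), i
        c0, c1 = i, min(n, i + w)
        sig[i] = mat[r0:r1, c0:c1].mean()
    return sig


def local_extrema(x: np.ndarray, mode: str = "min") -> np.ndarray:
    """Indices of local minima/maxima with plateau handling.

    A plateau counts once, at its center (ties broken leftward); NaN entries
    separate segments and array edges never qualify.
    """
    sign = 1.0 if mode == "min" else -1.0
    v = sign * np.asarray(x, dtype=float)
    out = []
    i = 0
    n = len(v)
    while i < n:
        if not np.isfinite(v[i]):
            i += 1
            continue
        j = i
        while j + 1 < n and np.isfinite(v[j + 1]) and v[j + 1] == v[i]:
            j += 1
        left_ok = i > 0 and np.isfinite(v[i - 1]) and v[i - 1] > v[i]
        right_ok = j < n - 1 and np.isfinite(v[j + 1]) and v[j + 1] > v[i]
        if left_ok and right_ok:
            out.append((i + j) // 2)
        i = j + 1
    return np.array(out, dtype=int)


def insulation_score(mat: np.ndarray, window: int = 10) -> np.ndarray:
    """Per-bin log2 ratio of the local diamond mean to its chromosome average."""
    n = mat.shape[0]
    sig = diamond_signal(mat, window)[1:n]  # boundaries 1..n-1
    valid = np.isfinite(sig) & (sig > 0)
    chrom_mean = sig[valid].mean() if valid.any() else np.nan
    out = np.full(n, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        out[1:n] = np.where(valid & (chrom_mean > 0), np.log2(sig / chrom_mean), np.nan)
    return out


def call_domains(
    imp: ImputedMatrix,
    w: int = 5,
    p_threshold: float = 0.05,
    insulation_window: int = 10,
) -> DomainSet:
    """TopDom-style domain calling on one cell x chromosome imputed matrix.

    Boundaries are local minima of the w-bin diamond signal whose diamond
    entries are significantly lower (one-tailed rank-sum, p < 0.05) than the
    entries of the flanking diamonds at i-w and i+w. Domains are the
    intervals between consecutive boundaries.
    """
    mat = imp.matrix
    n = mat.shape[0]
    if n < 2 * w:
        return DomainSet(imp.cell_id, imp.chrom, imp.resolution, np.array([], int), [], np.full(n, np.nan))
    sig = diamond_signal(mat, w)
    candidates = local_extrema(sig, mode="min")
    boundaries = []
    for i in candidates:
        r0, r1 = max(0, i - w), i
        c0, c1 = i, min(n, i + w)
        diamond = mat[r0:r1, c0:c1].ravel()
        # flanks are the within-region triangles up- and downstream: at a true
        # boundary the cross-region diamond is depleted relative to both
        flank = []
        up = mat[r0:r1, r0:r1]
        down = mat[c0:c1, c0:c1]
        for block in (up, down):
            iu = np.triu_indices(block.shape[0], k=1)
            if len(iu[0]):
                flank.append(block[iu])
        if not flank:
            continue
        flank = np.concatenate(flank)
        if np.ptp(np.concatenate([diamond, flank])) == 0:
            continue
        p = stats.mannwhitneyu(diamond, flank, alternative="less").pvalue
        if p < p_threshold:
            boundaries.append(i)
    boundaries = np.array(boundaries, dtype=int)
    edges = [0, *boundaries.tolist(), n]
    domains = [(a, b) for a, b in zip(edges[:-1], edges[1:]) if b > a]
    ins = insulation_score(mat, insulation_window)
    return DomainSet(imp.cell_id, imp.chrom, imp.resolution, boundaries, domains, ins)


def wilson_hilferty_z(chi2_stat, df: int):
    """Cube-root normal transform of a chi-squared statistic."""
    x = np.asarray(chi2_stat, dtype=float) / df
    return (np.cbrt(x) - (1 - 2 / (9 * df))) / np.sqrt(2 / (9 * df))


def boundary_probabilities(
    domain_sets: Sequence[DomainSet], labels: Sequence[str], n_bins: int
) -> pd.DataFrame:
    """Per-bin, per-type fraction of cells with a detected boundary."""
    labels = np.asarray(labels)
    types = sorted(set(labels))
    counts = {t: np.zeros(n_bins) for t in types}
    totals = {t: 0 for t in types}
    for ds, lab in zip(domain_sets, labels):
        totals[lab] += 1
        counts[lab][ds.boundaries[ds.boundaries < n_bins]] += 1
    out = pd.DataFrame({"bin": np.arange(n_bins)})
    for t in types:
        out[f"prob_{t}"] = counts[t] / max(totals[t], 1)
        out[f"count_{t}"] = counts[t]
        out[f"n_{t}"] = totals[t]
    return out


def differential_boundaries(
    domain_sets: Sequence[DomainSet],
    labels: Sequence[str],
    insulation_by_type: Dict[str, np.ndarray],
    n_bins: int,
    z_cutoff: float = Z_CUTOFF,
    prob_diff_min: float = 0.05,
    fdr: float = 0.001,
) -> pd.DataFrame:
    """Five-criteria differential-boundary detection on one chromosome.

    ``domain_sets`` are per-cell calls on the same chromosome;
    ``insulation_by_type`` the cell-type pseudobulk insulation tracks. For
    each 25 kb bin a K x 2 chi-squared statistic on boundary presence is
    z-transformed (Wilson-Hilferty, df = K-1); a bin is differential iff
    z > ``z_cutoff``, the max-min boundary-probability spread exceeds
    ``prob_diff_min``, the bin is a local maximum of the aggregate boundary
    probability and a local minimum of the mean insulation, and the
    BH-adjusted chi-squared p is below ``fdr``.
    """
    labels = np.asarray(labels)
    types = sorted(set(labels))
    K = len(types)
    probs = boundary_probabilities(domain_sets, labels, n_bins)
    count = probs[[f"count_{t}" for t in types]].to_numpy()
    n_cells = probs[[f"n_{t}" for t in types]].to_numpy().astype(float)
    prob = probs[[f"prob_{t}" for t in types]].to_numpy()
    with_b = count
    without_b = n_cells - count
    tot_with = with_b.sum(axis=1)
    tot_all = n_cells.sum(axis=1)
    p_pool = np.divide(tot_with, tot_all, out=np.zeros_like(tot_with), where=tot_all > 0)
    e_with = n_cells * p_pool[:, None]
    e_without = n_cells * (1 - p_pool)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(e_with > 0, (with_b - e_with) ** 2 / e_with, 0.0).sum(axis=1)
        chi2 += np.where(e_without > 0, (without_b - e_without) ** 2 / e_without, 0.0).sum(axis=1)
    low_power = ((e_with < 1) | (e_without < 1)).any(axis=1) & (tot_with > 0)
    df = K - 1
    z = wilson_hilferty_z(chi2, df)
    pvals = stats.chi2.sf(chi2, df)
    q = multipletests(pvals, method="fdr_bh")[1]
    agg_prob = np.divide(tot_with, tot_all, out=np.zeros_like(tot_with), where=tot_all > 0)
    peaks = set(local_extrema(agg_prob, mode="max").tolist())
    mean_ins = np.nanmean(np.stack([insulation_by_type[t][:n_bins] for t in types]), axis=0)
    valleys = set(local_extrema(mean_ins, mode="min").tolist())
    spread = prob.max(axis=1) - prob.min(axis=1)
    out = pd.DataFrame(
        {
            "bin": np.arange(n_bins),
            "chi2": chi2,
            "z": z,
            "p": pvals,
            "q": q,
            "aggregate_prob": agg_prob,
            "prob_spread": spread,
            "flag_z": z > z_cutoff,
            "flag_prob_diff": spread > prob_diff_min,
            "flag_peak": [b in peaks for b in range(n_bins)],
            "flag_valley": [b in valleys for b in range(n_bins)],
            "flag_fdr": q < fdr,
            "low_power": low_power,
        }
    )
    for t in types:
        out[f"prob_{t}"] = probs[f"prob_{t}"]
    out["differential"] = (
        out["flag_z"] & out["flag_prob_diff"] & out["flag_peak"] & out["flag_valley"] & out["flag_fdr"]
    )
    return out
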