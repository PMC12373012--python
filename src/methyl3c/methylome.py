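"""Methylation-modality analyses: cell QC, 5 kb hypomethylation scores,
LSI embedding, gene-body mCG quantification and marker-gene calling.

QC follows the standard snm3C filters: non-conversion estimate (mCCC) below
1.5%, global mCG above 0.5, global mCH below 0.15, total contacts between
100,000 and 500,000, and at least one intra-chromosomal contact on every
autosome after blacklist filtering. All comparisons are strict inequalities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import TruncatedSVD
from statsmodels.stats.multitest import multipletests

from .cells import CellContacts, CellMethylome, filter_blacklist
from .genome import GenomeSpec, Region, RegionSet

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "QCMetrics",
    "qc_filter",
    "qc_table",
    "BinScoreMatrix",
    "bin_hypomethylation",
    "lsi_embed",
    "GeneBodyMCG",
    "gene_body_mcg",
    "call_mcg_markers",
]


@dataclass(frozen=True)
class QCThresholds:
    mccc_max: float = 0.015
    mcg_min: float = 0.5
    mch_max: float = 0.15
    contacts_min: int = 100_000
    contacts_max: int = 500_000


@dataclass
class QCMetrics:
    cell_id: str
    mccc_rate: float
    global_mcg: float
    global_mch: float
    n_contacts: int
    intra_per_autosome: Dict[str, int]
    passed: bool
    fail_reasons: Tuple[str, ...]


def qc_filter(
    methylome: CellMethylome,
    contacts: CellContacts,
    genome: GenomeSpec,
    blacklist: Optional[RegionSet] = None,
    thresholds: QCThresholds = QCThresholds(),
) -> QCMetrics:
    """Compute QC metrics for one cell and evaluate the five pass criteria.

    Global fractions are coverage-weighted; mCH covers all non-CG contexts
    and mCCC the CCC subset. A context with zero coverage leaves its
    criterion vacuously satisfied (no evidence against the cell), except CG:
    zero CG coverage fails with reason ``no_coverage``.
    """
    if blacklist is not None:
        contacts = filter_blacklist(contacts, blacklist)
    cg = methylome.context("CG")
    non_cg = methylome.sites[methylome.sites["context"] != "CG"]
    ccc = methylome.context("CCC")
    reasons = []
    cg_cov = cg["cov"].sum()
    if cg_cov == 0:
        return QCMetrics(
            methylome.cell_id, float("nan"), float("nan"), float("nan"),
            contacts.n_contacts(), {}, False, ("no_coverage",),
        )
    mcg = float(cg["mc"].sum() / cg_cov)
    mch = float(non_cg["mc"].sum() / non_cg["cov"].sum()) if non_cg["cov"].sum() else float("nan")
    mccc = float(ccc["mc"].sum() / ccc["cov"].sum()) if ccc["cov"].sum() else float("nan")
    if np.isfinite(mccc) and not mccc < thresholds.mccc_max:
        reasons.append("mccc")
    if not mcg > thresholds.mcg_min:
        reasons.append("mcg")
    if np.isfinite(mch) and not mch < thresholds.mch_max:
        reasons.append("mch")
    n = contacts.n_contacts()
    if not (thresholds.contacts_min < n < thresholds.contacts_max):
        reasons.append("contacts")
    per_auto = contacts.intra_per_chrom().to_dict()
    if any(per_auto.get(chrom, 0) < 1 for chrom in genome.names):
        reasons.append("autosome_coverage")
    return QCMetrics(
        methylome.cell_id, mccc, mcg, mch, n,
        {c: int(per_auto.get(c, 0)) for c in genome.names},
        len(reasons) == 0, tuple(reasons),
    )


def qc_table(
    methylomes: Sequence[CellMethylome],
    contacts: Sequence[CellContacts],
    genome: GenomeSpec,
    blacklist: Optional[RegionSet] = None,
    thresholds: QCThresholds = QCThresholds(),
) -> pd.DataFrame:
    rows = []
    for m, c in zip(methylomes, contacts):
        q = qc_filter(m, c, genome, blacklist, thresholds)
        rows.append(
            {
                "cell_id": q.cell_id,
                "mccc_rate": q.mccc_rate,
                "global_mcg": q.global_mcg,
                "global_mch": q.global_mch,
                "n_contacts": q.n_contacts,
                "passed": q.passed,
                "fail_reasons": ",".join(q.fail_reasons),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class BinScoreMatrix:
    """Cells x bins hypomethylation indicators with a missing-data mask."""

    cell_ids: List[str]
    bins: pd.DataFrame  # chrom, start, end
    indicator: np.ndarray  # cells x bins, {0,1}
    pvalues: np.ndarray  # cells x bins, NaN where no coverage
    missing: np.ndarray  # cells x bins bool
    coverage: np.ndarray  # cells x bins total CG coverage


def hypomethylation_pvalue(mc, cov, global_mcg):
    """One-tailed binomial probability of observing <= mc methylated calls.

    Under the cell's global mCG rate, a small value flags a bin methylated
    well below the cell's expectation (a candidate regulatory region).
    """
    return stats.binom.cdf(mc, cov, global_mcg)


def bin_hypomethylation(
    methylomes: Sequence[CellMethylome],
    genome: GenomeSpec,
    bin_size: int = 5000,
    blacklist: Optional[RegionSet] = None,
    alpha: float = 0.05,
) -> BinScoreMatrix:
    """Score genome bins per cell for hypomethylation relative to the cell mean.

    For each cell and covered bin, the score is the exact binomial lower-tail
    probability P[X <= mc | Binomial(cov, global mCG)]; the binary indicator
    is 1 when that probability falls below ``alpha``. Bins overlapping the
    blacklist are dropped; zero-coverage bins are missing.
    """
    bin_df = genome.bin_table(bin_size)
    if blacklist is not None:
        drop = np.zeros(len(bin_df), dtype=bool)
        for chrom, sub in bin_df.groupby("chrom", sort=False):
            drop[sub.index] = blacklist.overlaps_intervals(
                chrom, sub["start"].to_numpy(), sub["end"].to_numpy()
            )
        bin_df = bin_df[~drop].reset_index(drop=True)
    # global flat index per retained bin
    key = {(r.chrom, r.bin): i for i, r in enumerate(bin_df.itertuples(index=False))}
    n_bins = len(bin_df)
    n_cells = len(methylomes)
    mc_mat = np.zeros((n_cells, n_bins))
    cov_mat = np.zeros((n_cells, n_bins))
    for ci, cell in enumerate(methylomes):
        cg = cell.cg()
        for chrom, sub in cg.groupby("chrom", sort=False):
            b = sub["pos"].to_numpy() // bin_size
            idx = np.array([key.get((chrom, bi), -1) for bi in b])
            ok = idx >= 0
            np.add.at(mc_mat[ci], idx[ok], sub["mc"].to_numpy()[ok])
            np.add.at(cov_mat[ci], idx[ok], sub["cov"].to_numpy()[ok])
    globals_ = np.array([m.global_fraction("CG") for m in methylomes])
    missing = cov_mat == 0
    pvals = np.full((n_cells, n_bins), np.nan)
    for ci in range(n_cells):
        cov = cov_mat[ci]
        nz = ~missing[ci]
        pvals[ci, nz] = hypomethylation_pvalue(mc_mat[ci, nz], cov[nz], globals_[ci])
    indicator = np.where(np.nan_to_num(pvals, nan=1.0) < alpha, 1.0, 0.0)
    return BinScoreMatrix(
        [m.cell_id for m in methylomes],
        bin_df[["chrom", "start", "end"]].reset_index(drop=True),
        indicator,
        pvals,
        missing,
        cov_mat,
    )


def lsi_embed(
    matrix: BinScoreMatrix,
    n_components: int = 30,
    coverage_corr_max: float = 0.8,
    random_state: int = 0,
) -> np.ndarray:
    """Latent semantic indexing of the binary hypomethylation matrix.

    TF-IDF weighting followed by truncated SVD; components whose absolute
    Spearman correlation with per-cell total coverage exceeds
    ``coverage_corr_max`` are dropped (they track sequencing depth, not
    biology).
    """
    X = matrix.indicator
    n_cells = X.shape[0]
    if n_components >= n_cells:
        warnings.warn("fewer cells than components; reducing")
        n_components = max(1, n_cells - 1)
    rowsum = X.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1
    tf = X / rowsum
    df_count = (X > 0).sum(axis=0)
    idf = np.log(1 + n_cells / (1 + df_count))
    tfidf = tf * idf
    svd = TruncatedSVD(n_components=n_components, random_state=random_state)
    emb = svd.fit_transform(tfidf)
    depth = matrix.coverage.sum(axis=1)
    keep = []
    for k in range(emb.shape[1]):
        rho = stats.spearmanr(emb[:, k], depth).statistic
        if not np.isfinite(rho) or abs(rho) <= coverage_corr_max:
            keep.append(k)
        else:
            logger.info("lsi: dropping component %d (|rho|=%.2f with coverage)", k, abs(rho))
    return emb[:, keep]


@dataclass
class GeneBodyMCG:
    """Cells x genes gene-body mCG fractions, raw and cell-normalized."""

    cell_ids: List[str]
    genes: List[Region]
    raw: np.ndarray  # cells x genes, NaN below min_cov
    normalized: np.ndarray  # raw / cell global mCG, capped
    mc: np.ndarray
    cov: np.ndarray

    @property
    def gene_names(self) -> List[str]:
        return [g.label or f"{g.chrom}:{g.start}-{g.end}" for g in self.genes]


def _small_covered_genes(genes: Sequence[Region], max_len: int = 200, frac: float = 0.9) -> set:
    """Indices of genes <= max_len bp whose span is >=90% covered by other genes."""
    out = set()
    for i, g in enumerate(genes):
        if len(g) > max_len:
            continue
        others = RegionSet([h for j, h in enumerate(genes) if j != i and h.chrom == g.chrom])
        covered = 0
        last_end = g.start
        for h in others:
            if h.start >= g.end or h.end <= g.start:
                continue
            s, e = max(h.start, last_end), min(h.end, g.end)
            if e > s:
                covered += e - s
                last_end = max(last_end, e)
        if covered >= frac * len(g):
            out.add(i)
    return out


def gene_body_mcg(
    methylomes: Sequence[CellMethylome],
    genes: RegionSet,
    min_cov: int = 5,
    blacklist: Optional[RegionSet] = None,
    norm_cap: float = 10.0,
) -> GeneBodyMCG:
    """Average gene-body mCG per cell, normalized by the cell's global mCG.

    Genes overlapping the blacklist and small genes (<=200 bp) mostly covered
    by other genes are excluded. Entries with coverage below ``min_cov`` are
    missing; the normalized fraction is capped at ``norm_cap`` to bound cells
    with very low global methylation.
    """
    gene_list = list(genes)
    if blacklist is not None:
        gene_list = [g for g in gene_list if not blacklist.overlaps_region(g)]
    drop = _small_covered_genes(gene_list)
    gene_list = [g for i, g in enumerate(gene_list) if i not in drop]
    n_cells, n_genes = len(methylomes), len(gene_list)
    mc = np.zeros((n_cells, n_genes))
    cov = np.zeros((n_cells, n_genes))
    by_chrom: Dict[str, List[Tuple[int, Region]]] = {}
    for gi, g in enumerate(gene_list):
        by_chrom.setdefault(g.chrom, []).append((gi, g))
    for ci, cell in enumerate(methylomes):
        cg = cell.cg()
        for chrom, sub in cg.groupby("chrom", sort=False):
            if chrom not in by_chrom:
                continue
            pos = sub["pos"].to_numpy()
            mcs = sub["mc"].to_numpy()
            covs = sub["cov"].to_numpy()
            for gi, g in by_chrom[chrom]:
                lo, hi = np.searchsorted(pos, [g.start, g.end])
                mc[ci, gi] = mcs[lo:hi].sum()
                cov[ci, gi] = covs[lo:hi].sum()
    raw = np.where(cov >= min_cov, mc / np.where(cov > 0, cov, 1), np.nan)
    globals_ = np.array([m.global_fraction("CG") for m in methylomes])
    normalized = np.minimum(raw / globals_[:, None], norm_cap)
    return GeneBodyMCG([m.cell_id for m in methylomes], gene_list, raw, normalized, mc, cov)


def _rank_sum(in_vals: np.ndarray, out_vals: np.ndarray) -> Tuple[float, float]:
    """Two-sided rank-sum p and the AUROC of out > in (hypomethylation sense)."""
    if len(in_vals) == 0 or len(out_vals) == 0:
        return 1.0, 0.5
    if np.ptp(np.concatenate([in_vals, out_vals])) == 0:
        return 1.0, 0.5  # constant gene: ties carry no signal
    res = stats.mannwhitneyu(out_vals, in_vals, alternative="two-sided", method="auto")
    auroc = res.statistic / (len(in_vals) * len(out_vals))
    return float(res.pvalue), float(auroc)


def call_mcg_markers(
    gbm: GeneBodyMCG,
    labels: Sequence[str],
    mode: str = "cluster",
    min_informative_cells: int = 10,
    min_informative_counts: int = 10,
) -> pd.DataFrame:
    """One-vs-rest hypomethylation marker genes per cell type.

    ``cluster`` mode requires a hypomethylation difference >= 0.15 in the
    average normalized fraction, BH-adjusted rank-sum p <= 0.01 and
    AUROC >= 0.75; ``dmg`` mode requires a difference >= 0.1 and BH p < 0.05.
    Genes are testable for a type only when >= 10 of its cells carry >= 10
    methylated or unmethylated counts over the gene body. ``unique`` flags
    genes passing for exactly one type.
    """
    if mode not in ("cluster", "dmg"):
        raise ValueError("mode must be 'cluster' or 'dmg'")
    labels = np.asarray(labels)
    types = sorted(set(labels))
    rows = []
    for t in types:
        in_mask = labels == t
        if in_mask.sum() < 2:
            warnings.warn(f"type {t} has <2 cells; skipped")
            continue
        informative = (
            (gbm.mc[in_mask] >= min_informative_counts)
            | ((gbm.cov[in_mask] - gbm.mc[in_mask]) >= min_informative_counts)
        ).sum(axis=0)
        pvals, keep_idx = [], []
        stats_rows = []
        for gi in range(len(gbm.genes)):
            if informative[gi] < min_informative_cells:
                continue
            vin = gbm.normalized[in_mask, gi]
            vout = gbm.normalized[~in_mask, gi]
            vin, vout = vin[np.isfinite(vin)], vout[np.isfinite(vout)]
            p, auroc = _rank_sum(vin, vout)
            mean_in = float(np.mean(vin)) if len(vin) else np.nan
            mean_out = float(np.mean(vout)) if len(vout) else np.nan
            pvals.append(p)
            keep_idx.append(gi)
            stats_rows.append((mean_in, mean_out, auroc))
        if not pvals:
            continue
        q = multipletests(pvals, method="fdr_bh")[1]
        for (gi, p, qv, (mi, mo, auroc)) in zip(keep_idx, pvals, q, stats_rows):
            diff = mo - mi  # positive = hypomethylated in the tested type
            if mode == "cluster":
                passed = diff >= 0.15 and qv <= 0.01 and auroc >= 0.75
            else:
                passed = diff >= 0.1 and qv < 0.05
            rows.append(
                {
                    "gene": gbm.gene_names[gi],
                    "cell_type": t,
                    "mean_in": mi,
                    "mean_out": mo,
                    "difference": diff,
                    "auroc": auroc,
                    "p": p,
                    "q": qv,
                    "passed": bool(passed),
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        n_pass = table[table["passed"]].groupby("gene").size()
        table["unique"] = table.apply(
            lambda r: bool(r["passed"] and n_pass.get(r["gene"], 0) == 1), axis=1
        )
    else:
        table["unique"] = pd.Series(dtype=bool)
    return table
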