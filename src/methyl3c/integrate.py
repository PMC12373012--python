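"""Cross-modality integration of gene-body mCG and RNA expression.

Gene-body mCG anti-correlates with transcription, so the normalized mCG
matrix is sign-reversed before canonical correlation with the RNA matrix;
the canonical scores of both modalities live in a shared space where
matched cell types co-locate. Agreement is quantified by a min-sum overlap
score over joint graph clusters and by the adjusted Rand index of
neighbor-transferred labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

__all__ = ["CoEmbedding", "coembed", "overlap_scores", "rna_markers", "top_variable_genes"]


@dataclass
class CoEmbedding:
    embedding: np.ndarray  # (n_mcg + n_rna) x n_cc
    modality: np.ndarray  # "mcg" | "rna" per row
    cell_ids: List[str]
    genes: List[str]


def top_variable_genes(rna_lognorm: pd.DataFrame, n: int = 2000) -> List[str]:
    """Most variable genes of a cells x genes log-normalized matrix."""
    var = rna_lognorm.var(axis=0)
    return list(var.sort_values(ascending=False).index[:n])


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def coembed(
    mcg_normalized: pd.DataFrame,
    rna_lognorm: pd.DataFrame,
    n_cc: int = 20,
    min_shared: int = 50,
) -> CoEmbedding:
    """Canonical-correlation co-embedding of mCG and RNA cells.

    Both inputs are cells x genes. The mCG matrix (normalized gene-body
    fractions) is sign-reversed so that marker genes point in the same
    direction as expression, then both matrices are per-gene standardized
    and the SVD of their cross-product yields paired canonical scores,
    L2-normalized per cell and stacked.
    """
    shared = [g for g in rna_lognorm.columns if g in set(mcg_normalized.columns)]
    if len(shared) < min_shared:
        raise ValueError(f"only {len(shared)} shared genes (< {min_shared})")
    Xm = -mcg_normalized[shared].to_numpy(dtype=float)  # sign reversal
    Xm = np.nan_to_num(Xm, nan=np.nanmean(Xm))
    Xr = rna_lognorm[shared].to_numpy(dtype=float)
    Xm = _standardize(Xm)
    Xr = _standardize(Xr)
    K = Xm @ Xr.T
    n_cc = min(n_cc, min(K.shape) - 1)
    U, s, Vt = np.linalg.svd(K, full_matrices=False)
    em = U[:, :n_cc]
    er = Vt.T[:, :n_cc]
    for E in (em, er):
        norms = np.linalg.norm(E, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        E /= norms
    emb = np.vstack([em, er])
    modality = np.array(["mcg"] * len(em) + ["rna"] * len(er))
    ids = list(mcg_normalized.index) + list(rna_lognorm.index)
    return CoEmbedding(emb, modality, ids, shared)


def overlap_scores(
    coemb: CoEmbedding,
    labels_mcg: Sequence[str],
    labels_rna: Sequence[str],
    k: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> Dict[str, object]:
    """Cross-modality agreement in the co-embedding space.

    Cells of both modalities are jointly clustered (k-NN graph + Leiden
    modularity). overlap(A, B) sums, over joint clusters, the minimum of the
    fraction of modality-1 type-A cells and modality-2 type-B cells assigned
    to the cluster; identically distributed types score 1, disjoint types 0.
    The ARI compares neighbor-transferred labels with native labels.
    """
    emb = coemb.embedding
    labels_mcg = np.asarray(labels_mcg)
    labels_rna = np.asarray(labels_rna)
    is_mcg = coemb.modality == "mcg"
    nn = NearestNeighbors(n_neighbors=min(k + 1, len(emb))).fit(emb)
    _, idx = nn.kneighbors(emb)
    edges = sorted({(min(i, j), max(i, j)) for i, row in enumerate(idx) for j in row[1:]})
    g = igraph.Graph(n=len(emb), edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    clusters = np.array(part.membership)
    types_m = sorted(set(labels_mcg))
    types_r = sorted(set(labels_rna))
    overlap = pd.DataFrame(0.0, index=types_m, columns=types_r)
    for a in types_m:
        ca = clusters[is_mcg][labels_mcg == a]
        if len(ca) == 0:
            warnings.warn(f"empty mCG type {a}")
            continue
        fa = pd.Series(ca).value_counts(normalize=True)
        for b in types_r:
            cb = clusters[~is_mcg][labels_rna == b]
            if len(cb) == 0:
                continue
            fb = pd.Series(cb).value_counts(normalize=True)
            common = set(fa.index) | set(fb.index)
            overlap.loc[a, b] = sum(
                min(fa.get(c, 0.0), fb.get(c, 0.0)) for c in common
            )
    # label transfer: majority native RNA label among cross-modality neighbors
    nn_rna = NearestNeighbors(n_neighbors=min(k, int((~is_mcg).sum()))).fit(emb[~is_mcg])
    _, ridx = nn_rna.kneighbors(emb[is_mcg])
    transferred = []
    for row in ridx:
        votes = pd.Series(labels_rna[row]).value_counts()
        transferred.append(votes.index[0])
    ari = adjusted_rand_score(labels_mcg, transferred)
    confusion = pd.crosstab(
        pd.Series(labels_mcg, name="mcg"),
        pd.Series(transferred, name="transferred"),
        normalize="index",
    )
    return {"overlap": overlap, "ari": float(ari), "confusion": confusion, "clusters": clusters}


def log_normalize(counts: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """Library-size log normalization of a genes x cells count matrix."""
    lib = counts.sum(axis=0).astype(float)
    lib[lib == 0] = 1.0
    return np.log1p(counts / lib * scale)


def rna_markers(
    counts: pd.DataFrame,
    labels: Sequence[str],
    min_counts: int = 3,
    min_cells: int = 3,
    min_pct: float = 0.25,
    lfc_min: float = 0.25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-vs-rest positive RNA marker genes per cell type.

    ``counts`` is genes x cells (raw). Genes must show >= ``min_counts``
    counts in >= ``min_cells`` cells; candidate markers need a positive
    log2 fold change >= ``lfc_min``, non-zero expression in >= 25% of cells
    of the tested type or the rest, and Bonferroni-adjusted rank-sum
    p < 0.05. ``unique`` flags genes passing for exactly one type.
    """
    labels = np.asarray(labels)
    expressed = (counts >= min_counts).sum(axis=1) >= min_cells
    counts = counts[expressed]
    logn = log_normalize(counts)
    types = sorted(set(labels))
    rows = []
    n_tests = 0
    for t in types:
        in_mask = labels == t
        if in_mask.sum() < min_cells:
            warnings.warn(f"type {t} has <{min_cells} cells; skipped")
            continue
        for gene in counts.index:
            vin = logn.loc[gene].to_numpy()[in_mask]
            vout = logn.loc[gene].to_numpy()[~in_mask]
            pct_in = float((vin > 0).mean())
            pct_out = float((vout > 0).mean())
            if max(pct_in, pct_out) < min_pct:
                continue
            mean_in = float(np.expm1(vin).mean())
            mean_out = float(np.expm1(vout).mean())
            lfc = np.log2((mean_in + 1e-9) / (mean_out + 1e-9))
            if lfc < lfc_min:
                continue  # positive markers only
            if np.ptp(np.concatenate([vin, vout])) == 0:
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(vin, vout, alternative="greater").pvalue)
            n_tests += 1
            rows.append(
                {
                    "gene": gene,
                    "cell_type": t,
                    "log2fc": float(lfc),
                    "pct_in": pct_in,
                    "pct_out": pct_out,
                    "p": p,
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_bonf"] = np.minimum(table["p"] * len(counts.index), 1.0)
        table["passed"] = table["p_bonf"] < alpha
        n_pass = table[table["passed"]].groupby("gene").size()
        table["unique"] = table.apply(
            lambda r: bool(r["passed"] and n_pass.get(r["gene"], 0) == 1), axis=1
        )
    return table
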