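"""Single-cell contact-matrix imputation and contact-distance statistics.

Imputation follows the random-walk-with-restart scheme used for sparse
single-cell Hi-C: a uniform (2*pad+1)^2 convolution, row-stochastic
normalization, then the stationary restart distribution
``Q = restart * (I - (1-restart) P)^-1`` obtained iteratively, symmetrized
and optionally band-limited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import convolve2d
from sklearn.decomposition import TruncatedSVD

from .cells import CellContacts
from .genome import GenomeSpec

__all__ = [
    "ImputedMatrix",
    "impute_matrix",
    "impute_cells",
    "distance_stats",
    "short_long_ratio",
    "embed_conformation",
]


@dataclass
class ImputedMatrix:
    cell_id: str
    chrom: str
    resolution: int
    matrix: np.ndarray
    empty: bool = False


def _boxcar_renormalized(mat: np.ndarray, pad: int) -> np.ndarray:
    """Uniform (2*pad+1)^2 filter, truncated and renormalized at the edges."""
    if pad == 0:
        return mat.copy()
    k = np.ones((2 * pad + 1, 2 * pad + 1))
    num = convolve2d(mat, k, mode="same")
    den = convolve2d(np.ones_like(mat), k, mode="same")
    return num / den


def rwr(P: np.ndarray, restart: float = 0.5, tol: float = 1e-6, max_iter: int = 100) -> np.ndarray:
    """Random walk with restart on a row-stochastic matrix, solved iteratively.

    Converges to ``restart * (I - (1-restart) P)^-1`` row-wise.
    """
    n = P.shape[0]
    Q = np.eye(n)
    I = np.eye(n)
    for _ in range(max_iter):
        Q_next = restart * I + (1 - restart) * (Q @ P)
        delta = np.abs(Q_next - Q).max()
        Q = Q_next
        if delta < tol:
            break
    return Q


def impute_matrix(
    cell: CellContacts,
    genome: GenomeSpec,
    chrom: str,
    resolution: int,
    pad: int = 1,
    max_dist: Optional[int] = None,
    restart: float = 0.5,
    tol: float = 1e-6,
) -> ImputedMatrix:
    """Impute one cell's contact matrix on one chromosome.

    Steps: bin raw contacts, convolve with a uniform (2*pad+1)^2 filter
    (truncated and renormalized at chromosome edges), row-normalize, run the
    random walk with restart to convergence, symmetrize by (M + M^T)/2 and
    zero entries beyond ``max_dist`` when given.
    """
    raw = cell.binned(genome, chrom, resolution)
    if raw.sum() == 0:
        return ImputedMatrix(cell.cell_id, chrom, resolution, np.zeros_like(raw), empty=True)
    E = _boxcar_renormalized(raw, pad)
    rowsum = E.sum(axis=1, keepdims=True)
    P = np.divide(E, rowsum, out=np.zeros_like(E), where=rowsum > 0)
    Q = rwr(P, restart=restart, tol=tol)
    M = (Q + Q.T) / 2
    if max_dist is not None:
        band = max_dist // resolution
        n = M.shape[0]
        i, j = np.indices(M.shape, sparse=True)
        M = np.where(np.abs(i - j) <= band, M, 0.0)
    return ImputedMatrix(cell.cell_id, chrom, resolution, M)


def impute_cells(
    cells: Sequence[CellContacts],
    genome: GenomeSpec,
    resolution: int,
    pad: int = 1,
    max_dist: Optional[int] = None,
    restart: float = 0.5,
) -> Dict[str, List[ImputedMatrix]]:
    """Impute every cell on every chromosome; returns chrom -> list per cell."""
    out: Dict[str, List[ImputedMatrix]] = {c: [] for c in genome.names}
    for cell in cells:
        for chrom in genome.names:
            out[chrom].append(
                impute_matrix(cell, genome, chrom, resolution, pad, max_dist, restart)
            )
    return out


def short_long_ratio(
    cell: CellContacts,
    short_range: Tuple[int, int] = (100_000, 2_000_000),
    long_range: Tuple[int, int] = (10_000_000, 100_000_000),
) -> Tuple[int, int, float]:
    """Counts of short- and long-range intra contacts and their ratio.

    The ratio is NaN when the cell has no long-range contacts.
    """
    d = cell.distances()
    n_short = int(((d >= short_range[0]) & (d < short_range[1])).sum())
    n_long = int(((d >= long_range[0]) & (d < long_range[1])).sum())
    ratio = n_short / n_long if n_long > 0 else float("nan")
    return n_short, n_long, ratio


def distance_stats(
    cells: Sequence[CellContacts],
    labels: Sequence[str],
    focal_type: str,
    short_range: Tuple[int, int] = (100_000, 2_000_000),
    long_range: Tuple[int, int] = (10_000_000, 100_000_000),
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell short/long contact ratios and one-tailed rank-sum tests.

    Tests whether the focal type has higher ratios than each other type
    (one-tailed Wilcoxon rank-sum). Cells with zero long-range contacts are
    excluded from testing; their number is reported.
    """
    labels = np.asarray(labels)
    if focal_type not in labels:
        raise ValueError(f"focal type {focal_type!r} absent")
    rows = []
    for cell, lab in zip(cells, labels):
        n_s, n_l, ratio = short_long_ratio(cell, short_range, long_range)
        rows.append({"cell_id": cell.cell_id, "cell_type": lab, "n_short": n_s, "n_long": n_l, "ratio": ratio})
    per_cell = pd.DataFrame(rows)
    usable = per_cell[np.isfinite(per_cell["ratio"])]
    focal = usable.loc[usable["cell_type"] == focal_type, "ratio"]
    tests = []
    for t in sorted(set(labels) - {focal_type}):
        other = usable.loc[usable["cell_type"] == t, "ratio"]
        if len(other) == 0 or len(focal) == 0:
            p = float("nan")
        else:
            p = float(
                stats.mannwhitneyu(focal, other, alternative="greater").pvalue
            )
        tests.append(
            {
                "focal": focal_type,
                "other": t,
                "p": p,
                "n_focal": len(focal),
                "n_other": len(other),
                "n_excluded": int((~np.isfinite(per_cell["ratio"])).sum()),
            }
        )
    return per_cell, pd.DataFrame(tests)


def embed_conformation(
    imputed: Dict[str, List[ImputedMatrix]],
    n_components: int = 30,
    band: Tuple[int, int] = (1, 100),
    random_state: int = 0,
) -> np.ndarray:
    """Project imputed contact maps to a low-dimensional space.

    Per chromosome the off-diagonal band (bin offsets ``band[0]..band[1]``,
    i.e. 100 kb to 10 Mb at 100 kb resolution) is vectorized per cell,
    z-scored per pixel across cells (zero-variance pixels dropped), reduced
    by truncated SVD, and the per-chromosome factors are concatenated and
    reduced again to ``n_components``.
    """
    per_chrom = []
    n_cells = len(next(iter(imputed.values())))
    for chrom, mats in imputed.items():
        n = mats[0].matrix.shape[0]
        iu, ju = np.triu_indices(n, k=band[0])
        sel = (ju - iu) <= band[1]
        iu, ju = iu[sel], ju[sel]
        X = np.stack([m.matrix[iu, ju] for m in mats])
        sd = X.std(axis=0)
        keep = sd > 0
        if keep.sum() == 0:
            continue
        Xz = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
        k = min(n_components, min(Xz.shape) - 1)
        if k < 1:
            continue
        svd = TruncatedSVD(n_components=k, random_state=random_state)
        per_chrom.append(svd.fit_transform(Xz))
    if not per_chrom:
        return np.zeros((n_cells, 0))
    concat = np.hstack(per_chrom)
    k = min(n_components, min(concat.shape) - 1)
    if k < 1:
        return concat
    if concat.shape[1] <= n_components:
        return concat
    svd2 = TruncatedSVD(n_components=k, random_state=random_state)
    return svd2.fit_transform(concat)
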