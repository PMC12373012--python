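"""Per-cell containers: CpG methylomes and chromatin contact lists.

``CellMethylome`` stores strand-merged CpG counts (one record per CpG, keyed
by the position of the + strand cytosine, 0-based). ``CellContacts`` stores
pairwise contacts; intra-chromosomal pairs are ordered pos1 <= pos2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .genome import GenomeSpec, RegionSet

logger = logging.getLogger(__name__)

__all__ = ["CellMethylome", "CellContacts", "filter_blacklist"]

_METH_COLS = ["chrom", "pos", "context", "mc", "cov"]
_CONTACT_COLS = ["chrom1", "pos1", "chrom2", "pos2"]


@dataclass
class CellMethylome:
    cell_id: str
    sites: pd.DataFrame  # chrom, pos, context (CG/CH/CCC), mc, cov

    def __post_init__(self):
        df = self.sites
        if len(df) == 0:
            self.sites = pd.DataFrame(columns=_METH_COLS).astype(
                {"pos": np.int64, "mc": np.int64, "cov": np.int64}
            )
            return
        if (df["mc"] > df["cov"]).any():
            bad = df.index[df["mc"] > df["cov"]][0]
            raise ValueError(f"mc > cov at record {bad} of cell {self.cell_id}")
        if (df["mc"] < 0).any() or (df["cov"] < 0).any():
            raise ValueError("negative counts")
        self.sites = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
            drop=True
        )

    def cg(self) -> pd.DataFrame:
        return self.sites[self.sites["context"] == "CG"]

    def context(self, context: str) -> pd.DataFrame:
        return self.sites[self.sites["context"] == context]

    def global_fraction(self, context: str = "CG") -> float:
        """Coverage-weighted global methylation fraction for a context."""
        df = self.context(context)
        cov = df["cov"].sum()
        return float(df["mc"].sum() / cov) if cov > 0 else float("nan")

    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class CellContacts:
    cell_id: str
    pairs: pd.DataFrame  # chrom1, pos1, chrom2, pos2

    def __post_init__(self):
        df = self.pairs
        if len(df) == 0:
            self.pairs = pd.DataFrame(columns=_CONTACT_COLS).astype(
                {"pos1": np.int64, "pos2": np.int64}
            )
            return
        intra = df["chrom1"] == df["chrom2"]
        swap = intra & (df["pos1"] > df["pos2"])
        if swap.any():
            df = df.copy()
            p1 = df.loc[swap, "pos1"].to_numpy()
            df.loc[swap, "pos1"] = df.loc[swap, "pos2"].to_numpy()
            df.loc[swap, "pos2"] = p1
        self.pairs = df.reset_index(drop=True)

    @property
    def intra(self) -> pd.DataFrame:
        return self.pairs[self.pairs["chrom1"] == self.pairs["chrom2"]]

    @property
    def inter(self) -> pd.DataFrame:
        return self.pairs[self.pairs["chrom1"] != self.pairs["chrom2"]]

    def n_contacts(self) -> int:
        return len(self.pairs)

    def distances(self) -> np.ndarray:
        d = self.intra
        return (d["pos2"] - d["pos1"]).to_numpy()

    def intra_per_chrom(self) -> pd.Series:
        return self.intra.groupby("chrom1").size()

    def binned(self, genome: GenomeSpec, chrom: str, resolution: int) -> np.ndarray:
        """Dense symmetric raw contact-count matrix for one chromosome."""
        n = genome.n_bins(chrom, resolution)
        mat = np.zeros((n, n))
        d = self.intra
        d = d[d["chrom1"] == chrom]
        if len(d):
            i = d["pos1"].to_numpy() // resolution
            j = d["pos2"].to_numpy() // resolution
            np.add.at(mat, (i, j), 1.0)
            np.add.at(mat, (j, i), (i != j).astype(float))
        return mat


def filter_blacklist(obj, blacklist: RegionSet):
    """Remove items overlapping blacklist intervals.

    Works on a ``RegionSet`` (regions dropped), ``CellMethylome`` (sites at a
    blacklisted position dropped) or ``CellContacts`` (a contact is dropped if
    *either* end falls inside a blacklisted interval). Removal counts are
    logged at INFO level.
    """
    if isinstance(obj, RegionSet):
        out = obj.filter(blacklist)
        logger.info("blacklist: removed %d/%d regions", len(obj) - len(out), len(obj))
        return out
    if isinstance(obj, CellMethylome):
        df = obj.sites
        keep = np.ones(len(df), dtype=bool)
        for chrom, sub in df.groupby("chrom", sort=False):
            hit = blacklist.overlaps_points(chrom, sub["pos"].to_numpy())
            keep[sub.index.to_numpy()] = ~hit
        removed = int((~keep).sum())
        if removed:
            logger.info("blacklist: removed %d sites from %s", removed, obj.cell_id)
        return CellMethylome(obj.cell_id, df[keep].reset_index(drop=True))
    if isinstance(obj, CellContacts):
        df = obj.pairs
        keep = np.ones(len(df), dtype=bool)
        for col_c, col_p in (("chrom1", "pos1"), ("chrom2", "pos2")):
            for chrom, sub in df.groupby(col_c, sort=False):
                hit = blacklist.overlaps_points(chrom, sub[col_p].to_numpy())
                keep[sub.index.to_numpy()] &= ~hit
        removed = int((~keep).sum())
        if removed:
            logger.info("blacklist: removed %d contacts from %s", removed, obj.cell_id)
        return CellContacts(obj.cell_id, df[keep].reset_index(drop=True))
    raise TypeError(f"cannot blacklist-filter {type(obj).__name__}")
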