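"""Genome coordinate model: chromosome registry, regions and interval sets.

Every coordinate in this package is 0-based, half-open ``[start, end)``.
File formats that use 1-based positions (ALLC tables, .pairs) are converted
on read and write; BED-family formats pass through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["GenomeSpec", "Region", "RegionSet"]


@dataclass(frozen=True)
class GenomeSpec:
    """An ordered set of chromosomes with lengths in bp.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length)`` pairs. Names must be unique and lengths
        strictly positive.
    """

    chromosomes: tuple

    def __post_init__(self):
        chroms = tuple((str(n), int(l)) for n, l in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for n, l in chroms:
            if l <= 0:
                raise ValueError(f"chromosome {n} has non-positive length {l}")

    @property
    def names(self) -> list:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict:
        return {n: l for n, l in self.chromosomes}

    def __contains__(self, name: str) -> bool:
        return name in self.lengths

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def check_position(self, chrom: str, pos: int) -> None:
        if not 0 <= pos < self.length(chrom):
            raise ValueError(f"position {chrom}:{pos} outside chromosome bounds")

    def n_bins(self, chrom: str, resolution: int) -> int:
        """Number of ``resolution``-bp bins; the last partial bin is kept."""
        return -(-self.length(chrom) // resolution)

    def bin_of(self, pos, resolution: int):
        return np.asarray(pos) // resolution

    def bin_table(self, resolution: int) -> pd.DataFrame:
        """Genome-wide bin table with columns chrom, start, end, bin (per-chrom index)."""
        frames = []
        for chrom, length in self.chromosomes:
            starts = np.arange(0, length, resolution)
            ends = np.minimum(starts + resolution, length)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts,
                        "end": ends,
                        "bin": np.arange(len(starts)),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def uniform(cls, n_chroms: int, length: int, prefix: str = "chr") -> "GenomeSpec":
        """Convenience constructor for synthetic genomes of equal-length chromosomes."""
        return cls(tuple((f"{prefix}{i + 1}", length) for i in range(n_chroms)))


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int
    end: int
    label: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty region {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class RegionSet:
    """Sorted, per-chromosome queryable collection of genomic intervals.

    Overlap queries use a binary search on start positions combined with a
    running maximum of end positions, which stays correct when the stored
    intervals themselves overlap one another. Half-open semantics throughout:
    a query ending exactly at an interval start does not overlap it.
    """

    def __init__(self, regions: Iterable[Region] = ()):
        self._regions = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
        self._index = {}
        for chrom in {r.chrom for r in self._regions}:
            rs = [r for r in self._regions if r.chrom == chrom]
            starts = np.array([r.start for r in rs], dtype=np.int64)
            ends = np.array([r.end for r in rs], dtype=np.int64)
            self._index[chrom] = (starts, np.maximum.accumulate(ends))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RegionSet":
        label = df["label"] if "label" in df else [None] * len(df)
        score = df["score"] if "score" in df else [None] * len(df)
        return cls(
            Region(c, int(s), int(e), l, sc)
            for c, s, e, l, sc in zip(df["chrom"], df["start"], df["end"], label, score)
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self._regions],
                "start": [r.start for r in self._regions],
                "end": [r.end for r in self._regions],
                "label": [r.label for r in self._regions],
                "score": [r.score for r in self._regions],
            }
        )

    def __len__(self) -> int:
        return len(self._regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self._regions)

    def __getitem__(self, i):
        return self._regions[i]

    def overlaps_points(self, chrom: str, pos) -> np.ndarray:
        """Vectorized: True where the 1-bp site at ``pos`` falls inside a region."""
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        if chrom not in self._index:
            return np.zeros(len(pos), dtype=bool)
        starts, maxends = self._index[chrom]
        # regions with start <= pos are candidates; overlap iff max end > pos
        idx = np.searchsorted(starts, pos, side="right")
        out = np.zeros(len(pos), dtype=bool)
        nz = idx > 0
        out[nz] = maxends[idx[nz] - 1] > pos[nz]
        return out

    def overlaps_intervals(self, chrom: str, start, end) -> np.ndarray:
        """Vectorized: True where [start, end) overlaps any stored region."""
        start = np.atleast_1d(np.asarray(start, dtype=np.int64))
        end = np.atleast_1d(np.asarray(end, dtype=np.int64))
        if chrom not in self._index:
            return np.zeros(len(start), dtype=bool)
        starts, maxends = self._index[chrom]
        idx = np.searchsorted(starts, end, side="left")  # region.start < end
        out = np.zeros(len(start), dtype=bool)
        nz = idx > 0
        out[nz] = maxends[idx[nz] - 1] > start[nz]
        return out

    def overlaps_region(self, region: Region) -> bool:
        return bool(self.overlaps_intervals(region.chrom, region.start, region.end)[0])

    def merged_length(self) -> int:
        """Total bp covered after merging overlapping intervals."""
        total = 0
        for chrom in self._index:
            rs = [(r.start, r.end) for r in self._regions if r.chrom == chrom]
            cur_s, cur_e = rs[0]
            for s, e in rs[1:]:
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    total += cur_e - cur_s
                    cur_s, cur_e = s, e
            total += cur_e - cur_s
        return total

    def filter(self, blacklist: "RegionSet") -> "RegionSet":
        """Return the subset of regions not overlapping ``blacklist``."""
        keep = [r for r in self._regions if not blacklist.overlaps_region(r)]
        return RegionSet(keep)
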