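"""Readers and writers for the text formats used throughout the package.

ALLC-style methylation tables and 4DN .pairs files carry 1-based positions on
disk and are converted to the internal 0-based convention on read (and back
on write). BED / bedGraph / BEDPE are natively 0-based half-open.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .cells import CellContacts, CellMethylome
from .genome import GenomeSpec, Region, RegionSet

logger = logging.getLogger(__name__)

__all__ = [
    "read_allc",
    "write_allc",
    "read_pairs",
    "write_pairs",
    "read_bed",
    "write_bed",
    "write_bedgraph",
    "write_bedpe",
]

_ALLC_NAMES = ["chrom", "pos", "strand", "context", "mc", "cov", "flag"]
_CONTEXT_OUT = {"CG": "CGN", "CH": "CHH", "CCC": "CCC"}


def _classify_context(context: str) -> str:
    if len(context) >= 2 and context[1] == "G":
        return "CG"
    if context.upper() == "CCC":
        return "CCC"
    return "CH"


def read_allc(path, genome: GenomeSpec, cell_id: Optional[str] = None) -> CellMethylome:
    """Read an ALLC-style TSV into a strand-merged :class:`CellMethylome`.

    CG records on the + and - strand of the same CpG (1-based positions p and
    p+1) are merged by summing ``mc`` and ``cov``; the merged site is keyed by
    the 0-based + strand cytosine. Merging is idempotent: re-reading a merged
    table changes nothing. Non-CG contexts are retained for QC.
    """
    cell_id = cell_id or str(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=_ALLC_NAMES,
            dtype={
                "chrom": str,
                "pos": np.int64,
                "strand": str,
                "context": str,
                "mc": np.int64,
                "cov": np.int64,
            },
            usecols=range(6),
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed ALLC file {path}: {exc}") from exc
    if len(df) == 0:
        return CellMethylome(cell_id, df.iloc[0:0][["chrom", "pos", "mc", "cov"]].assign(context=[]))
    bad = df.index[df["mc"] > df["cov"]]
    if len(bad):
        raise ValueError(f"{path} line {bad[0] + 1}: mc > cov")
    unknown = ~df["chrom"].isin(genome.names)
    if unknown.any():
        logger.warning("%s: skipped %d records on unknown chromosomes", path, int(unknown.sum()))
        df = df[~unknown]
    df = df.copy()
    df["pos"] = df["pos"] - 1  # to 0-based
    df["context"] = df["context"].map(_classify_context)
    # move - strand CG cytosines onto the + strand C of their CpG
    shift = (df["context"] == "CG") & (df["strand"] == "-")
    df.loc[shift, "pos"] -= 1
    merged = (
        df.groupby(["chrom", "pos", "context"], as_index=False)[["mc", "cov"]]
        .sum()
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    for chrom, sub in merged.groupby("chrom", sort=False):
        if sub["pos"].min() < 0 or sub["pos"].max() >= genome.length(chrom):
            raise ValueError(f"{path}: position outside {chrom} bounds")
    return CellMethylome(cell_id, merged[["chrom", "pos", "context", "mc", "cov"]])


def write_allc(methylome: CellMethylome, path) -> None:
    df = methylome.sites.copy()
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"] + 1,  # to 1-based
            "strand": "+",
            "context": df["context"].map(_CONTEXT_OUT),
            "mc": df["mc"],
            "cov": df["cov"],
            "flag": 1,
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_pairs(path, genome: GenomeSpec, cell_id: Optional[str] = None) -> CellContacts:
    """Read a 4DN .pairs-style file (readID chrom1 pos1 chrom2 pos2 ...).

    Positions are converted to 0-based; contacts on chromosomes absent from
    ``genome`` are skipped with a logged count.
    """
    cell_id = cell_id or str(path)
    rows = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise ValueError(f"{path} line {lineno}: expected >=5 columns")
            _, c1, p1, c2, p2 = parts[:5]
            if c1 not in genome or c2 not in genome:
                skipped += 1
                continue
            rows.append((c1, int(p1) - 1, c2, int(p2) - 1))
    if skipped:
        logger.warning("%s: skipped %d pairs on unknown chromosomes", path, skipped)
    df = pd.DataFrame(rows, columns=["chrom1", "pos1", "chrom2", "pos2"])
    return CellContacts(cell_id, df)


def write_pairs(contacts: CellContacts, path, genome: Optional[GenomeSpec] = None) -> None:
    with open(path, "w") as fh:
        fh.write("## pairs format v1.0\n")
        fh.write("#columns: readID chrom1 pos1 chrom2 pos2\n")
        if genome is not None:
            for name, length in genome.chromosomes:
                fh.write(f"#chromsize: {name} {length}\n")
        for k, row in enumerate(contacts.pairs.itertuples(index=False)):
            fh.write(
                f"{contacts.cell_id}.{k}\t{row.chrom1}\t{row.pos1 + 1}"
                f"\t{row.chrom2}\t{row.pos2 + 1}\n"
            )


def read_bed(path) -> RegionSet:
    """Read BED3/BED6 into a :class:`RegionSet` (0-based half-open, unchanged)."""
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else None
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else None
            regions.append(Region(chrom, start, end, label, score))
    return RegionSet(regions)


def write_bed(regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fields = [r.chrom, str(r.start), str(r.end)]
            if r.label is not None or r.score is not None:
                fields.append(r.label if r.label is not None else ".")
            if r.score is not None:
                fields.append(str(r.score))
            fh.write("\t".join(fields) + "\n")


def write_bedgraph(df: pd.DataFrame, path, value_col: str = "score") -> None:
    df[["chrom", "start", "end", value_col]].to_csv(path, sep="\t", header=False, index=False)


def write_bedpe(df: pd.DataFrame, path) -> None:
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, sep="\t", header=False, index=False)
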