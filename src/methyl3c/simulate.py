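"""Synthetic multi-cell-type data with planted, recoverable ground truth.

Four generators emulate the statistical structure of a single-cell
methylome + chromatin-conformation study of a heterogeneous tissue:

* :func:`simulate_methylomes` — per-cell CpG count tables with cell-type
  baseline mCG levels and planted hypo-/hypermethylated regions;
* :func:`simulate_contacts` — per-cell intra-chromosomal contact lists with
  type-specific distance decay, plaid compartments, TAD blocks and loop
  pixels;
* :func:`simulate_expression` — negative-binomial counts whose per-type
  means decrease monotonically with gene-body mCG;
* :func:`simulate_genetics` — LD-structured genotype dosages with causal
  variants enriched in a chosen annotation, a heritable quantitative trait,
  and marginal-regression summary statistics from an independent split.

Every generator is a pure function of its configuration (which carries the
seed); calling one twice yields identical output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .cells import CellContacts, CellMethylome
from .genome import GenomeSpec, Region, RegionSet

logger = logging.getLogger(__name__)

__all__ = [
    "PlantedDMR",
    "MethylationConfig",
    "ContactConfig",
    "ExpressionConfig",
    "GeneticsConfig",
    "SimulationConfig",
    "Truth",
    "simulate_methylomes",
    "simulate_contacts",
    "simulate_expression",
    "simulate_genetics",
    "random_dmrs",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedDMR:
    chrom: str
    start: int
    end: int
    affected: Tuple[int, ...]  # cell-type indices carrying the shift
    direction: str  # "hypo" | "hyper"
    delta: float  # methylation-fraction shift magnitude

    def region(self) -> Region:
        return Region(self.chrom, self.start, self.end, label=self.direction)


@dataclass(frozen=True)
class MethylationConfig:
    baselines: Tuple[float, ...] = (0.75, 0.75, 0.75, 0.75)  # per-type global mCG
    cpg_spacing: int = 100  # bp between simulated CpGs
    coverage_mean: float = 0.4  # Poisson mean reads per cell per CpG
    dmrs: Tuple[PlantedDMR, ...] = ()
    n_ch_sites: int = 1000  # non-CG sites per chromosome, for QC metrics
    ch_level: float = 0.01
    ccc_level: float = 0.005


@dataclass(frozen=True)
class ContactConfig:
    n_contacts: int = 20000  # contacts per cell
    decay_exponents: Tuple[float, ...] = (1.3, 1.15, 1.0, 0.9)  # alpha per type
    resolution: int = 100_000  # sampling bin size, bp
    compartment_resolution: int = 100_000
    compartment_block_bins: int = 10  # plaid period, in compartment bins
    compartment_multiplier: float = 2.0  # same-label contact boost
    flip_fraction: float = 0.0  # per-type fraction of bins with flipped label
    tad_bins: int = 0  # 0 disables TAD structure; else boundary spacing in bins
    tad_multiplier: float = 3.0
    differential_tad_fraction: float = 0.0  # boundaries present in only half the types
    n_loops: int = 0
    loop_multiplier: float = 10.0
    loop_min_sep: int = 20  # bins; loops live at a few hundred kb separation
    loop_max_sep: int = 100


@dataclass(frozen=True)
class ExpressionConfig:
    n_genes: int = 300
    gene_length: int = 2000
    cells_per_type: int = 50
    base_mean: float = 5.0  # NB mean for a gene at mid-range methylation
    slope: float = 5.0  # log-link steepness of the mCG -> expression decrease
    dispersion: float = 2.0  # NB size parameter (larger = less overdispersed)


@dataclass(frozen=True)
class GeneticsConfig:
    n_base: int = 2000  # individuals for summary statistics
    n_target: int = 1000  # independent individuals for PRS evaluation
    n_variants: int = 5000
    maf_range: Tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 20  # variants per LD block
    ld_rho: float = 0.8  # target adjacent dosage correlation within a block
    causal_fraction: float = 0.04
    annotation_fold: float = 1.0  # causal-density enrichment inside the annotation
    heritability: float = 0.3


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    genome: GenomeSpec = field(default_factory=lambda: GenomeSpec.uniform(2, 1_000_000))
    n_cell_types: int = 4
    cells_per_type: int = 50
    methylation: MethylationConfig = field(default_factory=MethylationConfig)
    contacts: ContactConfig = field(default_factory=ContactConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    genetics: GeneticsConfig = field(default_factory=GeneticsConfig)

    def type_names(self) -> List[str]:
        return [f"type{i + 1}" for i in range(self.n_cell_types)]


@dataclass
class Truth:
    """Planted ground truth, sufficient for downstream recall/precision."""

    dmrs: List[PlantedDMR] = field(default_factory=list)
    cpg_positions: Dict[str, np.ndarray] = field(default_factory=dict)
    methylation_p: Dict[str, np.ndarray] = field(default_factory=dict)  # K x sites
    compartment_labels: Dict[str, Dict[str, np.ndarray]] = field(default_factory=dict)
    density_track: Dict[str, np.ndarray] = field(default_factory=dict)
    tad_boundaries: Dict[str, Dict[str, np.ndarray]] = field(default_factory=dict)
    loop_pixels: List[Tuple[str, int, int]] = field(default_factory=list)
    gene_regions: Optional[RegionSet] = None
    gene_body_mcg: Optional[np.ndarray] = None  # K x genes
    causal_variants: Optional[np.ndarray] = None
    causal_betas: Optional[np.ndarray] = None
    annotation_mask: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# methylomes
# ---------------------------------------------------------------------------


def random_dmrs(
    config: SimulationConfig,
    n: int = 40,
    length: int = 500,
    delta: float = 0.4,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[PlantedDMR, ...]:
    """Plant ``n`` non-overlapping DMRs of ``length`` bp on the config genome.

    Each DMR shifts one random cell type by ``delta``, alternating hypo/hyper.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 101)
    K = config.n_cell_types
    spacing = config.methylation.cpg_spacing
    # snap the planted region onto CpG positions: [first CpG, last CpG + 1)
    n_sites = max(2, round(length / spacing))
    span = (n_sites - 1) * spacing + 1
    slot_len = 3 * n_sites * spacing
    dmrs = []
    names = config.genome.names
    lengths = config.genome.lengths
    slots_per_chrom = {c: (lengths[c] - 2 * slot_len) // slot_len for c in names}
    chroms = [c for c in names for _ in range(slots_per_chrom[c])]
    chosen = rng.choice(len(chroms), size=min(n, len(chroms)), replace=False)
    chosen.sort()
    slot_of = {}
    offset = 0
    for c in names:
        slot_of[c] = offset
        offset += slots_per_chrom[c]
    for idx in chosen:
        chrom = chroms[idx]
        slot = idx - slot_of[chrom]
        start = spacing * (1 + (slot_len // spacing) * slot)
        t = int(rng.integers(K))
        direction = "hypo" if rng.random() < 0.5 else "hyper"
        dmrs.append(PlantedDMR(chrom, start, start + span, (t,), direction, delta))
    return tuple(dmrs)


def _site_probabilities(config: SimulationConfig) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """Per-chromosome CpG positions and K x sites methylation probabilities."""
    m = config.methylation
    K = config.n_cell_types
    if len(m.baselines) != K:
        raise ValueError("baselines must have one entry per cell type")
    positions, probs = {}, {}
    for chrom, length in config.genome.chromosomes:
        pos = np.arange(m.cpg_spacing, length - 1, m.cpg_spacing, dtype=np.int64)
        p = np.tile(np.asarray(m.baselines)[:, None], (1, len(pos))).astype(float)
        for dmr in m.dmrs:
            if dmr.chrom != chrom:
                continue
            inside = (pos >= dmr.start) & (pos < dmr.end)
            shift = -dmr.delta if dmr.direction == "hypo" else dmr.delta
            for t in dmr.affected:
                p[t, inside] += shift
        if ((p < 0) | (p > 1)).any():
            warnings.warn("planted effect pushes methylation outside (0,1); clipping")
        positions[chrom] = pos
        probs[chrom] = np.clip(p, 0.01, 0.99)
    return positions, probs


def simulate_methylomes(
    config: SimulationConfig,
) -> Tuple[List[CellMethylome], List[str], Truth]:
    """Simulate per-cell CpG count tables for K cell types.

    Per cell and CpG, coverage is Poisson(``coverage_mean``) and the
    methylated count Binomial(cov, p) where p is the type baseline shifted by
    +-delta inside planted DMRs, clipped to [0.01, 0.99]. Sites with zero
    coverage are absent from the cell's table (as in real sparse data).
    Non-CG (CH and CCC) sites are added at low methylation levels so QC
    metrics are computable.
    """
    rng = np.random.default_rng(config.seed)
    m = config.methylation
    positions, probs = _site_probabilities(config)
    truth = Truth(
        dmrs=list(m.dmrs),
        cpg_positions=positions,
        methylation_p=probs,
    )
    cells: List[CellMethylome] = []
    labels: List[str] = []
    names = config.type_names()
    for t in range(config.n_cell_types):
        for c in range(config.cells_per_type):
            frames = []
            for chrom, _ in config.genome.chromosomes:
                pos = positions[chrom]
                cov = rng.poisson(m.coverage_mean, size=len(pos))
                nz = cov > 0
                mc = rng.binomial(cov[nz], probs[chrom][t, nz])
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": pos[nz],
                            "context": "CG",
                            "mc": mc,
                            "cov": cov[nz],
                        }
                    )
                )
                if m.n_ch_sites:
                    length = config.genome.length(chrom)
                    ch_pos = rng.choice(length, size=m.n_ch_sites, replace=False)
                    ch_cov = rng.poisson(m.coverage_mean, size=m.n_ch_sites)
                    nzh = ch_cov > 0
                    half = int(nzh.sum()) // 2
                    ctx = np.where(np.arange(int(nzh.sum())) < half, "CH", "CCC")
                    level = np.where(ctx == "CH", m.ch_level, m.ccc_level)
                    ch_mc = rng.binomial(ch_cov[nzh], level)
                    frames.append(
                        pd.DataFrame(
                            {
                                "chrom": chrom,
                                "pos": np.sort(ch_pos[nzh]),
                                "context": ctx,
                                "mc": ch_mc,
                                "cov": ch_cov[nzh],
                            }
                        )
                    )
            cells.append(
                CellMethylome(f"{names[t]}_c{c}", pd.concat(frames, ignore_index=True))
            )
            labels.append(names[t])
    return cells, labels, truth


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------


def _contact_structure(config: SimulationConfig, rng: np.random.Generator) -> Truth:
    """Draw the planted compartment / TAD / loop structure shared by all cells."""
    cc = config.contacts
    K = config.n_cell_types
    names = config.type_names()
    truth = Truth()
    for chrom, length in config.genome.chromosomes:
        n_comp = -(-length // cc.compartment_resolution)
        base = np.where((np.arange(n_comp) // cc.compartment_block_bins) % 2 == 0, 1, -1)
        truth.density_track[chrom] = (base > 0).astype(float) + rng.normal(
            0, 0.05, n_comp
        )
        for t, name in enumerate(names):
            lab = base.copy()
            if cc.flip_fraction > 0:
                # flips are contiguous runs (half a plaid block), as real
                # compartment switches span regions rather than lone bins
                n_flip = int(round(cc.flip_fraction * n_comp))
                run = max(1, cc.compartment_block_bins // 2)
                flipped: list = []
                guard = 0
                while len(flipped) < n_flip and guard < 50 * n_comp:
                    s = int(rng.integers(0, max(n_comp - run, 1)))
                    seg = [b for b in range(s, s + run) if b not in flipped]
                    if len(seg) == run:
                        flipped.extend(seg)
                    guard += 1
                lab[np.array(flipped[:n_flip], dtype=int)] *= -1
            truth.compartment_labels.setdefault(name, {})[chrom] = lab
        if cc.tad_bins:
            n_bins = -(-length // cc.resolution)
            base_bounds = np.arange(cc.tad_bins, n_bins, cc.tad_bins)
            diff = rng.random(len(base_bounds)) < cc.differential_tad_fraction
            half = rng.random(len(base_bounds)) < 0.5
            for t, name in enumerate(names):
                keep = ~diff | (half == (t % 2 == 0))
                truth.tad_boundaries.setdefault(name, {})[chrom] = base_bounds[keep]
        if cc.n_loops:
            n_bins = -(-length // cc.resolution)
            for _ in range(cc.n_loops):
                i = int(rng.integers(0, n_bins - cc.loop_min_sep - 1))
                sep = int(rng.integers(cc.loop_min_sep, min(cc.loop_max_sep, n_bins - i - 1) + 1))
                truth.loop_pixels.append((chrom, i, i + sep))
    return truth


def _probability_map(
    config: SimulationConfig, truth: Truth, type_index: int, chrom: str
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle contact probabilities for one type on one chromosome."""
    cc = config.contacts
    name = config.type_names()[type_index]
    n = -(-config.genome.length(chrom) // cc.resolution)
    iu, ju = np.triu_indices(n)
    d = ju - iu
    alpha = cc.decay_exponents[type_index]
    w = (d + 1.0) ** (-alpha)
    if truth.compartment_labels:
        lab = truth.compartment_labels[name][chrom]
        scale = cc.compartment_resolution // cc.resolution
        lab_fine = np.repeat(lab, scale)[:n]
        same = lab_fine[iu] == lab_fine[ju]
        w = np.where(same, w * cc.compartment_multiplier, w)
    if truth.tad_boundaries:
        bounds = truth.tad_boundaries[name][chrom]
        domain = np.searchsorted(bounds, np.arange(n), side="right")
        w = np.where(domain[iu] == domain[ju], w * cc.tad_multiplier, w)
    if truth.loop_pixels:
        # a loop is a ~3x3-pixel contact dot (tens of kb), not a lone pixel;
        # the planted truth coordinate is the dot center
        pix = set()
        for (c, i0, j0) in truth.loop_pixels:
            if c != chrom:
                continue
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    pix.add((i0 + di, j0 + dj))
        if pix:
            mask = np.fromiter(((i, j) in pix for i, j in zip(iu, ju)), bool, len(iu))
            w = np.where(mask, w * cc.loop_multiplier, w)
    return iu, ju, w


def simulate_contacts(
    config: SimulationConfig,
) -> Tuple[List[CellContacts], List[str], Truth]:
    """Simulate per-cell intra-chromosomal contact lists.

    Per cell, ``n_contacts`` pairs are drawn from a bin-pair probability map
    proportional to ``(d+1)^(-alpha_t)`` times compartment / TAD / loop
    multipliers, then jittered uniformly within bins so the same cells serve
    analyses at several resolutions.
    """
    rng = np.random.default_rng(config.seed)
    cc = config.contacts
    K = config.n_cell_types
    if len(cc.decay_exponents) != K:
        raise ValueError("decay_exponents must have one entry per cell type")
    truth = _contact_structure(config, rng)
    names = config.type_names()
    # per-type concatenated probability map over all chromosomes
    maps = []
    for t in range(K):
        parts = []
        for chrom, _ in config.genome.chromosomes:
            iu, ju, w = _probability_map(config, truth, t, chrom)
            parts.append((chrom, iu, ju, w))
        total = sum(p[3].sum() for p in parts)
        maps.append([(c, iu, ju, w / total) for (c, iu, ju, w) in parts])
    cells: List[CellContacts] = []
    labels: List[str] = []
    res = cc.resolution
    for t in range(K):
        flat_p = np.concatenate([w for (_, _, _, w) in maps[t]])
        flat_chrom = np.concatenate(
            [np.full(len(w), ci) for ci, (_, _, _, w) in enumerate(maps[t])]
        )
        flat_i = np.concatenate([iu for (_, iu, _, _) in maps[t]])
        flat_j = np.concatenate([ju for (_, _, ju, _) in maps[t]])
        chrom_names = [c for (c, _, _, _) in maps[t]]
        for c in range(config.cells_per_type):
            if cc.n_contacts == 0:
                warnings.warn("cell with zero contacts requested")
                cells.append(CellContacts(f"{names[t]}_c{c}", pd.DataFrame()))
                labels.append(names[t])
                continue
            counts = rng.multinomial(cc.n_contacts, flat_p)
            nz = counts > 0
            reps = counts[nz]
            ci = np.repeat(flat_chrom[nz], reps)
            bi = np.repeat(flat_i[nz], reps)
            bj = np.repeat(flat_j[nz], reps)
            p1 = bi * res + rng.integers(0, res, size=len(bi))
            p2 = bj * res + rng.integers(0, res, size=len(bj))
            chrom_arr = pd.Categorical.from_codes(ci.astype(np.int8), chrom_names)
            df = pd.DataFrame(
                {"chrom1": chrom_arr, "pos1": p1, "chrom2": chrom_arr.copy(), "pos2": p2}
            )
            # clamp jitter inside the chromosome for partial last bins
            for k, (chrom, length) in enumerate(config.genome.chromosomes):
                sel = ci == k
                df.loc[sel, "pos1"] = np.minimum(df.loc[sel, "pos1"], length - 1)
                df.loc[sel, "pos2"] = np.minimum(df.loc[sel, "pos2"], length - 1)
            df["chrom1"] = df["chrom1"].astype(str)
            df["chrom2"] = df["chrom2"].astype(str)
            cells.append(CellContacts(f"{names[t]}_c{c}", df))
            labels.append(names[t])
    return cells, labels, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    config: SimulationConfig, truth: Truth
) -> Tuple[pd.DataFrame, List[str]]:
    """Simulate an RNA count matrix anti-correlated with gene-body mCG.

    Genes tile the genome; each gene's per-type negative-binomial mean has a
    monotone decreasing log-link in the type's expected gene-body mCG (taken
    from the methylation truth), so genes over planted hypomethylated regions
    become expression markers of the affected types.

    Returns a genes x cells count matrix (gene/cell ids as index/columns) and
    per-cell type labels. Gene regions and the per-type expected gene-body
    mCG matrix are recorded on ``truth``.
    """
    rng = np.random.default_rng(config.seed + 7)
    ec = config.expression
    K = config.n_cell_types
    names = config.type_names()
    if not truth.methylation_p:
        raise ValueError("expression simulation requires methylation truth")
    # lay genes uniformly across chromosomes
    genes: List[Region] = []
    per_chrom = -(-ec.n_genes // len(config.genome.chromosomes))
    for chrom, length in config.genome.chromosomes:
        step = max((length - ec.gene_length) // per_chrom, ec.gene_length)
        for g in range(per_chrom):
            start = g * step
            if start + ec.gene_length > length or len(genes) >= ec.n_genes:
                break
            genes.append(Region(chrom, start, start + ec.gene_length, f"gene{len(genes)}"))
    gene_set = RegionSet(genes)
    # expected gene-body mCG per type from the planted site probabilities
    p_tg = np.zeros((K, len(genes)))
    for gi, g in enumerate(genes):
        pos = truth.cpg_positions[g.chrom]
        inside = (pos >= g.start) & (pos < g.end)
        if inside.any():
            p_tg[:, gi] = truth.methylation_p[g.chrom][:, inside].mean(axis=1)
        else:
            p_tg[:, gi] = np.nan
    truth.gene_regions = gene_set
    truth.gene_body_mcg = p_tg
    mid = np.nanmean(p_tg)
    means = ec.base_mean * np.exp(ec.slope * (mid - np.nan_to_num(p_tg, nan=mid)))
    counts = np.zeros((len(genes), K * ec.cells_per_type), dtype=np.int64)
    cols = []
    labels = []
    r = ec.dispersion
    for t in range(K):
        for c in range(ec.cells_per_type):
            col = t * ec.cells_per_type + c
            mu = means[t]
            counts[:, col] = rng.negative_binomial(r, r / (r + mu))
            cols.append(f"rna_{names[t]}_c{c}")
            labels.append(names[t])
    df = pd.DataFrame(counts, index=[g.label for g in genes], columns=cols)
    return df, labels


# ---------------------------------------------------------------------------
# genetics
# ---------------------------------------------------------------------------


def _dosage_correlation(latent_rho: float, maf_a: float, maf_b: float) -> float:
    """Correlation of two {0,1,2} dosages from a thresholded bivariate normal."""

    def cuts_of(maf):
        p0 = (1 - maf) ** 2
        p1 = 2 * maf * (1 - maf)
        return np.array([-np.inf, stats.norm.ppf(p0), stats.norm.ppf(p0 + p1), np.inf])

    ca, cb = cuts_of(maf_a), cuts_of(maf_b)
    cov = np.array([[1.0, latent_rho], [latent_rho, 1.0]])
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov, allow_singular=True)
    cdf = np.zeros((4, 4))
    for a in range(1, 4):
        for b in range(1, 4):
            if np.isinf(ca[a]) and np.isinf(cb[b]):
                cdf[a, b] = 1.0
            elif np.isinf(ca[a]):
                cdf[a, b] = stats.norm.cdf(cb[b])
            elif np.isinf(cb[b]):
                cdf[a, b] = stats.norm.cdf(ca[a])
            else:
                cdf[a, b] = mvn.cdf([ca[a], cb[b]])
    e_xy = 0.0
    for a in range(3):
        for b in range(3):
            rect = cdf[a + 1, b + 1] - cdf[a, b + 1] - cdf[a + 1, b] + cdf[a, b]
            e_xy += a * b * rect
    mean_a, mean_b = 2 * maf_a, 2 * maf_b
    var_a, var_b = 2 * maf_a * (1 - maf_a), 2 * maf_b * (1 - maf_b)
    return (e_xy - mean_a * mean_b) / np.sqrt(var_a * var_b)


def _calibrate_latent_rho(target_rho: float, maf_a: float, maf_b: float) -> float:
    """Latent correlation whose thresholded dosages correlate at ``target_rho``.

    Single-latent thresholding attenuates correlation (Hermite-expansion
    attenuation ~0.75-0.85 for common MAFs), so the latent chain runs hotter
    than the target.
    """
    if target_rho <= 0:
        return 0.0
    f = lambda r: _dosage_correlation(r, maf_a, maf_b) - target_rho
    hi = 0.9999
    if f(hi) < 0:
        return hi
    return brentq(f, target_rho * 0.5, hi, xtol=1e-3)


class _LatentRhoTable:
    """Grid-cached latent-correlation lookup keyed by a MAF pair."""

    def __init__(self, target_rho: float, step: float = 0.05):
        self.target = target_rho
        self.step = step
        self._cache: Dict[Tuple[int, int], float] = {}

    def __call__(self, maf_a: float, maf_b: float) -> float:
        key = tuple(sorted((round(maf_a / self.step), round(maf_b / self.step))))
        if key not in self._cache:
            ma = max(key[0] * self.step, 0.02)
            mb = max(key[1] * self.step, 0.02)
            self._cache[key] = _calibrate_latent_rho(self.target, ma, mb)
        return self._cache[key]


def simulate_genetics(
    config: SimulationConfig, annotation: RegionSet
) -> Tuple[pd.DataFrame, Dict[str, np.ndarray], pd.DataFrame, Truth]:
    """Simulate LD-structured dosages, a heritable trait, and summary stats.

    Genotypes come from a per-block latent Gaussian AR(1) chain thresholded
    to {0,1,2} at Hardy-Weinberg genotype quantiles; the latent correlation
    is calibrated so realized adjacent dosage correlation matches ``ld_rho``.
    Causal variants are drawn with probability proportional to
    ``annotation_fold`` inside the annotation and 1 outside; the trait is
    ``y = G beta + eps`` scaled to heritability h2. Marginal least-squares
    summary statistics are computed on the independent "base" split.

    Returns ``(dosages, phenotypes, sumstats, truth)`` where dosages is an
    (n_base + n_target) x variants DataFrame whose first ``n_base`` rows are
    the base split, and ``phenotypes`` holds "base" and "target" arrays.
    """
    g = config.genetics
    if not 0 <= g.heritability < 1:
        raise ValueError("heritability must be in [0, 1)")
    rng = np.random.default_rng(config.seed + 13)
    total_len = sum(l for _, l in config.genome.chromosomes)
    # variant positions spread uniformly over the genome
    per_chrom = [
        int(round(g.n_variants * l / total_len)) for _, l in config.genome.chromosomes
    ]
    per_chrom[-1] = g.n_variants - sum(per_chrom[:-1])
    chroms, positions = [], []
    for (chrom, length), m in zip(config.genome.chromosomes, per_chrom):
        pos = np.sort(rng.choice(length, size=m, replace=False))
        chroms.extend([chrom] * m)
        positions.append(pos)
    positions = np.concatenate(positions)
    mafs = rng.uniform(*g.maf_range, size=g.n_variants)
    n_ind = g.n_base + g.n_target
    # latent AR(1) per LD block; each step's latent correlation is calibrated
    # (grid-cached) to the adjacent pair's MAFs so realized dosage
    # correlation matches ld_rho
    table = _LatentRhoTable(g.ld_rho)
    z = np.empty((n_ind, g.n_variants))
    start = 0
    while start < g.n_variants:
        stop = min(start + g.ld_block_size, g.n_variants)
        block = np.empty((n_ind, stop - start))
        block[:, 0] = rng.standard_normal(n_ind)
        for j in range(1, stop - start):
            rho_lat = table(float(mafs[start + j - 1]), float(mafs[start + j]))
            block[:, j] = rho_lat * block[:, j - 1] + np.sqrt(
                1 - rho_lat**2
            ) * rng.standard_normal(n_ind)
        z[:, start:stop] = block
        start = stop
    p0 = (1 - mafs) ** 2
    t1 = stats.norm.ppf(p0)
    t2 = stats.norm.ppf(p0 + 2 * mafs * (1 - mafs))
    dosage = (z > t1).astype(np.int8) + (z > t2).astype(np.int8)
    # causal variants enriched inside the annotation
    in_ann = np.zeros(g.n_variants, dtype=bool)
    for chrom in config.genome.names:
        sel = np.array([c == chrom for c in chroms])
        if sel.any():
            in_ann[sel] = annotation.overlaps_points(chrom, positions[sel])
    weights = np.where(in_ann, g.annotation_fold, 1.0)
    n_causal = max(1, int(round(g.causal_fraction * g.n_variants)))
    causal = rng.choice(
        g.n_variants, size=n_causal, replace=False, p=weights / weights.sum()
    )
    betas = rng.standard_normal(n_causal)
    G = dosage[:, causal].astype(float)
    G = (G - G.mean(axis=0)) / np.where(G.std(axis=0) > 0, G.std(axis=0), 1.0)
    genetic = G @ betas
    if g.heritability > 0 and genetic.std() > 0:
        genetic *= np.sqrt(g.heritability) / genetic.std()
    else:
        genetic = np.zeros(n_ind)
    y = genetic + rng.standard_normal(n_ind) * np.sqrt(1 - g.heritability)
    # marginal OLS on the base split
    yb = y[: g.n_base]
    Gb = dosage[: g.n_base].astype(float)
    n = g.n_base
    gm = Gb.mean(axis=0)
    gv = Gb.var(axis=0)
    gv = np.where(gv > 0, gv, np.nan)
    beta_hat = ((Gb - gm) * (yb - yb.mean())[:, None]).sum(axis=0) / (n * gv)
    resid_var = yb.var() - beta_hat**2 * gv
    se = np.sqrt(np.maximum(resid_var, 1e-12) / ((n - 2) * gv))
    tstat = beta_hat / se
    pvals = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    sumstats = pd.DataFrame(
        {
            "id": [f"v{i}" for i in range(g.n_variants)],
            "chrom": chroms,
            "pos": positions,
            "a1": "A",
            "beta": beta_hat,
            "se": se,
            "p": np.clip(pvals, np.finfo(float).tiny, 1.0),
            "maf": mafs,
        }
    )
    dosages = pd.DataFrame(
        dosage,
        columns=sumstats["id"],
        index=[f"ind{i}" for i in range(n_ind)],
    )
    phenotypes = {"base": yb, "target": y[g.n_base :]}
    truth = Truth(
        causal_variants=causal,
        causal_betas=betas,
        annotation_mask=in_ann,
    )
    return dosages, phenotypes, sumstats, truth
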