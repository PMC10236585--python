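"""Windowed selective-sweep scan: pooled heterozygosity, Weir–Cockerham
Fst, Z-transformation, empirical joint thresholding and region calling.

For each sliding window (default 100 kb, 10 kb step) the scan computes

* pooled heterozygosity of the focal population,
  ``Hp = sum(nMAJ) * sum(nMIN) / (sum(nMAJ) + sum(nMIN))**2``, from the
  per-site major/minor allele counts of the pool, and
* Fst between the focal population and the two remaining populations
  pooled into a single deme, as the ratio-of-sums ("weighted") combination
  of per-SNP Weir & Cockerham (1984) variance components.

Both statistics are Z-transformed across evaluated windows genome-wide
(sample standard deviation), and windows simultaneously in the low-ZHp
tail and the high-ZFst tail (nearest-rank empirical quantiles, boundary
inclusive) are flagged as sweep outliers. Overlapping or bookended outlier
windows are merged into sweep regions and overlapping genes assigned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genes import GeneModelSet
from .variants import MISSING, AlleleCounts, GenotypeTable, SampleGroups, \
    pooled_major_minor

__all__ = ["ScanConfig", "WindowStat", "SweepRegion", "ScanResult",
           "DegenerateDistributionError", "make_windows", "window_hp",
           "window_fst", "wc_fst_components", "z_transform",
           "empirical_thresholds", "select_outlier_windows", "merge_regions",
           "assign_genes", "scan_genome", "windows_frame", "regions_frame",
           "write_regions_bed"]


class DegenerateDistributionError(ValueError):
    """Z-transform of a zero-spread vector."""


@dataclass(frozen=True)
class ScanConfig:
    window_size: int = 100_000
    step_size: int = 10_000
    tail_fraction: float = 0.05
    min_snps_per_window: int = 10
    focal_population: str = "Angora"

    def __post_init__(self) -> None:
        if self.step_size > self.window_size:
            raise ValueError("step_size must be <= window_size")
        if not 0.0 < self.tail_fraction < 0.5:
            raise ValueError("tail_fraction must be in (0, 0.5)")


@dataclass
class WindowStat:
    """One sliding window; start/end are 0-based half-open."""

    chromosome: str
    start: int
    end: int
    n_snps: int = 0
    hp: float = math.nan
    fst: float = math.nan
    z_hp: float = math.nan
    z_fst: float = math.nan
    is_outlier: bool = False

    @property
    def evaluated(self) -> bool:
        return not (math.isnan(self.hp) or math.isnan(self.fst))


@dataclass
class SweepRegion:
    chromosome: str
    start: int  # 0-based half-open
    end: int
    n_windows_merged: int
    gene_ids: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ScanResult:
    windows: list[WindowStat]
    hp_cutoff: float
    fst_cutoff: float
    regions: list[SweepRegion]

    @property
    def total_region_length(self) -> int:
        return sum(r.length for r in self.regions)


# ---------------------------------------------------------------------------
# Window construction


def make_windows(chromosome_lengths: dict[str, int], config: ScanConfig
                 ) -> list[WindowStat]:
    """Sliding windows per chromosome, 0-based half-open.

    Full-size windows start at multiples of ``step_size`` while they fit;
    when they do not cover the chromosome end, one final truncated window
    is appended so every base is covered.
    """
    windows: list[WindowStat] = []
    for chrom, length in chromosome_lengths.items():
        if length <= 0:
            raise ValueError(f"{chrom}: non-positive length {length}")
        start = 0
        covered = 0
        while start + config.window_size <= length:
            windows.append(WindowStat(chrom, start, start + config.window_size))
            covered = start + config.window_size
            start += config.step_size
        if covered < length:
            windows.append(WindowStat(chrom, start, length))
    return windows


# ---------------------------------------------------------------------------
# Window statistics


def window_hp(counts_in_window: list[AlleleCounts]) -> float:
    """Pooled heterozygosity Hp of one window; NaN when undefined."""
    s_maj = sum(c.n_major for c in counts_in_window)
    s_min = sum(c.n_minor for c in counts_in_window)
    total = s_maj + s_min
    if total == 0:
        return math.nan
    return (s_maj * s_min) / total**2


def wc_fst_components(table: GenotypeTable, focal_idx: np.ndarray,
                      rest_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Weir–Cockerham (1984) variance components for two demes.

    Returns arrays ``a`` (among-deme) and ``a + b + c`` (total); sites that
    are unusable (a deme with no called genotype, fewer than two called
    genotypes on average, or monomorphic overall) carry zeros and so drop
    out of the ratio-of-sums window combination.
    """
    a_out = np.zeros(table.n_variants)
    abc_out = np.zeros(table.n_variants)
    stats = []
    for idx in (focal_idx, rest_idx):
        gt = table.genotypes[:, idx, :]
        called = gt[:, :, 0] != MISSING
        n_i = called.sum(axis=1).astype(float)                 # diploids
        alt = ((gt == 1).sum(axis=2)) * called                 # dosage, called only
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = alt.sum(axis=1) / (2 * n_i)
            h_i = (((gt[:, :, 0] != gt[:, :, 1]) & called).sum(axis=1) / n_i)
        stats.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = stats

    n_sum = n1 + n2
    nbar = n_sum / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = n_sum - (n1**2 + n2**2) / n_sum
        pbar = (n1 * p1 + n2 * p2) / n_sum
        hbar = (n1 * h1 + n2 * h2) / n_sum
        s2 = (n1 * (p1 - pbar)**2 + n2 * (p2 - pbar)**2) / nbar
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 / 2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0

    usable = ((n1 >= 1) & (n2 >= 1) & (nbar > 1) & (nc > 0)
              & ~((pbar <= 0) | (pbar >= 1)))
    a_out[usable] = a[usable]
    abc_out[usable] = (a + b + c)[usable]
    return a_out, abc_out


def window_fst(table: GenotypeTable, groups: SampleGroups,
               focal_population: str, window: tuple[str, int, int]) -> float:
    """Weir–Cockerham Fst of one window, focal deme vs pooled rest.

    ``window`` is (chromosome, start, end), 0-based half-open. Ratio of
    summed among-deme components to summed total components; negative
    values are retained as computed; NaN when no SNP is usable.
    """
    chrom, start, end = window
    focal_idx, rest_idx = _deme_indices(table, groups, focal_population)
    mask = ((table.chromosomes == chrom) & (table.positions > start)
            & (table.positions <= end) & ~table.is_indel)
    sub = table.subset_variants(mask)
    if sub.n_variants == 0:
        return math.nan
    a, abc = wc_fst_components(sub, focal_idx, rest_idx)  # samples unchanged
    denom = abc.sum()
    if denom == 0:
        return math.nan
    return float(a.sum() / denom)


def _deme_indices(table: GenotypeTable, groups: SampleGroups,
                  focal_population: str) -> tuple[np.ndarray, np.ndarray]:
    if focal_population not in groups.populations:
        raise KeyError(f"unknown focal population {focal_population!r}")
    focal = table.sample_indices(groups.members(focal_population))
    rest_samples = [s for p in groups.populations if p != focal_population
                    for s in groups.members(p)]
    rest = table.sample_indices(rest_samples)
    return focal, rest


# ---------------------------------------------------------------------------
# Z-scores and thresholds


def z_transform(values) -> np.ndarray:
    """Standardise to mean 0, sample sd 1; NaNs propagate."""
    values = np.asarray(values, dtype=float)
    defined = values[~np.isnan(values)]
    if defined.size < 2:
        raise DegenerateDistributionError("need >= 2 defined values")
    sd = defined.std(ddof=1)
    if sd == 0:
        raise DegenerateDistributionError("zero spread in values")
    return (values - defined.mean()) / sd


def empirical_thresholds(z_hp_values, z_fst_values, tail_fraction: float
                         ) -> tuple[float, float]:
    """Nearest-rank empirical cutoffs: lower tail of ZHp, upper of ZFst."""
    z_hp = np.sort(np.asarray(z_hp_values, float))
    z_hp = z_hp[~np.isnan(z_hp)]
    z_fst = np.sort(np.asarray(z_fst_values, float))
    z_fst = z_fst[~np.isnan(z_fst)]
    if z_hp.size < 20 or z_fst.size < 20:
        raise ValueError("need >= 20 evaluated windows for empirical cutoffs")
    k_hp = math.ceil(tail_fraction * z_hp.size)
    k_fst = math.ceil(tail_fraction * z_fst.size)
    return float(z_hp[k_hp - 1]), float(z_fst[z_fst.size - k_fst])


def select_outlier_windows(window_stats: list[WindowStat],
                           cutoffs: tuple[float, float]) -> list[WindowStat]:
    """Flag windows jointly beyond both cutoffs (boundary inclusive)."""
    hp_cutoff, fst_cutoff = cutoffs
    out = []
    for w in window_stats:
        flag = (not math.isnan(w.z_hp) and not math.isnan(w.z_fst)
                and w.z_hp <= hp_cutoff and w.z_fst >= fst_cutoff)
        out.append(replace(w, is_outlier=flag) if flag != w.is_outlier else w)
    return out


# ---------------------------------------------------------------------------
# Regions


def merge_regions(outlier_windows: list[WindowStat]) -> list[SweepRegion]:
    """Merge overlapping or bookended outlier windows per chromosome."""
    flagged = sorted((w for w in outlier_windows if w.is_outlier),
                     key=lambda w: (w.chromosome, w.start))
    regions: list[SweepRegion] = []
    for w in flagged:
        if (regions and regions[-1].chromosome == w.chromosome
                and w.start <= regions[-1].end):
            regions[-1].end = max(regions[-1].end, w.end)
            regions[-1].n_windows_merged += 1
        else:
            regions.append(SweepRegion(w.chromosome, w.start, w.end, 1))
    return regions


def assign_genes(regions: list[SweepRegion], genes: GeneModelSet
                 ) -> list[SweepRegion]:
    """Attach overlapping gene identifiers to each region (in place).

    A gene overlaps a half-open region when ``gene_start < region.end`` and
    ``gene_end > region.start``; a gene may appear in several regions but
    at most once per region.
    """
    for region in regions:
        hits = [g.gene_id for g in genes.on_chromosome(region.chromosome)
                if g.gene_start < region.end and g.gene_end > region.start]
        region.gene_ids = list(dict.fromkeys(hits))
    return regions


# ---------------------------------------------------------------------------
# Driver


def scan_genome(table: GenotypeTable, groups: SampleGroups,
                config: ScanConfig,
                chromosome_lengths: dict[str, int] | None = None,
                genes: GeneModelSet | None = None) -> ScanResult:
    """Run the full scan on a filtered SNP table.

    Windows with fewer than ``min_snps_per_window`` SNPs, or with undefined
    Hp or Fst, are excluded before the Z-transformation; the genome-wide
    mean and sample standard deviation are taken over the remaining
    evaluated windows.
    """
    groups.validate_against(table)
    snp = table.subset_variants(~table.is_indel)
    if chromosome_lengths is None:
        chromosome_lengths = {
            c: int(snp.positions[snp.chromosomes == c].max())
            for c in dict.fromkeys(snp.chromosomes)}
    windows = make_windows(chromosome_lengths, config)

    focal_idx, rest_idx = _deme_indices(snp, groups, config.focal_population)
    n_maj, n_min = pooled_major_minor(snp, focal_idx)
    a_site, abc_site = wc_fst_components(snp, focal_idx, rest_idx)

    cs_maj = np.concatenate([[0], np.cumsum(n_maj)])
    cs_min = np.concatenate([[0], np.cumsum(n_min)])
    cs_a = np.concatenate([[0.0], np.cumsum(a_site)])
    cs_abc = np.concatenate([[0.0], np.cumsum(abc_site)])

    chrom_bounds: dict[str, tuple[int, int]] = {}
    for chrom in dict.fromkeys(snp.chromosomes):
        on = np.flatnonzero(snp.chromosomes == chrom)
        chrom_bounds[chrom] = (int(on[0]), int(on[-1]) + 1)

    for w in windows:
        if w.chromosome not in chrom_bounds:
            continue
        lo, hi = chrom_bounds[w.chromosome]
        pos = snp.positions[lo:hi]
        i0 = lo + int(np.searchsorted(pos, w.start, side="right"))
        i1 = lo + int(np.searchsorted(pos, w.end, side="right"))
        w.n_snps = i1 - i0
        if w.n_snps < config.min_snps_per_window:
            continue
        s_maj = cs_maj[i1] - cs_maj[i0]
        s_min = cs_min[i1] - cs_min[i0]
        if s_maj + s_min > 0:
            w.hp = (s_maj * s_min) / (s_maj + s_min)**2
        denom = cs_abc[i1] - cs_abc[i0]
        if denom != 0:
            w.fst = (cs_a[i1] - cs_a[i0]) / denom

    hp_vals = np.array([w.hp if w.evaluated else math.nan for w in windows])
    fst_vals = np.array([w.fst if w.evaluated else math.nan for w in windows])
    z_hp = z_transform(hp_vals)
    z_fst = z_transform(fst_vals)
    for w, zh, zf in zip(windows, z_hp, z_fst):
        if w.evaluated:
            w.z_hp, w.z_fst = float(zh), float(zf)
    cutoffs = empirical_thresholds(z_hp, z_fst, config.tail_fraction)
    windows = select_outlier_windows(windows, cutoffs)
    regions = merge_regions(windows)
    if genes is not None:
        assign_genes(regions, genes)
    return ScanResult(windows, cutoffs[0], cutoffs[1], regions)


# ---------------------------------------------------------------------------
# Export


def windows_frame(windows: list[WindowStat]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"chromosome": w.chromosome, "start": w.start, "end": w.end,
          "n_snps": w.n_snps, "hp": w.hp, "fst": w.fst, "z_hp": w.z_hp,
          "z_fst": w.z_fst, "is_outlier": w.is_outlier} for w in windows])


def regions_frame(regions: list[SweepRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"chromosome": r.chromosome, "start": r.start, "end": r.end,
          "length": r.length, "n_windows_merged": r.n_windows_merged,
          "genes": ",".join(r.gene_ids)} for r in regions])


def write_regions_bed(regions: list[SweepRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chromosome}\t{r.start}\t{r.end}\n")
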