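"""Genotype data model, VCF I/O, site-quality filters and allele counting.

The population-scale SNP set is held as a :class:`GenotypeTable`: a
variants × samples matrix of diploid calls plus the per-site metadata
(summed read depth, RMS mapping quality, SNP/InDel flag) that the quality
filters test. Coordinates are 1-based in VCF, as usual; window arithmetic
elsewhere in the package is 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # allele code for an uncalled slot

__all__ = [
    "MISSING",
    "VariantRecord",
    "GenotypeTable",
    "SampleGroups",
    "FilterConfig",
    "FilterReport",
    "AlleleCounts",
    "VcfFormatError",
    "UndefinedFrequencyError",
    "read_vcf",
    "write_vcf",
    "read_sample_groups",
    "write_sample_groups",
    "apply_site_filters",
    "pool_allele_counts",
    "allele_frequency",
]


class VcfFormatError(ValueError):
    """Raised when an input VCF violates the expected format."""


class UndefinedFrequencyError(ValueError):
    """Raised when an allele frequency is requested with zero called alleles."""


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic site: alleles, per-site metadata, diploid calls."""

    chromosome: str
    position: int  # 1-based, as in VCF
    ref_allele: str
    alt_allele: str
    is_indel: bool
    site_depth: int
    rms_mapping_quality: float
    genotypes: np.ndarray  # (n_samples, 2) allele codes, MISSING for uncalled

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("alleles must be non-empty")


class GenotypeTable:
    """Ordered variants × ordered samples, stored as numpy arrays.

    Parameters
    ----------
    chromosomes, positions, refs, alts, is_indel, depths, mqs :
        Per-variant arrays (length ``n_variants``).
    genotypes :
        ``(n_variants, n_samples, 2)`` int8 array of allele codes
        (0 = ref, 1 = alt, ``MISSING`` = uncalled).
    samples :
        Ordered sample identifiers.
    """

    def __init__(self, chromosomes, positions, refs, alts, is_indel,
                 depths, mqs, genotypes, samples) -> None:
        self.chromosomes = np.asarray(chromosomes, dtype=object)
        self.positions = np.asarray(positions, dtype=np.int64)
        self.refs = np.asarray(refs, dtype=object)
        self.alts = np.asarray(alts, dtype=object)
        self.is_indel = np.asarray(is_indel, dtype=bool)
        self.depths = np.asarray(depths, dtype=np.int64)
        self.mqs = np.asarray(mqs, dtype=float)
        self.genotypes = np.asarray(genotypes, dtype=np.int8)
        self.samples = list(samples)
        n = len(self.positions)
        if self.genotypes.shape != (n, len(self.samples), 2):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} does not match "
                f"{n} variants x {len(self.samples)} samples x 2")
        self._sort()
        self._check_duplicates()

    def _sort(self) -> None:
        order = np.lexsort((self.alts.astype(str), self.positions,
                            self.chromosomes.astype(str)))
        if not np.array_equal(order, np.arange(len(order))):
            for name in ("chromosomes", "positions", "refs", "alts",
                         "is_indel", "depths", "mqs", "genotypes"):
                setattr(self, name, getattr(self, name)[order])

    def _check_duplicates(self) -> None:
        keys = set()
        for c, p, a in zip(self.chromosomes, self.positions, self.alts):
            k = (c, int(p), a)
            if k in keys:
                raise ValueError(f"duplicate variant {c}:{p} alt={a}")
            keys.add(k)

    @property
    def n_variants(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def record(self, i: int) -> VariantRecord:
        return VariantRecord(
            chromosome=self.chromosomes[i], position=int(self.positions[i]),
            ref_allele=self.refs[i], alt_allele=self.alts[i],
            is_indel=bool(self.is_indel[i]), site_depth=int(self.depths[i]),
            rms_mapping_quality=float(self.mqs[i]),
            genotypes=self.genotypes[i])

    def subset_variants(self, mask) -> "GenotypeTable":
        mask = np.asarray(mask)
        return GenotypeTable(
            self.chromosomes[mask], self.positions[mask], self.refs[mask],
            self.alts[mask], self.is_indel[mask], self.depths[mask],
            self.mqs[mask], self.genotypes[mask], self.samples)

    def subset_samples(self, samples) -> "GenotypeTable":
        idx = [self.samples.index(s) for s in samples]
        return GenotypeTable(
            self.chromosomes, self.positions, self.refs, self.alts,
            self.is_indel, self.depths, self.mqs,
            self.genotypes[:, idx, :], list(samples))

    def sample_indices(self, samples) -> np.ndarray:
        return np.asarray([self.samples.index(s) for s in samples], dtype=int)

    def dosage_matrix(self) -> np.ndarray:
        """Alternate-allele dosage per (variant, sample); NaN where any
        allele slot is uncalled."""
        gt = self.genotypes.astype(float)
        gt[self.genotypes == MISSING] = np.nan
        return gt.sum(axis=2)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (self.samples == other.samples
                and np.array_equal(self.chromosomes, other.chromosomes)
                and np.array_equal(self.positions, other.positions)
                and np.array_equal(self.refs, other.refs)
                and np.array_equal(self.alts, other.alts)
                and np.array_equal(self.is_indel, other.is_indel)
                and np.array_equal(self.depths, other.depths)
                and np.allclose(self.mqs, other.mqs, atol=1e-3)  # MQ is
                # serialised at 2 decimals and read back as float32
                and np.array_equal(self.genotypes, other.genotypes))

    def __repr__(self) -> str:
        return (f"GenotypeTable({self.n_variants} variants, "
                f"{self.n_samples} samples)")


@dataclass
class SampleGroups:
    """Sample → population assignment with a stable population order."""

    assignments: dict[str, str]
    populations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.populations:
            seen: list[str] = []
            for pop in self.assignments.values():
                if pop not in seen:
                    seen.append(pop)
            self.populations = seen
        missing = set(self.assignments.values()) - set(self.populations)
        if missing:
            raise ValueError(f"populations {missing} not in declared order")

    def members(self, population: str) -> list[str]:
        if population not in self.populations:
            raise KeyError(f"unknown population {population!r}")
        return [s for s, p in self.assignments.items() if p == population]

    def validate_against(self, table: GenotypeTable) -> None:
        unassigned = [s for s in table.samples if s not in self.assignments]
        if unassigned:
            raise ValueError(f"samples without population: {unassigned}")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the post-call site-quality filter.

    Defaults follow the resequencing convention of keeping SNPs with
    coverage depth in [4, 1000], RMS mapping quality >= 20, no neighbouring
    SNP closer than 5 bp, no InDel within a 3 bp window, and a per-group
    missing-genotype ratio <= 50%.
    """

    min_depth: int = 4
    max_depth: int = 1000
    min_rms_mq: float = 20.0
    min_adjacent_distance: int = 5
    indel_exclusion_window: int = 3
    max_group_missing_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must be <= max_depth")
        for name in ("min_depth", "min_rms_mq", "min_adjacent_distance",
                     "indel_exclusion_window", "max_group_missing_ratio"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# Reporting precedence: a failing site is attributed to the first rule
# it fails, in this order.
FILTER_RULES = ("depth", "mq", "indel_proximity", "adjacency",
                "group_missingness")


@dataclass
class FilterReport:
    """Per-rule removal counts; InDel records are tallied separately."""

    input_snps: int = 0
    input_indels: int = 0
    removed: dict[str, int] = field(default_factory=lambda: dict.fromkeys(FILTER_RULES, 0))
    retained: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": r, "removed": self.removed[r]} for r in FILTER_RULES]
        rows.append({"rule": "retained", "removed": self.retained})
        rows.append({"rule": "input_snps", "removed": self.input_snps})
        rows.append({"rule": "input_indels", "removed": self.input_indels})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class AlleleCounts:
    """Major/minor allele tally within one population pool at one site."""

    n_major: int
    n_minor: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        if self.n_minor < 0 or self.n_major < self.n_minor:
            raise ValueError("require n_major >= n_minor >= 0")


# ---------------------------------------------------------------------------
# VCF I/O


def write_vcf(table: GenotypeTable, path, contig_lengths=None) -> None:
    """Write a minimal VCF v4.2 with per-site DP/MQ INFO and GT genotypes."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        if contig_lengths:
            for contig, length in contig_lengths.items():
                fh.write(f"##contig=<ID={contig},length={length}>\n")
        else:
            for contig in dict.fromkeys(table.chromosomes):
                fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,'
                 'Description="Total read depth at the site">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,'
                 'Description="RMS mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        for i in range(table.n_variants):
            gts = []
            for a, b in table.genotypes[i]:
                sa = "." if a == MISSING else str(int(a))
                sb = "." if b == MISSING else str(int(b))
                gts.append(f"{sa}/{sb}")
            info = f"DP={int(table.depths[i])};MQ={table.mqs[i]:.2f}"
            fh.write(f"{table.chromosomes[i]}\t{table.positions[i]}\t.\t"
                     f"{table.refs[i]}\t{table.alts[i]}\t.\tPASS\t{info}\t"
                     f"GT\t" + "\t".join(gts) + "\n")


def read_vcf(path, sample_subset=None) -> GenotypeTable:
    """Read a multi-sample VCF into a :class:`GenotypeTable`.

    Multiallelic records are split into one biallelic record per alternate
    allele (other alternate alleles are treated as reference in the split
    record). DP and MQ are taken from INFO when present; absent values are
    recorded as passing (very high depth / MQ) so they survive filtering.
    """
    from cyvcf2 import VCF

    path = str(path)
    n_header = 0
    with open(path) as fh:
        for line in fh:
            n_header += 1
            if line.startswith("#CHROM"):
                break
        else:
            raise VcfFormatError(f"{path}: no #CHROM header line found")

    vcf = VCF(path, samples=sample_subset)
    samples = list(vcf.samples)
    chroms, poss, refs, alts, indel, dps, mqs, gts = ([] for _ in range(8))
    for idx, var in enumerate(vcf):
        line_no = n_header + idx + 1
        arr = np.asarray(var.genotype.array())
        if arr.shape[1] != 3:  # two allele columns + phase flag
            raise VcfFormatError(
                f"{path}:{line_no}: ploidy != 2 at {var.CHROM}:{var.POS}")
        calls = arr[:, :2].astype(np.int8)
        dp = var.INFO.get("DP")
        mq = var.INFO.get("MQ")
        dp = int(dp) if dp is not None else 10**9
        mq = float(mq) if mq is not None else float("inf")
        for ai, alt in enumerate(var.ALT, start=1):
            split = np.where(calls == MISSING, MISSING,
                             (calls == ai).astype(np.int8))
            chroms.append(var.CHROM)
            poss.append(var.POS)
            refs.append(var.REF)
            alts.append(alt)
            indel.append(len(alt) != len(var.REF))
            dps.append(dp)
            mqs.append(mq)
            gts.append(split)
    vcf.close()
    genotypes = (np.stack(gts) if gts
                 else np.empty((0, len(samples), 2), dtype=np.int8))
    return GenotypeTable(chroms, poss, refs, alts, indel, dps, mqs,
                         genotypes, samples)


def write_sample_groups(groups: SampleGroups, path) -> None:
    pd.DataFrame(
        {"sample_id": list(groups.assignments),
         "population": list(groups.assignments.values())}
    ).to_csv(path, sep="\t", index=False)


def read_sample_groups(path) -> SampleGroups:
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "population"} <= set(df.columns):
        raise ValueError(
            f"{path}: expected columns sample_id, population; got {list(df.columns)}")
    return SampleGroups(dict(zip(df["sample_id"], df["population"])))


# ---------------------------------------------------------------------------
# Filtering


def apply_site_filters(table: GenotypeTable, groups: SampleGroups,
                       config: FilterConfig | None = None,
                       ) -> tuple[GenotypeTable, FilterReport]:
    """Apply the post-call site-quality filters, SNP records only.

    A SNP is retained when its depth lies in ``[min_depth, max_depth]``, its
    RMS mapping quality is at least ``min_rms_mq``, no InDel from the input
    (retained or not) lies within ``indel_exclusion_window`` bp, the nearest
    neighbouring input SNP is at least ``min_adjacent_distance`` bp away
    (BOTH members of a too-close pair are dropped), and the fraction of
    uncalled genotypes is at most ``max_group_missing_ratio`` within every
    population. Removed sites are attributed to the first failed rule in
    the order depth → MQ → InDel proximity → adjacency → group missingness.
    """
    if config is None:
        config = FilterConfig()
    groups.validate_against(table)
    report = FilterReport()
    snp_mask = ~table.is_indel
    report.input_snps = int(snp_mask.sum())
    report.input_indels = int(table.is_indel.sum())
    if table.n_variants == 0:
        return table.subset_variants(snp_mask), report

    n = table.n_variants
    fail_depth = (table.depths < config.min_depth) | (table.depths > config.max_depth)
    fail_mq = table.mqs < config.min_rms_mq

    # neighbourhood rules are evaluated against ALL input sites of the
    # relevant kind, not only those that survive the marginal filters
    fail_indel = np.zeros(n, dtype=bool)
    fail_adj = np.zeros(n, dtype=bool)
    for chrom in dict.fromkeys(table.chromosomes):
        on_chrom = table.chromosomes == chrom
        snp_idx = np.flatnonzero(on_chrom & snp_mask)
        indel_pos = np.sort(table.positions[on_chrom & table.is_indel])
        snp_pos = table.positions[snp_idx]
        if indel_pos.size and snp_idx.size:
            left = np.searchsorted(indel_pos, snp_pos - config.indel_exclusion_window)
            right = np.searchsorted(indel_pos, snp_pos + config.indel_exclusion_window,
                                    side="right")
            fail_indel[snp_idx] = right > left
        if snp_idx.size > 1:
            gaps = np.diff(snp_pos)
            close = gaps < config.min_adjacent_distance
            bad = np.zeros(snp_idx.size, dtype=bool)
            bad[:-1] |= close
            bad[1:] |= close
            fail_adj[snp_idx] = bad

    fail_miss = np.zeros(n, dtype=bool)
    called = table.genotypes[:, :, 0] != MISSING
    for pop in groups.populations:
        idx = table.sample_indices(groups.members(pop))
        if idx.size == 0:
            continue
        miss_frac = 1.0 - called[:, idx].mean(axis=1)
        fail_miss |= miss_frac > config.max_group_missing_ratio

    rules = [("depth", fail_depth), ("mq", fail_mq),
             ("indel_proximity", fail_indel), ("adjacency", fail_adj),
             ("group_missingness", fail_miss)]
    attributed = np.zeros(n, dtype=bool)
    keep = snp_mask.copy()
    for name, fail in rules:
        hit = snp_mask & fail & ~attributed
        report.removed[name] = int(hit.sum())
        attributed |= fail
        keep &= ~fail
    report.retained = int(keep.sum())
    return table.subset_variants(keep), report


# ---------------------------------------------------------------------------
# Allele counting


def pool_allele_counts(table: GenotypeTable, groups: SampleGroups,
                       population: str, variant_index: int) -> AlleleCounts:
    """Count the most (nMAJ) and least (nMIN) frequent allele in one pool.

    Only called allele slots contribute; a frequency tie assigns the
    reference allele to nMAJ (the counts are equal, so downstream window
    statistics are unaffected).
    """
    idx = table.sample_indices(groups.members(population))
    gt = table.genotypes[variant_index, idx, :].ravel()
    called = gt[gt != MISSING]
    n_alt = int((called == 1).sum())
    n_ref = called.size - n_alt
    n_missing = gt.size - called.size
    return AlleleCounts(max(n_ref, n_alt), min(n_ref, n_alt), n_missing)


def pooled_major_minor(table: GenotypeTable, sample_idx) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised nMAJ/nMIN arrays over all variants for one sample pool."""
    gt = table.genotypes[:, sample_idx, :]
    called = gt != MISSING
    n_called = called.sum(axis=(1, 2))
    n_alt = ((gt == 1) & called).sum(axis=(1, 2))
    n_ref = n_called - n_alt
    return np.maximum(n_ref, n_alt), np.minimum(n_ref, n_alt)


def allele_frequency(counts: AlleleCounts, allele: str = "major") -> float:
    """Frequency of the major or minor allele among called slots."""
    total = counts.n_major + counts.n_minor
    if total == 0:
        raise UndefinedFrequencyError("no called alleles in pool")
    if allele == "major":
        return counts.n_major / total
    if allele == "minor":
        return counts.n_minor / total
    raise ValueError(f"allele must be 'major' or 'minor', got {allele!r}")
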