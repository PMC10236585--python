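"""Synthetic three-population resequencing cohorts with planted sweeps.

The generator emulates the statistical structure a sweep scan consumes: a
shared U-shaped background allele-frequency spectrum, per-population drift
(Balding–Nichols model), and planted sweep intervals in which the focal
population is driven to near-fixation of the allele that is minor in the
background — which simultaneously depresses pooled heterozygosity and
inflates focal-vs-rest differentiation, the joint signature the scan
thresholds on. Per-genotype read depth, per-site RMS mapping quality,
missingness and a fraction of InDel sites are attached so the site-quality
filters have realistic work to do.

No haplotype or recombination structure is simulated: the scan consumes
per-site allele counts only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genes import GeneModel, GeneModelSet
from .variants import MISSING, GenotypeTable, SampleGroups

__all__ = ["SimConfig", "SimTruth", "simulate_cohort", "simulate_gene_models",
           "write_truth"]

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic cohort.

    Defaults mirror a three-breed resequencing design: 3 populations of 6
    diploid individuals, one 5 Mb chromosome at ~1 SNP/kb, breed-level
    drift (Balding–Nichols F = 0.15), ~6.5-fold per-sample depth, and mild
    missingness and InDel contamination.
    """

    seed: int = 0
    n_chromosomes: int = 1
    chromosome_length: int = 5_000_000
    snp_density: float = 1.0e-3
    population_sizes: tuple[int, ...] = (6, 6, 6)
    population_labels: tuple[str, ...] = ("Angora", "NewZealand", "Rex")
    background_freq_shape: tuple[float, float] = (0.3, 0.3)
    divergence_scale: float = 0.15
    sweep_intervals: tuple[tuple[str, int, int, str], ...] = ()
    sweep_fixation_prob: float = 0.9
    depth_mean: float = 6.5
    depth_dispersion: float = 3.0
    mq_mean: float = 50.0
    mq_sd: float = 8.0
    missing_rate: float = 0.02
    indel_rate: float = 0.05

    def __post_init__(self) -> None:
        for name in ("sweep_fixation_prob", "missing_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(n < 2 for n in self.population_sizes):
            raise ValueError("every population must have >= 2 individuals")
        if len(self.population_labels) != len(self.population_sizes):
            raise ValueError("population_labels and population_sizes mismatch")
        chrom_names = set(self.chromosome_names())
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, focal in self.sweep_intervals:
            if chrom not in chrom_names:
                raise ValueError(f"sweep interval on unknown chromosome {chrom}")
            if not (0 <= start < end <= self.chromosome_length):
                raise ValueError(
                    f"sweep interval [{start}, {end}) outside chromosome bounds")
            if focal not in self.population_labels:
                raise ValueError(f"unknown focal population {focal!r}")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping sweep intervals on {chrom}: "
                        f"[{s1},{e1}) and [{s2},{e2})")

    def chromosome_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def sample_names(self) -> list[str]:
        names = []
        for label, size in zip(self.population_labels, self.population_sizes):
            names.extend(f"{label}_{i + 1}" for i in range(size))
        return names


@dataclass
class SimTruth:
    """What was planted: intervals and true per-population site frequencies."""

    planted_intervals: list[tuple[str, int, int, str]]
    site_chromosomes: np.ndarray
    site_positions: np.ndarray
    population_frequencies: dict[str, np.ndarray]  # per-pop true alt freq


def _population_frequencies(cfg: SimConfig, rng: np.random.Generator,
                            chrom: str, positions: np.ndarray) -> np.ndarray:
    """True alt-allele frequency per (population, site) on one chromosome."""
    a, b = cfg.background_freq_shape
    n_sites = positions.size
    p_bg = rng.beta(a, b, size=n_sites)
    # guard against exactly-monomorphic background sites
    p_bg = np.clip(p_bg, 1e-4, 1 - 1e-4)

    n_pops = len(cfg.population_labels)
    F = cfg.divergence_scale
    if F <= 0:
        freqs = np.tile(p_bg, (n_pops, 1))
    else:
        shape1 = p_bg * (1 - F) / F
        shape2 = (1 - p_bg) * (1 - F) / F
        freqs = rng.beta(shape1, shape2, size=(n_pops, n_sites))

    for ivl_chrom, start, end, focal in cfg.sweep_intervals:
        if ivl_chrom != chrom:
            continue
        pi = cfg.population_labels.index(focal)
        inside = (positions > start) & (positions <= end)  # 0-based half-open
        swept = inside & (rng.random(n_sites) < cfg.sweep_fixation_prob)
        n_swept = int(swept.sum())
        if n_swept == 0:
            continue
        # near-fix the allele that is minor in the background so the focal
        # pool loses diversity while the pooled-rest frequency stays put
        eps = rng.beta(1, 50, size=n_swept)
        freqs[pi, swept] = np.where(p_bg[swept] >= 0.5, eps, 1 - eps)
    return freqs


def simulate_cohort(config: SimConfig
                    ) -> tuple[GenotypeTable, SampleGroups, SimTruth]:
    """Simulate genotypes, site metadata and truth for one cohort.

    Deterministic given ``config.seed``: one ``numpy`` generator drives all
    draws. Genotypes are Hardy–Weinberg binomial draws from each
    population's true site frequency; depth is overdispersed
    (gamma–Poisson) per genotype and summed per site; RMS MQ is normal per
    site; genotypes go missing independently; a fraction of sites is
    emitted as ±1 bp InDels.
    """
    rng = np.random.default_rng(config.seed)
    labels = config.population_labels
    sizes = config.population_sizes
    samples = config.sample_names()
    pop_of_sample = np.repeat(np.arange(len(sizes)), sizes)
    n_samples = len(samples)

    all_chrom, all_pos = [], []
    truth_freqs = {label: [] for label in labels}
    gt_blocks = []
    for chrom in config.chromosome_names():
        n_sites = rng.binomial(config.chromosome_length, config.snp_density)
        positions = np.sort(rng.choice(
            np.arange(1, config.chromosome_length + 1), size=n_sites,
            replace=False))
        freqs = _population_frequencies(config, rng, chrom, positions)
        p_per_sample = freqs[pop_of_sample, :]  # (n_samples, n_sites)
        alt_dosage = rng.binomial(2, p_per_sample.T)  # (n_sites, n_samples)
        gt = np.zeros((n_sites, n_samples, 2), dtype=np.int8)
        gt[:, :, 0] = alt_dosage >= 1
        gt[:, :, 1] = alt_dosage == 2
        gt_blocks.append(gt)
        all_chrom.extend([chrom] * n_sites)
        all_pos.append(positions)
        for pi, label in enumerate(labels):
            truth_freqs[label].append(freqs[pi])

    positions = np.concatenate(all_pos)
    genotypes = np.concatenate(gt_blocks, axis=0)
    n_total = positions.size

    if config.missing_rate > 0:
        miss = rng.random((n_total, n_samples)) < config.missing_rate
        genotypes[miss] = MISSING

    # depth: gamma-Poisson per called genotype, summed per site
    shape = config.depth_dispersion
    lam = rng.gamma(shape, config.depth_mean / shape, size=(n_total, n_samples))
    per_gt_depth = rng.poisson(lam)
    depths = per_gt_depth.sum(axis=1)
    mqs = np.clip(rng.normal(config.mq_mean, config.mq_sd, size=n_total), 0, None)
    mqs = np.round(mqs, 2)  # match VCF serialisation precision

    is_indel = rng.random(n_total) < config.indel_rate
    ref_idx = rng.integers(0, 4, size=n_total)
    alt_shift = rng.integers(1, 4, size=n_total)
    refs = _BASES[ref_idx].astype(object)
    alts = _BASES[(ref_idx + alt_shift) % 4].astype(object)
    ins = rng.random(n_total) < 0.5  # insertion vs deletion for InDel sites
    extra = _BASES[rng.integers(0, 4, size=n_total)]
    for i in np.flatnonzero(is_indel):
        if ins[i]:
            alts[i] = refs[i] + extra[i]
        else:
            refs[i] = refs[i] + extra[i]
            alts[i] = refs[i][0]

    table = GenotypeTable(np.array(all_chrom, dtype=object), positions, refs,
                          alts, is_indel, depths, mqs, genotypes, samples)
    groups = SampleGroups(
        {s: labels[pop_of_sample[i]] for i, s in enumerate(samples)},
        list(labels))
    truth = SimTruth(
        planted_intervals=list(config.sweep_intervals),
        site_chromosomes=np.array(all_chrom, dtype=object),
        site_positions=positions,
        population_frequencies={k: np.concatenate(v)
                                for k, v in truth_freqs.items()})
    return table, groups, truth


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + TAA, with codon 191 set to TTA/TTG."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    if n_codons >= 191:
        codons[190] = "TTA" if rng.random() < 0.5 else "TTG"
    return "".join(codons)


def simulate_gene_models(config: SimConfig) -> GeneModelSet:
    """Toy gene models tiling the simulated chromosomes.

    Every chromosome carries one three-exon plus-strand protein-coding gene
    patterned on Fgf5 — 702 bp CDS (234 codons), leucine codon of the TTR
    form at codon 191 so the c.572 T>C missense worked example is
    reproducible, variant-bearing third exon — placed inside the first
    planted sweep interval when one exists. Additional genes (alternating
    strand) are tiled every 500 kb for region-assignment and enrichment
    tests.
    """
    rng = np.random.default_rng(config.seed)
    genes: list[GeneModel] = []
    span = 5_000  # genomic footprint of each toy gene

    for chrom in config.chromosome_names():
        focal_ivls = [(s, e) for c, s, e, _ in config.sweep_intervals
                      if c == chrom]
        if focal_ivls:
            s, e = focal_ivls[0]
            fgf5_start = min(s + (e - s) // 3, config.chromosome_length - span - 1)
        else:
            fgf5_start = min(200_000, max(1, config.chromosome_length - span - 1))
        genes.append(_three_exon_gene(f"Fgf5_like_{chrom}", chrom,
                                      fgf5_start, "+", rng))
        idx = 0
        for start in range(500_000, config.chromosome_length - span, 500_000):
            if abs(start - fgf5_start) < 2 * span:
                continue
            idx += 1
            strand = "+" if idx % 2 else "-"
            genes.append(_three_exon_gene(f"{chrom}_gene_{idx:03d}", chrom,
                                          start, strand, rng))
    return GeneModelSet(genes)


def _three_exon_gene(gene_id: str, chrom: str, start: int, strand: str,
                     rng: np.random.Generator) -> GeneModel:
    # exon1 200 bp (100 bp 5'UTR), intron 2 kb, exon2 300 bp, intron 2 kb,
    # exon3 400 bp (302 bp CDS + 98 bp 3'UTR) -> CDS 100+300+302 = 702 bp
    e1 = (start, start + 199)
    e2 = (start + 2200, start + 2499)
    e3 = (start + 4500, start + 4899)
    if strand == "+":
        cds = ((e1[0] + 100, e1[1]), e2, (e3[0], e3[0] + 301))
    else:
        cds = ((e1[0] + 98, e1[1]), e2, (e3[0], e3[0] + 301))
        # minus strand: translation runs right-to-left; keep 702 bp total
        cds = ((e1[0] + 98, e1[1]), e2, (e3[0], e3[0] + 299))
    seq = _random_cds(rng, sum(e - s + 1 for s, e in cds) // 3)
    return GeneModel(gene_id=gene_id, chromosome=chrom, strand=strand,
                     gene_start=e1[0], gene_end=e3[1],
                     exons=(e1, e2, e3), cds_segments=cds,
                     cds_sequence=seq)


def write_truth(truth: SimTruth, path) -> None:
    """Planted sweep intervals as TSV (chromosome, start, end, focal)."""
    import pandas as pd

    pd.DataFrame(truth.planted_intervals,
                 columns=["chromosome", "start", "end", "focal_population"]
                 ).to_csv(path, sep="\t", index=False)
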