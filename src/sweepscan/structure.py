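"""Population-structure diagnostics: pairwise r² LD decay and genotype PCA.

Two r² estimators are offered. ``em_haplotype`` (default) estimates the
four two-locus haplotype frequencies from unphased diploid genotypes by
expectation–maximisation and returns r² = D²/(pA·pa·pB·pb) — the
haplotype-based semantics of classical LD software. ``dosage_correlation``
is the squared Pearson correlation of alternate-allele dosages, a fast
composite-LD alternative. PCA standardises the dosage matrix per site by
the binomial scale sqrt(2p(1-p)) and eigendecomposes the sample-sample
relationship matrix; coordinates are the orthonormal eigenvectors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import GenotypeTable, SampleGroups

__all__ = ["LDConfig", "LDDecayCurve", "PCAResult", "two_locus_r2",
           "em_haplotype_frequencies", "ld_decay_curve", "genotype_pca"]


@dataclass(frozen=True)
class LDConfig:
    max_pair_distance: int = 500_000
    min_maf: float = 0.01
    decay_bin_width: int = 10_000
    estimator: str = "em_haplotype"

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_maf < 0.5:
            raise ValueError("min_maf must be in [0, 0.5)")
        if self.decay_bin_width <= 0:
            raise ValueError("decay_bin_width must be > 0")
        if self.estimator not in ("em_haplotype", "dosage_correlation"):
            raise ValueError(f"unknown estimator {self.estimator!r}")


@dataclass
class LDDecayCurve:
    """Mean r² by distance bin, per population."""

    curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    # each frame: bin_start, bin_end, mid, mean_r2, n_pairs

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for pop, df in self.curves.items():
            out = df.copy()
            out.insert(0, "population", pop)
            frames.append(out)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


@dataclass
class PCAResult:
    samples: list[str]
    coordinates: np.ndarray        # (n_samples, k) orthonormal eigenvectors
    eigenvalues: np.ndarray        # length k, non-increasing
    variance_explained: np.ndarray  # fraction of total variance, length k

    def to_frame(self, groups: SampleGroups | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.coordinates, columns=[
            f"PC{i + 1}" for i in range(self.coordinates.shape[1])])
        df.insert(0, "sample", self.samples)
        if groups is not None:
            df.insert(1, "population",
                      [groups.assignments.get(s, "") for s in self.samples])
        return df


# ---------------------------------------------------------------------------
# Two-locus r²


def em_haplotype_frequencies(dos_a: np.ndarray, dos_b: np.ndarray,
                             tol: float = 1e-10, max_iter: int = 1000
                             ) -> tuple[np.ndarray, bool]:
    """EM estimate of two-locus haplotype frequencies from dosage vectors.

    Returns ``(freqs, ambiguous)`` with ``freqs = [pAB, pAb, paB, pab]``
    (allele 1 = alternate). Only double heterozygotes have ambiguous
    phase; the EM starts at linkage equilibrium and iterates the standard
    fractional-assignment update. ``ambiguous`` is True for the degenerate
    all-double-heterozygote input, for which equilibrium is a stationary
    point and is returned as such.
    """
    n = dos_a.size
    counts = np.zeros((3, 3))
    for i, j in zip(dos_a.astype(int), dos_b.astype(int)):
        counts[i, j] += 1
    n_dh = counts[1, 1]
    p_a = dos_a.mean() / 2.0
    p_b = dos_b.mean() / 2.0

    # haplotype counts fully determined by genotypes, except double hets
    base = np.zeros(4)  # AB, Ab, aB, ab with A/B = alternate alleles
    for i in range(3):
        for j in range(3):
            if i == 1 and j == 1:
                continue
            c = counts[i, j]
            if c == 0:
                continue
            # at most one locus is heterozygous, so phase is determined:
            # a homozygous locus contributes the same allele to both
            # haplotypes, a heterozygous one splits 1/0 across them
            h1a, h2a = (1, 1) if i == 2 else ((1, 0) if i == 1 else (0, 0))
            h1b, h2b = (1, 1) if j == 2 else ((1, 0) if j == 1 else (0, 0))
            base[_hap_index(h1a, h1b)] += c
            base[_hap_index(h2a, h2b)] += c

    freqs = np.array([p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b,
                      (1 - p_a) * (1 - p_b)])
    freqs = np.clip(freqs, 1e-12, None)
    freqs /= freqs.sum()
    ambiguous = n_dh == n and n > 0
    if n_dh == 0:
        freqs = base / base.sum()
        return freqs, False
    for _ in range(max_iter):
        # E-step: split double hets between the two phase configurations
        cis = freqs[0] * freqs[3]     # AB/ab
        trans = freqs[1] * freqs[2]   # Ab/aB
        denom = cis + trans
        f_cis = 0.5 if denom == 0 else cis / denom
        hap = base.copy()
        hap[0] += n_dh * f_cis
        hap[3] += n_dh * f_cis
        hap[1] += n_dh * (1 - f_cis)
        hap[2] += n_dh * (1 - f_cis)
        new = hap / hap.sum()
        if np.max(np.abs(new - freqs)) < tol * max(1.0, np.max(np.abs(freqs))):
            freqs = new
            break
        freqs = new
    return freqs, ambiguous


def _hap_index(alt_a: int, alt_b: int) -> int:
    # order: AB, Ab, aB, ab with A = alt at locus a, B = alt at locus b
    return {(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}[(alt_a, alt_b)]


def two_locus_r2(genotypes_a, genotypes_b, estimator: str = "em_haplotype",
                 min_maf: float = 0.0) -> float | None:
    """r² between two loci from dosage vectors (0/1/2, NaN = missing).

    Samples missing at either locus are dropped pairwise. Returns ``None``
    when either locus fails the MAF gate or has zero variance after
    missing-data removal. The degenerate all-double-heterozygote input
    returns the linkage-equilibrium stationary point (r² = 0) with a
    warning.
    """
    a = np.asarray(genotypes_a, dtype=float)
    b = np.asarray(genotypes_b, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < 2:
        return None
    for v in (a, b):
        p = v.mean() / 2.0
        if min(p, 1 - p) < min_maf or p <= 0 or p >= 1:
            return None
    if estimator == "dosage_correlation":
        if a.std() == 0 or b.std() == 0:
            return None
        r = np.corrcoef(a, b)[0, 1]
        return float(r * r)
    if estimator != "em_haplotype":
        raise ValueError(f"unknown estimator {estimator!r}")
    freqs, ambiguous = em_haplotype_frequencies(a, b)
    if ambiguous:
        warnings.warn("all samples doubly heterozygous: phase unidentifiable, "
                      "returning the linkage-equilibrium stationary point",
                      stacklevel=2)
    p_ab = freqs[0]
    p_a = freqs[0] + freqs[1]
    p_b = freqs[0] + freqs[2]
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom <= 0:
        return None
    d = p_ab - p_a * p_b
    return float(d * d / denom)


# ---------------------------------------------------------------------------
# LD decay


def ld_decay_curve(table: GenotypeTable, groups: SampleGroups,
                   config: LDConfig | None = None) -> LDDecayCurve:
    """Per-population mean r² by pair distance, within-chromosome pairs
    closer than ``max_pair_distance``."""
    if config is None:
        config = LDConfig()
    groups.validate_against(table)
    snp = table.subset_variants(~table.is_indel)
    dosage = snp.dosage_matrix()
    result = LDDecayCurve()
    n_bins = int(np.ceil(config.max_pair_distance / config.decay_bin_width))
    for pop in groups.populations:
        idx = snp.sample_indices(groups.members(pop))
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins, dtype=int)
        for chrom in dict.fromkeys(snp.chromosomes):
            on = np.flatnonzero(snp.chromosomes == chrom)
            pos = snp.positions[on]
            dos = dosage[on][:, idx]
            usable = []
            for k in range(len(on)):
                v = dos[k][~np.isnan(dos[k])]
                if v.size < 2:
                    continue
                p = v.mean() / 2.0
                if min(p, 1 - p) >= config.min_maf and v.std() > 0:
                    usable.append(k)
            for ii, k1 in enumerate(usable):
                for k2 in usable[ii + 1:]:
                    dist = int(pos[k2] - pos[k1])
                    if dist >= config.max_pair_distance:
                        break
                    r2 = two_locus_r2(dos[k1], dos[k2], config.estimator,
                                      config.min_maf)
                    if r2 is None:
                        continue
                    b = dist // config.decay_bin_width
                    sums[b] += r2
                    counts[b] += 1
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        bw = config.decay_bin_width
        result.curves[pop] = pd.DataFrame({
            "bin_start": np.arange(n_bins) * bw,
            "bin_end": (np.arange(n_bins) + 1) * bw,
            "mid": (np.arange(n_bins) + 0.5) * bw,
            "mean_r2": means,
            "n_pairs": counts})
    return result


# ---------------------------------------------------------------------------
# PCA


def genotype_pca(table: GenotypeTable, groups: SampleGroups | None = None,
                 k: int = 2) -> PCAResult:
    """PCA of the standardised dosage matrix via the sample-sample
    relationship matrix.

    Missing dosages are imputed to the site mean before standardisation;
    zero-variance sites are dropped. Coordinates are the top-k orthonormal
    eigenvectors; variance fractions are eigenvalue / trace.
    """
    if k >= table.n_samples:
        raise ValueError(f"k={k} must be < n_samples={table.n_samples}")
    dosage = table.dosage_matrix()  # (variants, samples)
    mean = np.nanmean(dosage, axis=1, keepdims=True)
    filled = np.where(np.isnan(dosage), mean, dosage)
    p_hat = mean.ravel() / 2.0
    scale = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    keep = (scale > 0) & (filled.std(axis=1) > 0)
    x = (filled[keep] - mean[keep]) / scale[keep, None]
    m = int(keep.sum())
    if m == 0:
        raise ValueError("no polymorphic sites for PCA")
    grm = x.T @ x / m
    eigvals, eigvecs = np.linalg.eigh(grm)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    total = eigvals.sum()
    return PCAResult(samples=list(table.samples),
                     coordinates=eigvecs[:, :k],
                     eigenvalues=eigvals[:k],
                     variance_explained=eigvals[:k] / total)
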