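"""Gene-set enrichment, annotation tabulation and cohort summaries.

Enrichment follows the classical over-representation scheme: for a set
with K members in a universe of N genes, and n candidate genes of which k
fall in the set, the p-value is the exact hypergeometric upper tail
P(X >= k), Benjamini–Hochberg adjusted across the tested sets. Sets with
zero candidate hits are excluded before the adjustment (this changes m and
hence the adjusted values — the behaviour of common enrichment tools).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = ["GeneSetCollection", "EnrichmentResult", "SampleStats",
           "hypergeometric_enrichment", "bh_adjust",
           "tabulate_annotation_counts", "coding_totals",
           "shared_snp_summary", "shared_percent_from_counts",
           "summarize_sample_stats",
           "read_gene_sets", "read_sample_stats", "enrichment_frame"]

REGION_CATEGORIES = ("upstream", "exonic", "intronic", "splicing",
                     "downstream", "upstream/downstream", "intergenic")
CODING_CATEGORIES = ("synonymous", "missense", "stop_gain", "stop_loss")


@dataclass
class GeneSetCollection:
    """Named gene sets over a background universe.

    When ``universe`` is not given it defaults to the union of all set
    members (the convention of pathway-annotation enrichment tools).
    """

    sets: dict[str, tuple[str, frozenset[str]]]  # set_id -> (name, members)
    universe: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.universe:
            members: set[str] = set()
            for _, genes in self.sets.values():
                members |= set(genes)
            self.universe = frozenset(members)
        for set_id, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {set_id} is empty")
            if not genes <= self.universe:
                raise ValueError(f"gene set {set_id} has members outside "
                                 f"the universe")


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    name: str
    k: int           # candidate genes in the set
    K: int           # universe genes in the set
    n: int           # candidate genes in the universe
    N: int           # universe size
    p_value: float
    adjusted_p: float = float("nan")


@dataclass(frozen=True)
class SampleStats:
    """One row of a per-sample sequencing summary table."""

    sample_id: str
    raw_bases: int
    effective_rate: float   # %
    mapped_reads: int
    total_reads: int
    mapping_rate: float     # %
    average_depth: float    # fold
    coverage_1x: float      # %

    def __post_init__(self) -> None:
        if self.mapped_reads > self.total_reads:
            raise ValueError(f"{self.sample_id}: mapped > total reads")


def hypergeometric_enrichment(candidates, sets: GeneSetCollection
                              ) -> list[EnrichmentResult]:
    """Exact hypergeometric over-representation test per gene set.

    Candidates outside the universe are reported (warning) and dropped.
    Only sets with at least one candidate hit are returned; BH adjustment
    is applied across those.
    """
    candidates = set(candidates)
    if not candidates:
        return []
    outside = candidates - sets.universe
    if outside:
        import warnings
        warnings.warn(f"{len(outside)} candidate gene(s) outside the "
                      f"universe dropped: {sorted(outside)[:5]}...",
                      stacklevel=2)
    cand = candidates & sets.universe
    if not cand:
        return []
    N = len(sets.universe)
    n = len(cand)
    raw: list[EnrichmentResult] = []
    for set_id, (name, genes) in sets.sets.items():
        k = len(cand & genes)
        if k == 0:
            continue
        K = len(genes)
        p = float(hypergeom.sf(k - 1, N, K, n))
        raw.append(EnrichmentResult(set_id, name, k, K, n, N, p))
    if not raw:
        return []
    adj = bh_adjust([r.p_value for r in raw])
    return [EnrichmentResult(r.set_id, r.name, r.k, r.K, r.n, r.N,
                             r.p_value, float(q))
            for r, q in zip(raw, adj)]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def tabulate_annotation_counts(annotations) -> pd.DataFrame:
    """Count variants per region class and coding subcategory.

    Accepts the output of :func:`sweepscan.annotate.annotate_table` or a
    mapping of pre-computed category counts. Derived rows: nonsynonymous =
    missense + stop_gain + stop_loss, coding = synonymous + nonsynonymous.
    """
    counts = dict.fromkeys(REGION_CATEGORIES + CODING_CATEGORIES, 0)
    if isinstance(annotations, dict):
        for cat, c in annotations.items():
            if cat not in counts:
                raise KeyError(f"unknown category {cat!r}")
            counts[cat] = int(c)
    else:
        for a in annotations:
            counts[a.region.value] += 1
            if a.consequence is not None:
                counts[a.consequence.category] += 1
    derived = coding_totals(counts)
    rows = [{"category": c, "count": counts[c]}
            for c in REGION_CATEGORIES + CODING_CATEGORIES]
    rows.append({"category": "nonsynonymous", "count": derived["nonsynonymous"]})
    rows.append({"category": "coding", "count": derived["coding"]})
    rows.append({"category": "total",
                 "count": sum(counts[c] for c in REGION_CATEGORIES)})
    return pd.DataFrame(rows)


def coding_totals(counts: dict[str, int]) -> dict[str, int]:
    """Derived coding totals from the subcategory counts."""
    nonsyn = (counts.get("missense", 0) + counts.get("stop_gain", 0)
              + counts.get("stop_loss", 0))
    return {"nonsynonymous": nonsyn,
            "coding": counts.get("synonymous", 0) + nonsyn}


def shared_snp_summary(per_population_snp_sets: dict[str, set]
                       ) -> dict[str, float | int | dict[str, int]]:
    """Intersection/union bookkeeping over per-population SNP sets.

    The shared fraction is |intersection of all populations| / |union|,
    reported as a percentage rounded to 2 decimals.
    """
    if len(per_population_snp_sets) < 2:
        raise ValueError("need >= 2 populations")
    sets = list(per_population_snp_sets.values())
    inter = set.intersection(*map(set, sets))
    union = set.union(*map(set, sets))
    pct = 0.0 if not union else round(100.0 * len(inter) / len(union), 2)
    return {"per_population": {k: len(v)
                               for k, v in per_population_snp_sets.items()},
            "intersection": len(inter),
            "union": len(union),
            "shared_percent": pct}


def shared_percent_from_counts(shared: float, union: float) -> float:
    """Shared-SNP percentage from pre-tallied intersection/union counts,
    rounded to 2 decimals as reported."""
    if union <= 0:
        raise ValueError("union count must be positive")
    return round(100.0 * shared / union, 2)


def summarize_sample_stats(stats: list[SampleStats]) -> dict[str, float | int]:
    """Column totals and unweighted means of a sequencing summary table.

    Raw bases are summed; the rate, depth and coverage columns are
    averaged arithmetically and rounded to 2 decimals for reporting.
    """
    if not stats:
        raise ValueError("need >= 1 sample record")
    df = pd.DataFrame([vars(s) for s in stats])
    return {
        "n_samples": len(df),
        "raw_bases_total": int(df["raw_bases"].sum()),
        "effective_rate_mean": round(float(df["effective_rate"].mean()), 2),
        "mapping_rate_mean": round(float(df["mapping_rate"].mean()), 2),
        "average_depth_mean": round(float(df["average_depth"].mean()), 2),
        "coverage_1x_mean": round(float(df["coverage_1x"].mean()), 2),
    }


# ---------------------------------------------------------------------------
# I/O


def read_gene_sets(path, universe=None) -> GeneSetCollection:
    """Gene-set TSV with columns set_id, set_name, gene_id (one row per
    member)."""
    df = pd.read_csv(path, sep="\t")
    need = {"set_id", "set_name", "gene_id"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    sets = {}
    for set_id, sub in df.groupby("set_id", sort=False):
        sets[str(set_id)] = (str(sub["set_name"].iloc[0]),
                             frozenset(sub["gene_id"].astype(str)))
    return GeneSetCollection(sets, frozenset(universe) if universe else frozenset())


def read_sample_stats(path) -> list[SampleStats]:
    df = pd.read_csv(path, sep="\t")
    return [SampleStats(**{k: row[k] for k in (
        "sample_id", "raw_bases", "effective_rate", "mapped_reads",
        "total_reads", "mapping_rate", "average_depth", "coverage_1x")})
        for _, row in df.iterrows()]


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"set_id": r.set_id, "name": r.name, "k": r.k, "K": r.K, "n": r.n,
          "N": r.N, "p_value": r.p_value, "adjusted_p": r.adjusted_p}
         for r in results])
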