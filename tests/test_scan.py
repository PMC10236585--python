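"""Windowed Hp/Fst scan: statistics, thresholds, regions."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import table_from_dosages, two_pop_groups
from sweepscan.genes import GeneModel, GeneModelSet
from sweepscan.scan import (DegenerateDistributionError, ScanConfig,
                            SweepRegion, WindowStat, assign_genes,
                            empirical_thresholds, make_windows, merge_regions,
                            scan_genome, select_outlier_windows, window_fst,
                            window_hp, z_transform)
from sweepscan.simulate import SimConfig, simulate_cohort
from sweepscan.variants import AlleleCounts, SampleGroups


# -- independent brute-force transcription of the Weir-Cockerham (1984)
#    two-deme variance components, used as the oracle throughout ----------

def wc_oracle_site(dos_focal, dos_rest):
    def deme(dos):
        dos = [d for d in dos if d >= 0]
        n = len(dos)
        p = sum(dos) / (2 * n)
        h = sum(1 for d in dos if d == 1) / n
        return n, p, h
    (n1, p1, h1), (n2, p2, h2) = deme(dos_focal), deme(dos_rest)
    r = 2
    nbar = (n1 + n2) / 2
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    s2 = (n1 * (p1 - pbar)**2 + n2 * (p2 - pbar)**2) / ((r - 1) * nbar)
    if pbar <= 0 or pbar >= 1:
        return 0.0, 0.0
    a = (nbar / nc) * (s2 - (1 / (nbar - 1))
                       * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2
                               - ((2 * nbar - 1) / (4 * nbar)) * hbar)
    c = hbar / 2
    return a, a + b + c


class TestMakeWindows:
    def test_full_windows_with_default_step(self):
        w = make_windows({"chr1": 120_000}, ScanConfig())
        assert [(x.start, x.end) for x in w] == [
            (0, 100_000), (10_000, 110_000), (20_000, 120_000)]

    def test_short_chromosome_single_truncated_window(self):
        w = make_windows({"chr1": 50_000}, ScanConfig())
        assert [(x.start, x.end) for x in w] == [(0, 50_000)]

    def test_step_equals_window_tiles(self):
        w = make_windows({"chr1": 300_000},
                         ScanConfig(window_size=100_000, step_size=100_000))
        assert [(x.start, x.end) for x in w] == [
            (0, 100_000), (100_000, 200_000), (200_000, 300_000)]

    def test_every_base_covered(self):
        for length in (125_000, 99_999, 100_001, 105_000):
            ws = make_windows({"chr1": length}, ScanConfig())
            assert ws[0].start == 0
            assert max(w.end for w in ws) == length
            for a, b in zip(ws, ws[1:]):
                assert b.start <= a.end  # no gaps


class TestWindowHp:
    @pytest.mark.parametrize("counts,expected", [
        ([(6, 6)], 0.25),
        ([(12, 0), (10, 0)], 0.0),
        ([(10, 2), (8, 4)], (18 * 6) / 24**2),  # 0.1875 by hand
    ])
    def test_examples(self, counts, expected):
        hp = window_hp([AlleleCounts(a, b) for a, b in counts])
        assert hp == pytest.approx(expected, abs=1e-15)

    def test_empty_window_undefined(self):
        assert math.isnan(window_hp([]))
        assert math.isnan(window_hp([AlleleCounts(0, 0, 12)]))

    @given(st.lists(st.tuples(st.integers(0, 12), st.integers(0, 12)),
                    min_size=1, max_size=20))
    def test_bounded_by_quarter(self, pairs):
        counts = [AlleleCounts(max(a, b), min(a, b)) for a, b in pairs]
        hp = window_hp(counts)
        if not math.isnan(hp):
            assert 0.0 <= hp <= 0.25


class TestWindowFst:
    def _table(self, rows):
        table = table_from_dosages(rows)
        return table, two_pop_groups(table.samples, 6)

    def test_fixed_difference_is_one(self):
        table, groups = self._table([[2] * 6 + [0] * 12])
        fst = window_fst(table, groups, "focal", ("chr1", 0, 1000))
        assert fst == pytest.approx(1.0, abs=1e-12)

    def test_identical_pools_not_positive(self):
        rows = [[1] * 18, [0] * 9 + [2, 2] + [0] * 7, [1, 0, 2] * 6]
        table, groups = self._table(rows)
        fst = window_fst(table, groups, "focal", ("chr1", 0, 1000))
        assert fst <= 0.0

    def test_hand_evaluated_single_site(self):
        # focal 6 diploids [2,2,2,2,1,1]; rest 6 het + 3 hom-ref + 3 hom-alt;
        # frozen from the independent a/b/c transcription above
        table, groups = self._table([[2, 2, 2, 2, 1, 1]
                                     + [1] * 6 + [0] * 3 + [2] * 3])
        fst = window_fst(table, groups, "focal", ("chr1", 0, 1000))
        assert fst == pytest.approx(0.1544715447154472, abs=1e-12)
        a, abc = wc_oracle_site([2, 2, 2, 2, 1, 1],
                                [1] * 6 + [0] * 3 + [2] * 3)
        assert fst == pytest.approx(a / abc, abs=1e-12)

    def test_monomorphic_window_undefined(self):
        table, groups = self._table([[0] * 18, [0] * 18])
        assert math.isnan(window_fst(table, groups, "focal", ("chr1", 0, 1000)))

    def test_ratio_of_sums_matches_per_site_oracle(self):
        rng = np.random.default_rng(42)
        rows = rng.integers(0, 3, size=(25, 18))
        table, groups = self._table(rows)
        num = den = 0.0
        for row in rows:
            a, abc = wc_oracle_site(row[:6], row[6:])
            num += a
            den += abc
        fst = window_fst(table, groups, "focal", ("chr1", 0, 10**6))
        assert fst == pytest.approx(num / den, abs=1e-12)


class TestZTransform:
    def test_simple_example(self):
        assert z_transform([1, 2, 3]) == pytest.approx([-1, 0, 1])

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        z = z_transform(rng.normal(5, 3, size=200))
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1) < 1e-9

    def test_nan_propagates(self):
        z = z_transform([1.0, np.nan, 3.0])
        assert math.isnan(z[1]) and not math.isnan(z[0])

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateDistributionError):
            z_transform([2.0, 2.0, 2.0])


class TestThresholds:
    def test_nearest_rank_cutoffs_on_1_to_100(self):
        vals = np.arange(1.0, 101.0)
        hp_cut, fst_cut = empirical_thresholds(vals, vals, 0.05)
        assert (hp_cut, fst_cut) == (5.0, 96.0)

    def test_cutoffs_select_exactly_five_per_marginal(self):
        vals = np.arange(1.0, 101.0)
        hp_cut, fst_cut = empirical_thresholds(vals, vals, 0.05)
        assert (vals <= hp_cut).sum() == 5
        assert (vals >= fst_cut).sum() == 5

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="20"):
            empirical_thresholds(np.arange(10.0), np.arange(10.0), 0.05)

    def test_half_tail_rejected_by_config(self):
        with pytest.raises(ValueError):
            ScanConfig(tail_fraction=0.5)


class TestSelectOutliers:
    def _w(self, z_hp, z_fst):
        return WindowStat("chr1", 0, 100, 10, 0.1, 0.1, z_hp, z_fst)

    def test_boundary_inclusive_and_joint(self):
        ws = [self._w(-2.0, 3.0),   # both beyond -> outlier
              self._w(-2.0, 1.0),   # ZFst below cutoff -> no
              self._w(0.0, 3.0),    # ZHp above cutoff -> no
              self._w(-1.825, 1.967)]  # exactly at both cutoffs -> outlier
        out = select_outlier_windows(ws, (-1.825, 1.967))
        assert [w.is_outlier for w in out] == [True, False, False, True]

    def test_empty_outlier_set_is_fine(self):
        out = select_outlier_windows([self._w(0, 0)], (-2, 2))
        assert not any(w.is_outlier for w in out)


class TestRegions:
    def _outlier(self, chrom, start, end):
        return WindowStat(chrom, start, end, 10, 0.1, 0.1, -3, 3, True)

    def test_overlapping_windows_merge(self):
        regions = merge_regions([self._outlier("chr1", 0, 100_000),
                                 self._outlier("chr1", 10_000, 110_000)])
        assert [(r.start, r.end, r.n_windows_merged) for r in regions] == \
            [(0, 110_000, 2)]

    def test_chromosome_boundary_never_merges(self):
        regions = merge_regions([self._outlier("chr1", 0, 100_000),
                                 self._outlier("chr2", 0, 100_000)])
        assert len(regions) == 2

    def test_gap_keeps_regions_apart(self):
        regions = merge_regions([self._outlier("chr1", 0, 100_000),
                                 self._outlier("chr1", 200_000, 300_000)])
        assert len(regions) == 2

    def test_bookended_windows_merge(self):
        regions = merge_regions([self._outlier("chr1", 0, 100_000),
                                 self._outlier("chr1", 100_000, 200_000)])
        assert len(regions) == 1 and regions[0].end == 200_000


class TestAssignGenes:
    def _genes(self, *spans):
        return GeneModelSet([
            GeneModel(f"g{i}", "chr1", "+", s, e, ((s, e),), ())
            for i, (s, e) in enumerate(spans)])

    def test_contained_gene_assigned(self):
        regions = [SweepRegion("chr1", 0, 110_000, 1)]
        assign_genes(regions, self._genes((50_000, 60_000)))
        assert regions[0].gene_ids == ["g0"]

    def test_half_open_boundary_excludes_gene_at_region_end(self):
        regions = [SweepRegion("chr1", 0, 110_000, 1)]
        assign_genes(regions, self._genes((110_000, 120_000)))
        assert regions[0].gene_ids == []

    def test_gene_overlapping_two_regions_listed_in_both(self):
        regions = [SweepRegion("chr1", 0, 55_000, 1),
                   SweepRegion("chr1", 58_000, 100_000, 1)]
        assign_genes(regions, self._genes((50_000, 60_000)))
        assert regions[0].gene_ids == ["g0"]
        assert regions[1].gene_ids == ["g0"]


class TestScanGenome:
    def test_windowed_stats_match_brute_force(self):
        """Driver Hp and Fst equal per-window brute-force recomputation on
        a 50-SNP toy table (1e-12)."""
        rng = np.random.default_rng(7)
        positions = np.sort(rng.choice(np.arange(1, 300_000), 50,
                                       replace=False))
        rows = rng.integers(0, 3, size=(50, 18))
        table = table_from_dosages(rows, positions=positions)
        groups = two_pop_groups(table.samples, 6)
        cfg = ScanConfig(min_snps_per_window=1, focal_population="focal")
        res = scan_genome(table, groups, cfg,
                          chromosome_lengths={"chr1": 300_000})
        checked = 0
        for w in res.windows:
            in_w = (positions > w.start) & (positions <= w.end)
            assert w.n_snps == in_w.sum()
            if not w.evaluated:
                continue
            # brute-force Hp from per-site focal major/minor tallies
            maj = min_ = 0
            for row in rows[in_w]:
                n_alt = int(row[:6].sum())
                n_ref = 12 - n_alt
                maj += max(n_ref, n_alt)
                min_ += min(n_ref, n_alt)
            assert w.hp == pytest.approx(maj * min_ / (maj + min_)**2,
                                         abs=1e-12)
            num = den = 0.0
            for row in rows[in_w]:
                a, abc = wc_oracle_site(row[:6], row[6:])
                num += a
                den += abc
            assert w.fst == pytest.approx(num / den, abs=1e-12)
            checked += 1
        assert checked >= 20

    def test_z_scores_normalised_and_outlier_budget(self):
        cfg = SimConfig(seed=13, chromosome_length=3_000_000,
                        sweep_intervals=(("chr1", 1_000_000, 1_200_000,
                                          "Angora"),),
                        sweep_fixation_prob=1.0)
        table, groups, _ = simulate_cohort(cfg)
        res = scan_genome(table, groups, ScanConfig(),
                          chromosome_lengths={"chr1": 3_000_000})
        z_hp = np.array([w.z_hp for w in res.windows if w.evaluated])
        z_fst = np.array([w.z_fst for w in res.windows if w.evaluated])
        for z in (z_hp, z_fst):
            assert abs(z.mean()) < 1e-9
            assert abs(z.std(ddof=1) - 1) < 1e-9
        n_out = sum(w.is_outlier for w in res.windows)
        assert n_out / len(z_hp) <= 0.05

    def test_planted_sweep_recovered_with_genes(self):
        cfg = SimConfig(seed=21, chromosome_length=3_000_000,
                        sweep_intervals=(("chr1", 1_000_000, 1_200_000,
                                          "Angora"),),
                        sweep_fixation_prob=1.0)
        table, groups, _ = simulate_cohort(cfg)
        from sweepscan.simulate import simulate_gene_models
        genes = simulate_gene_models(cfg)
        res = scan_genome(table, groups, ScanConfig(),
                          chromosome_lengths={"chr1": 3_000_000},
                          genes=genes)
        hits = [r for r in res.regions
                if r.start < 1_200_000 and r.end > 1_000_000]
        assert hits
        assert any("Fgf5_like_chr1" in r.gene_ids for r in hits)
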