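"""Filter cascade: masking, individual removal, site filters, thinning."""

import numpy as np
import pytest

from rrspanel.filters import (
    FilterConfig,
    AttritionLog,
    apply_site_filters,
    intersect_candidate_regions,
    mask_low_depth_genotypes,
    reduce_by_maf,
    remove_poor_individuals,
    run_filter_cascade,
    thin_by_distance,
)
from rrspanel.genotypes import MISSING

from conftest import make_genotype_matrix


class TestDepthMask:
    def test_threshold_is_inclusive(self):
        gm = make_genotype_matrix([[1, 1]], depths=[[4, 5]])
        masked = mask_low_depth_genotypes(gm, 5)
        assert masked.dosages[0, 0] == MISSING  # DP=4 -> missing
        assert masked.dosages[0, 1] == 1  # DP=5 -> retained

    def test_missingness_never_decreases(self, rng):
        dosages = rng.integers(0, 3, size=(10, 50))
        dosages[rng.random((10, 50)) < 0.1] = MISSING
        depths = rng.poisson(8, size=(10, 50))
        gm = make_genotype_matrix(dosages, depths=depths)
        before = (gm.dosages == MISSING).sum()
        after = (mask_low_depth_genotypes(gm, 5).dosages == MISSING).sum()
        assert after >= before

    def test_missing_dp_field_names_offender(self):
        gm = make_genotype_matrix([[1]], depths=[[-1]])
        with pytest.raises(ValueError, match="ind0"):
            mask_low_depth_genotypes(gm, 5)


class TestIndividualRemoval:
    def test_high_missingness_individual_removed(self):
        dosages = np.ones((3, 10), dtype=np.int8)
        dosages[1, :9] = MISSING  # 90% missing
        gm = make_genotype_matrix(dosages)
        kept, removed = remove_poor_individuals(gm, 0.5)
        assert removed == ["ind1"] and kept.n_individuals == 2

    def test_threshold_one_removes_nobody(self):
        dosages = np.full((2, 5), MISSING, dtype=np.int8)
        dosages[0, 0] = 1
        gm = make_genotype_matrix(dosages)
        kept, removed = remove_poor_individuals(gm, 1.0)
        assert removed == [] and kept.n_individuals == 2

    def test_removing_everyone_errors(self):
        gm = make_genotype_matrix(np.full((2, 5), MISSING, dtype=np.int8))
        with pytest.raises(ValueError, match="every individual"):
            remove_poor_individuals(gm, 0.5)

    def test_synthetic_cohort_87_to_83(self, filtered_population):
        filtered, truth, log = filtered_population
        assert filtered.n_individuals == 83
        assert sorted(log.removed_individuals) == sorted(truth.poor_individuals)
        assert len(log.removed_individuals) == 4


class TestSiteFilters:
    def test_quality_threshold_inclusive(self):
        gm = make_genotype_matrix(np.ones((6, 2), dtype=np.int8), quals=[29.0, 30.0])
        out = apply_site_filters(gm, FilterConfig(min_mac=0, min_maf=0.0,
                                                  min_mean_depth=0))
        assert out.n_loci == 1 and out.quals[0] == 30.0

    def test_minor_allele_count(self):
        # 10 diploids, one het + one hom-alt = 3 alt alleles -> MAC 3 kept;
        # a single het (MAC 2... actually 1) removed
        dosages = np.zeros((10, 2), dtype=np.int8)
        dosages[0, 0] = 1
        dosages[1, 0] = 2  # site0: alt count 3
        dosages[0, 1] = 2  # site1: alt count 2
        gm = make_genotype_matrix(dosages)
        out = apply_site_filters(gm, FilterConfig(min_q=0, min_maf=0.0,
                                                  min_mean_depth=0))
        assert out.n_loci == 1 and out.positions[0] == gm.positions[0]

    def test_call_rate(self):
        dosages = np.ones((4, 1), dtype=np.int8)
        dosages[0, 0] = MISSING  # call rate 0.75 < 0.80
        gm = make_genotype_matrix(dosages)
        out = apply_site_filters(gm, FilterConfig(min_q=0, min_mac=0, min_maf=0,
                                                  min_mean_depth=0))
        assert out.n_loci == 0

    def test_mean_depth_over_all_individuals(self):
        gm = make_genotype_matrix(np.ones((2, 2), dtype=np.int8),
                                  depths=[[24, 25], [24, 25]])
        out = apply_site_filters(gm, FilterConfig(min_q=0, min_mac=0, min_maf=0))
        assert out.n_loci == 1

    def test_attrition_log_sums(self, rng):
        dosages = rng.integers(0, 3, size=(20, 200)).astype(np.int8)
        dosages[rng.random((20, 200)) < 0.15] = MISSING
        quals = rng.uniform(0, 100, 200)
        depths = rng.poisson(28, size=(20, 200))
        gm = make_genotype_matrix(dosages, depths=depths, quals=quals)
        log = AttritionLog(n_input_sites=gm.n_loci, n_input_individuals=20)
        out = apply_site_filters(gm, FilterConfig(), log=log)
        assert gm.n_loci == out.n_loci + sum(r for _, r in log.site_stages)

    def test_monotonic_in_thresholds(self, rng):
        dosages = rng.integers(0, 3, size=(30, 300)).astype(np.int8)
        dosages[rng.random((30, 300)) < 0.1] = MISSING
        gm = make_genotype_matrix(
            dosages,
            depths=rng.poisson(27, size=(30, 300)),
            quals=rng.uniform(0, 200, 300),
        )
        loose = apply_site_filters(gm, FilterConfig())
        for tighter in (
            FilterConfig(min_q=60),
            FilterConfig(min_mac=6),
            FilterConfig(max_missing_callrate=0.95),
            FilterConfig(min_maf=0.2),
            FilterConfig(min_mean_depth=28),
        ):
            assert apply_site_filters(gm, tighter).n_loci <= loose.n_loci

    def test_idempotent(self, filtered_population):
        filtered, _, _ = filtered_population
        again, log = run_filter_cascade(filtered, FilterConfig())
        assert again.n_loci == filtered.n_loci
        assert again.n_individuals == filtered.n_individuals
        assert np.array_equal(again.dosages, filtered.dosages)


class TestCandidateRegions:
    def test_extension_window(self):
        gm = make_genotype_matrix(
            np.ones((2, 3), dtype=np.int8),
            positions=[99_999, 100_001, 1_101_500],
        )
        out = intersect_candidate_regions(
            gm, [("chr1", 600_000, 601_000)], 500_000, {"chr1": 2_000_000}
        )
        # window [100000, 1101000): 1-based SNP at 100001 inside; 99999 and
        # 1101500 outside
        assert out.n_loci == 1 and out.positions[0] == 100_001

    def test_clipping_at_contig_start(self):
        gm = make_genotype_matrix(np.ones((2, 1), dtype=np.int8), positions=[5])
        out = intersect_candidate_regions(
            gm, [("chr1", 100, 200)], 500, {"chr1": 1000}
        )
        assert out.n_loci == 1

    def test_zero_extension_disjoint_snps(self):
        gm = make_genotype_matrix(
            np.ones((2, 4), dtype=np.int8), positions=[10, 20, 30, 40]
        )
        out = intersect_candidate_regions(
            gm, [("chr1", 100, 200)], 0, {"chr1": 1000}
        )
        assert out.n_loci == 0

    def test_gene_outside_contig_errors(self):
        gm = make_genotype_matrix(np.ones((2, 1), dtype=np.int8))
        with pytest.raises(ValueError):
            intersect_candidate_regions(gm, [("chr1", 0, 99)], 0, {"chr1": 50})


class TestThinning:
    def _gm(self, positions, contigs=None):
        n = len(positions)
        return make_genotype_matrix(
            np.ones((2, n), dtype=np.int8),
            positions=positions,
            contigs=contigs or ["chr1"] * n,
        )

    def test_greedy_worked_example(self):
        gm = self._gm([1, 500_000, 2_000_001])
        out = thin_by_distance(gm, 1_000_000, "greedy")
        assert out.positions.tolist() == [1, 2_000_001]

    def test_mutual_worked_example(self):
        gm = self._gm([1, 500_000, 2_000_001])
        out = thin_by_distance(gm, 1_000_000, "mutual")
        assert out.positions.tolist() == [2_000_001]

    def test_single_site_per_contig_always_kept(self):
        gm = self._gm([5, 7], contigs=["chr1", "chr2"])
        for mode in ("greedy", "mutual"):
            assert thin_by_distance(gm, 10**9, mode).n_loci == 2

    def test_greedy_spacing_invariant(self, rng):
        positions = np.sort(rng.choice(10**8, size=300, replace=False))
        out = thin_by_distance(self._gm(positions), 1_000_000, "greedy")
        assert np.all(np.diff(out.positions) >= 1_000_000)

    def test_mutual_matches_pairwise_oracle(self, rng):
        positions = np.sort(rng.choice(10**7, size=60, replace=False))
        out = thin_by_distance(self._gm(positions), 1_000_000, "mutual")
        expected = [
            p
            for p in positions
            if all(q == p or abs(q - p) >= 1_000_000 for q in positions)
        ]
        assert out.positions.tolist() == expected

    def test_unsorted_input_sorted_with_warning(self):
        gm = self._gm([2_000_001, 1, 500_000])
        with pytest.warns(UserWarning, match="sort"):
            out = thin_by_distance(gm, 1_000_000, "greedy")
        assert out.positions.tolist() == [1, 2_000_001]

    def test_maf_reduction_monotone(self, filtered_population):
        filtered, _, _ = filtered_population
        reduced = reduce_by_maf(filtered, 0.35)
        assert reduced.n_loci <= filtered.n_loci
        assert np.all(reduced.minor_allele_frequencies() >= 0.35)
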