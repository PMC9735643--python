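"""Size profiles, smoothing, smear windows, target/complement partition."""

import numpy as np
import pytest

from rrspanel.digest import Fragment
from rrspanel.profile import (
    TargetRegions,
    make_target_bed,
    on_off_target,
    size_histogram,
    smear_summary,
    smooth_profile,
)


def frags_of_lengths(lengths, contig="c"):
    out, cursor = [], 0
    for L in lengths:
        out.append(Fragment(contig, cursor, cursor + L))
        cursor += L
    return out


class TestSizeHistogram:
    def test_worked_example(self):
        prof = size_histogram(frags_of_lengths([100, 100, 200]), (100, 300), 100)
        assert prof.count_per_bin.tolist() == [2, 1]
        assert prof.mass_per_bin.tolist() == [200.0, 200.0]

    def test_range_excluding_everything_is_zero(self):
        prof = size_histogram(frags_of_lengths([50, 2000]), (100, 300), 10)
        assert prof.count_per_bin.sum() == 0 and prof.mass_per_bin.sum() == 0

    def test_empty_fragment_list_is_zero_profile(self):
        prof = size_histogram([], (100, 1000), 1)
        assert prof.count_per_bin.sum() == 0

    def test_inclusive_on_both_ends(self):
        prof = size_histogram(frags_of_lengths([100, 300]), (100, 300), 100)
        assert prof.count_per_bin.sum() == 2

    def test_mass_conservation_random(self, rng):
        lengths = rng.integers(1, 2000, size=500)
        prof = size_histogram(frags_of_lengths(lengths), (100, 1000), 7)
        in_range = lengths[(lengths >= 100) & (lengths <= 1000)]
        assert prof.count_per_bin.sum() == len(in_range)
        assert prof.mass_per_bin.sum() == pytest.approx(in_range.sum())


class TestSmoothing:
    def test_constant_profile_unchanged(self):
        prof = size_histogram(frags_of_lengths([150] * 10), (100, 200), 1)
        prof.mass_per_bin = np.full(prof.n_bins, 5.0)
        sm = smooth_profile(prof, 11, 3)
        assert np.allclose(sm.smoothed_mass, 5.0)

    def test_linear_ramp_unchanged(self):
        prof = size_histogram([], (0, 100), 1)
        prof.mass_per_bin = np.arange(prof.n_bins, dtype=float)
        sm = smooth_profile(prof, 11, 1)
        assert np.allclose(sm.smoothed_mass, prof.mass_per_bin, atol=1e-8)

    def test_noise_variance_reduced(self, rng):
        prof = size_histogram([], (0, 500), 1)
        prof.mass_per_bin = rng.normal(100, 20, size=prof.n_bins)
        sm = smooth_profile(prof, 51, 3)
        assert np.var(sm.smoothed_mass) <= np.var(prof.mass_per_bin)

    def test_linearity_of_smoother(self, rng):
        prof = size_histogram([], (0, 200), 1)
        prof.mass_per_bin = rng.random(prof.n_bins)
        a = 3.7
        scaled = size_histogram([], (0, 200), 1)
        scaled.mass_per_bin = a * prof.mass_per_bin
        assert np.allclose(
            smooth_profile(scaled, 21, 3).smoothed_mass,
            a * smooth_profile(prof, 21, 3).smoothed_mass,
        )

    def test_window_too_large_errors_with_suggestion(self):
        prof = size_histogram([], (100, 120), 1)
        with pytest.raises(ValueError, match="reduce the window"):
            smooth_profile(prof, 51, 3)

    def test_lowess_mode_runs(self, rng):
        prof = size_histogram([], (0, 300), 1)
        prof.mass_per_bin = rng.random(prof.n_bins)
        sm = smooth_profile(prof, 51, 3, method="lowess")
        assert np.all(np.isfinite(sm.smoothed_mass))


class TestSmear:
    def test_worked_example(self):
        smear = smear_summary(frags_of_lengths([50, 150, 250, 800]), (100, 300))
        assert smear.fragment_count == 2 and smear.fragment_mass == 400

    def test_unbounded_window_counts_all(self):
        frags = frags_of_lengths([50, 150, 250, 800])
        smear = smear_summary(frags, (0, float("inf")))
        assert smear.fragment_count == len(frags)

    def test_frequent_cutter_wins_small_window(self):
        """A genome rich in AluI sites yields more 100-300 bp fragments for
        AluI/EcoRI than for EcoRI/PstI."""
        from rrspanel.digest import digest
        from rrspanel.synth import SyntheticGenomeConfig, make_genome

        genome, _ = make_genome(
            SyntheticGenomeConfig(
                contig_lengths={"c": 30_000}, planted={"AluI": 150}, seed=5
            )
        )
        alu_ecori = smear_summary(digest(genome, ["AluI", "EcoRI"]), (100, 300))
        ecori_psti = smear_summary(digest(genome, ["EcoRI", "PstI"]), (100, 300))
        assert alu_ecori.fragment_count > ecori_psti.fragment_count


class TestTargetRegions:
    def test_complement_of_single_target(self):
        frag = Fragment("c", 2, 5)
        regions = make_target_bed([frag], (1, 10), {"c": 10})
        assert regions.target == [("c", 2, 5)]
        assert regions.complement == [("c", 0, 2), ("c", 5, 10)]

    def test_window_selecting_all_leaves_empty_complement(self):
        frags = frags_of_lengths([4, 6])
        regions = make_target_bed(frags, (1, 100), {"c": 10})
        assert regions.complement == []

    def test_partition_property_random(self, rng):
        lengths = rng.integers(50, 400, size=200)
        frags = frags_of_lengths(lengths)
        total = int(lengths.sum())
        regions = make_target_bed(frags, (100, 300), {"c": total})
        assert regions.target_bp() + regions.complement_bp() == total
        # disjointness: sorted intervals never overlap
        all_iv = sorted(regions.target + regions.complement, key=lambda t: t[1])
        for (_, _, e1), (_, s2, _) in zip(all_iv, all_iv[1:]):
            assert e1 <= s2

    def test_fragment_beyond_contig_errors(self):
        with pytest.raises(ValueError, match="exceeds contig"):
            make_target_bed([Fragment("c", 0, 20)], (1, 100), {"c": 10})


class TestOnOffTarget:
    def test_reads_inside_target(self):
        regions = make_target_bed([Fragment("c", 100, 300)], (1, 1000), {"c": 1000})
        report = on_off_target([("c", 150, 250), ("c", 120, 140)], regions)
        assert report.on_target_fraction == 1.0 and report.off_target == 0

    def test_no_reads_is_undefined_not_error(self):
        regions = make_target_bed([Fragment("c", 0, 5)], (1, 10), {"c": 10})
        report = on_off_target([], regions)
        assert report.total == 0
        assert report.on_target_fraction is None and report.density_ratio is None

    def test_unknown_contig_warns_and_unassigned(self):
        regions = make_target_bed([Fragment("c", 0, 5)], (1, 10), {"c": 10})
        with pytest.warns(UserWarning, match="unassigned"):
            report = on_off_target([("other", 0, 5), ("c", 1, 3)], regions)
        assert report.unassigned == 1 and report.on_target == 1
        assert report.on_target + report.off_target + report.unassigned == 2

    def test_uniform_reads_density_ratio_near_one(self, rng):
        # target = every other 500 bp block of a 100 kb contig
        frags = [Fragment("c", s, s + 500) for s in range(0, 100_000, 1000)]
        regions = make_target_bed(frags, (400, 600), {"c": 100_000})
        # point-like reads so the >=1 bp overlap rule introduces no edge bias
        starts = rng.integers(0, 100_000, size=20_000)
        reads = [("c", int(s), int(s) + 1) for s in starts]
        report = on_off_target(reads, regions)
        assert report.density_ratio == pytest.approx(1.0, rel=0.1)
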