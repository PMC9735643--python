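"""Nei's distance, distance summaries, individual distances, NJ trees."""

import re

import numpy as np
import pytest

from rrspanel.datasets import nei_d_10_varieties
from rrspanel.distance import (
    DistanceMatrix,
    allele_frequencies,
    distance_summary,
    individual_distance,
    nei_distance,
    nei_distance_matrix,
    nj_tree,
)

from conftest import make_genotype_matrix


class TestAlleleFrequencies:
    def test_hand_count(self):
        gm = make_genotype_matrix(
            [[0], [1], [2]], varieties=["v1", "v1", "v1"]
        )
        labels, freqs = allele_frequencies(gm)
        assert labels == ["v1"] and freqs[0, 0] == 0.5

    def test_all_missing_locus_undefined(self):
        gm = make_genotype_matrix([[-1], [-1]], varieties=["v1", "v1"])
        _, freqs = allele_frequencies(gm)
        assert np.isnan(freqs[0, 0])

    def test_matches_counting_oracle(self, rng):
        dosages = rng.integers(-1, 3, size=(12, 40)).astype(np.int8)
        varieties = ["a"] * 6 + ["b"] * 6
        gm = make_genotype_matrix(dosages, varieties=varieties)
        labels, freqs = allele_frequencies(gm)
        for vi, label in enumerate(labels):
            rows = dosages[np.array(varieties) == label]
            for l in range(40):
                called = rows[:, l][rows[:, l] >= 0]
                if len(called) == 0:
                    assert np.isnan(freqs[vi, l])
                else:
                    assert freqs[vi, l] == pytest.approx(
                        called.sum() / (2 * len(called))
                    )
        assert np.all((freqs >= 0) & (freqs <= 1) | np.isnan(freqs))

    def test_unlabelled_individuals_error(self):
        gm = make_genotype_matrix([[0], [1]])
        with pytest.raises(ValueError, match="variety label"):
            allele_frequencies(gm)


class TestNeiDistance:
    def test_identical_frequencies_give_zero(self, rng):
        x = rng.random(50)
        nc = nei_distance(x, x)
        assert nc.identity == pytest.approx(1.0) and nc.d == 0.0

    def test_hand_arithmetic_example(self):
        # one locus, x fixed (1,0), y at (0.5,0.5):
        # Jx=1, Jy=0.5, Jxy=0.5, I=1/sqrt(2), D=ln(2)/2
        nc = nei_distance(np.array([1.0]), np.array([0.5]))
        assert nc.jx == pytest.approx(1.0)
        assert nc.jy == pytest.approx(0.5)
        assert nc.jxy == pytest.approx(0.5)
        assert nc.d == pytest.approx(0.34657, abs=1e-5)

    def test_symmetry_and_nonnegativity(self, rng):
        for _ in range(25):
            x, y = rng.random(30), rng.random(30)
            dxy, dyx = nei_distance(x, y).d, nei_distance(y, x).d
            assert dxy == pytest.approx(dyx)
            assert dxy >= 0.0

    def test_pairwise_deletion_of_undefined_loci(self):
        x = np.array([1.0, np.nan, 0.2])
        y = np.array([0.5, 0.3, np.nan])
        nc = nei_distance(x, y)
        assert nc.n_loci == 1
        assert nc.d == pytest.approx(np.log(2) / 2)

    def test_no_shared_loci_errors(self):
        with pytest.raises(ValueError, match="no locus"):
            nei_distance(np.array([np.nan, 0.5]), np.array([0.5, np.nan]))

    def test_matrix_properties_on_synthetic(self, filtered_population):
        filtered, truth, _ = filtered_population
        dm = nei_distance_matrix(filtered)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0)
        assert np.all(dm.values >= 0)
        # founder-sharing pairs are the closest varieties
        summary = distance_summary(dm)
        top_two = {frozenset(p) for p, _ in summary["ranked_pairs"][:2]}
        assert top_two == {frozenset({"CBD1", "CBD2"}), frozenset({"BV", "Mot"})}


class TestDistanceSummary:
    def test_published_matrix_row_means_and_minima(self):
        summary = distance_summary(nei_d_10_varieties())
        assert round(summary["row_means"]["SDA"], 4) == 0.0573
        assert round(summary["row_means"]["CBD1"], 4) == 0.0575
        assert round(summary["row_means"]["CBD2"], 4) == 0.0569
        assert frozenset(summary["min_pair"]) == frozenset({"CBD1", "CBD2"})
        assert summary["min_value"] == pytest.approx(0.0095)
        assert summary["ranked_values"][1] == pytest.approx(0.0125)
        pair2, val2 = summary["ranked_pairs"][1]
        assert frozenset(pair2) == frozenset({"BV", "Mot"})

    def test_two_by_two(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 0.5], [0.5, 0]]))
        summary = distance_summary(dm)
        assert summary["row_means"] == {"a": 0.5, "b": 0.5}

    def test_row_means_match_direct_sums(self, rng):
        n = 6
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        dm = DistanceMatrix([f"p{i}" for i in range(n)], m)
        summary = distance_summary(dm)
        for i in range(n):
            expected = (m[i].sum()) / (n - 1)
            assert summary["row_means"][f"p{i}"] == pytest.approx(expected)


class TestIndividualDistance:
    def test_identical_individuals_zero(self):
        gm = make_genotype_matrix([[0, 1, 2], [0, 1, 2]])
        dm = individual_distance(gm)
        assert dm.values[0, 1] == 0.0

    def test_opposite_homozygotes(self):
        gm = make_genotype_matrix([[0], [2]])
        assert individual_distance(gm).values[0, 1] == 1.0

    def test_matches_bruteforce_loop(self, rng):
        dosages = rng.integers(-1, 3, size=(5, 30)).astype(np.int8)
        dosages[:, 0] = [0, 1, 2, 0, 1]  # guarantee a shared called locus
        gm = make_genotype_matrix(dosages)
        dm = individual_distance(gm, "allele_mismatch")
        i, j = 1, 3
        num = cnt = 0
        for l in range(30):
            if dosages[i, l] >= 0 and dosages[j, l] >= 0:
                num += abs(int(dosages[i, l]) - int(dosages[j, l])) / 2
                cnt += 1
        assert dm.values[i, j] == pytest.approx(num / cnt)

    def test_no_shared_loci_errors(self):
        gm = make_genotype_matrix([[0, -1], [-1, 2]])
        with pytest.raises(ValueError, match="no called locus"):
            individual_distance(gm)

    def test_euclidean_mode_symmetric(self, rng):
        dosages = rng.integers(-1, 3, size=(6, 20)).astype(np.int8)
        dm = individual_distance(make_genotype_matrix(dosages), "euclidean")
        assert np.allclose(dm.values, dm.values.T)


def _cherries(newick: str) -> set[frozenset]:
    """Leaf pairs that form two-leaf clades in a newick string."""
    out = set()
    for a, b in re.findall(r"\(([\w.]+):[\d.eE+-]+,([\w.]+):[\d.eE+-]+\)", newick):
        out.add(frozenset({a, b}))
    return out


class TestNJTree:
    def test_three_taxa_unique_topology(self):
        dm = DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0.0]]),
        )
        newick = nj_tree(dm)
        assert all(leaf in newick for leaf in "abc")

    def test_recovers_additive_tree(self):
        # tree: ((a:1,b:2):1.5,(c:0.5,d:1):1); additive pairwise distances
        d = {
            ("a", "b"): 3, ("a", "c"): 4, ("a", "d"): 4.5,
            ("b", "c"): 5, ("b", "d"): 5.5, ("c", "d"): 1.5,
        }
        labels = ["a", "b", "c", "d"]
        m = np.zeros((4, 4))
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                if i < j:
                    m[i, j] = m[j, i] = d[(x, y)]
        newick = nj_tree(DistanceMatrix(labels, m))
        assert frozenset({"a", "b"}) in _cherries(newick) or frozenset(
            {"c", "d"}
        ) in _cherries(newick)

    def test_published_matrix_recovers_clone_cherries(self):
        newick = nj_tree(nei_d_10_varieties())
        cherries = _cherries(newick)
        assert frozenset({"CBD1", "CBD2"}) in cherries
        assert frozenset({"BV", "Mot"}) in cherries

    def test_too_few_taxa_errors(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0.0]]))
        with pytest.raises(ValueError):
            nj_tree(dm)

    def test_no_negative_branch_lengths(self):
        newick = nj_tree(nei_d_10_varieties())
        assert not re.search(r":-\d", newick)
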