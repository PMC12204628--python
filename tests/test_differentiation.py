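"""Differentiation: WC theta, Jost's D, distances, Mantel, correlogram."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from amupopgen.differentiation import (
    PairwiseMatrix,
    geographic_distances,
    great_circle_km,
    linearize,
    mantel_correlogram,
    mantel_test,
    pairwise_fst,
    pairwise_jost_d,
)
from amupopgen.io import AmuRecord
from tests.conftest import make_table, simulate_demes


def wc_theta_oracle(pops):
    """Brute-force Weir-Cockerham theta for two samples at one locus.

    ``pops``: two lists of (a, b) genotype tuples.  Literal transcription
    of the a/b/c variance components with explicit python loops.
    """
    r = 2
    n = [len(p) for p in pops]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni**2 for ni in n) / (r * nbar)) / (r - 1)
    alleles = sorted({a for pop in pops for g in pop for a in g})
    sum_a = sum_b = sum_c = 0.0
    for allele in alleles:
        p = []
        h = []
        for pop in pops:
            copies = sum(int(g[0] == allele) + int(g[1] == allele) for g in pop)
            hets = sum(1 for g in pop if (g[0] == allele) != (g[1] == allele))
            p.append(copies / (2 * len(pop)))
            h.append(hets / len(pop))
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        sum_a += a
        sum_b += b
        sum_c += c
    return sum_a / (sum_a + sum_b + sum_c)


def jost_d_oracle(pops):
    """Brute-force Jost's D with Nei-Chesser corrections, one locus."""
    n1, n2 = len(pops[0]), len(pops[1])
    ntilde = 2 / (1 / n1 + 1 / n2)
    alleles = sorted({a for pop in pops for g in pop for a in g})
    p1 = [sum(int(g[0] == a) + int(g[1] == a) for g in pops[0]) / (2 * n1) for a in alleles]
    p2 = [sum(int(g[0] == a) + int(g[1] == a) for g in pops[1]) / (2 * n2) for a in alleles]
    hs = 1 - (sum(x**2 for x in p1) + sum(x**2 for x in p2)) / 2
    ht = 1 - sum(((a + b) / 2) ** 2 for a, b in zip(p1, p2))
    hs_est = (2 * ntilde / (2 * ntilde - 1)) * hs
    ht_est = ht + hs_est / (4 * ntilde)
    return (ht_est - hs_est) / (1 - hs_est) * 2


class TestPairwiseFst:
    def test_matches_brute_force_oracle_to_1e12(self):
        rng = np.random.default_rng(4)
        genos = rng.choice([100, 102, 104], size=(10, 1, 2))
        table, grouping = make_table(genos, amus=["A"] * 5 + ["B"] * 5)
        theta = pairwise_fst(table, grouping, n_boot=0).values[0, 1]
        oracle = wc_theta_oracle(
            [
                [tuple(g) for g in np.sort(genos[:5, 0], axis=1)],
                [tuple(g) for g in np.sort(genos[5:, 0], axis=1)],
            ]
        )
        assert theta == pytest.approx(oracle, abs=1e-12)

    def test_fixation_limit(self):
        """Two demes fixed for different alleles at every locus: theta near 1."""
        calls = [[(100, 100)] * 4] * 20 + [[(102, 102)] * 4] * 20
        table, grouping = make_table(calls, amus=["A"] * 20 + ["B"] * 20)
        theta = pairwise_fst(table, grouping, n_boot=0).values[0, 1]
        assert theta > 0.95
        # exact textbook value on the 2-allele fixed case
        oracle = wc_theta_oracle(
            [[(100, 100)] * 20, [(102, 102)] * 20]
        )
        assert theta == pytest.approx(oracle, abs=1e-12)

    def test_duplicated_population_near_zero(self):
        """One panmictic sample split randomly in two: theta within +-0.02."""
        table, samples, *_ = simulate_demes(
            1, deme_size=100, sample_size=60, n_generations=30, seed=21
        )
        rng = np.random.default_rng(0)
        halves = np.where(rng.permutation(60) < 30, "A", "B")
        grouping = pd.DataFrame(
            {"individual_id": table.individual_ids, "amu_code": halves}
        )
        theta = pairwise_fst(table, grouping, n_boot=0).values[0, 1]
        assert abs(theta) < 0.02

    def test_negative_estimates_not_truncated(self):
        table, samples, *_ = simulate_demes(
            1, deme_size=100, sample_size=40, n_generations=10, seed=5
        )
        rng = np.random.default_rng(1)
        found_negative = False
        for split_seed in range(10):
            halves = np.where(np.random.default_rng(split_seed).permutation(40) < 20, "A", "B")
            grouping = pd.DataFrame(
                {"individual_id": table.individual_ids, "amu_code": halves}
            )
            if pairwise_fst(table, grouping, n_boot=0).values[0, 1] < 0:
                found_negative = True
                break
        assert found_negative

    def test_bootstrap_significance_on_separated_demes(self, separated_three_demes):
        table, samples, *_ = separated_three_demes
        fst = pairwise_fst(table, samples, n_boot=200, seed=0)
        assert fst.significant[0, 1] and fst.significant[0, 2]


class TestJostD:
    def test_identical_frequencies_near_zero_and_vanishing(self):
        """Samples with identical allele frequencies give D ~ 0; the
        sample-size correction makes the point value slightly negative at
        finite n and it vanishes as O(1/n)."""
        ds = {}
        for n in (50, 500):
            half = [[(100, 102)]] * (n // 2) + [[(100, 100)]] * (n // 2)
            table, grouping = make_table(half + half, amus=["A"] * n + ["B"] * n)
            ds[n] = pairwise_jost_d(table, grouping, n_boot=0).values[0, 1]
        assert abs(ds[50]) < 0.01
        assert abs(ds[500]) < abs(ds[50])

    def test_disjoint_allele_sets_approach_one(self):
        calls = [[(100, 102)]] * 50 + [[(104, 106)]] * 50
        table, grouping = make_table(calls, amus=["A"] * 50 + ["B"] * 50)
        d = pairwise_jost_d(table, grouping, n_boot=0).values[0, 1]
        assert d > 0.95

    def test_matches_formula_oracle(self):
        # pop A: alleles 100/102 at 0.5 each; pop B: all 100
        calls_a = [[(100, 100)]] * 12 + [[(100, 102)]] * 1 + [[(102, 102)]] * 12
        calls_b = [[(100, 100)]] * 25
        table, grouping = make_table(calls_a + calls_b, amus=["A"] * 25 + ["B"] * 25)
        d = pairwise_jost_d(table, grouping, n_boot=0).values[0, 1]
        oracle = jost_d_oracle(
            [
                [(100, 100)] * 12 + [(100, 102)] + [(102, 102)] * 12,
                [(100, 100)] * 25,
            ]
        )
        assert d == pytest.approx(oracle, abs=1e-9)


class TestLinearize:
    def test_arithmetic(self):
        m = PairwiseMatrix(["A", "B"], np.array([[0.0, 0.2], [0.2, 0.0]]), "fst")
        assert linearize(m).values[0, 1] == pytest.approx(0.25)

    def test_fixation_maps_to_inf(self):
        m = PairwiseMatrix(["A", "B"], np.array([[0.0, 1.0], [1.0, 0.0]]), "fst")
        assert np.isinf(linearize(m).values[0, 1])

    @given(st.lists(st.floats(-0.2, 0.95), min_size=3, max_size=6))
    def test_rank_order_preserved(self, offdiag):
        n = len(offdiag)
        vals = np.array(offdiag)
        lin = vals / (1 - vals)
        assert np.array_equal(np.argsort(vals), np.argsort(lin))


class TestGeographicDistances:
    def amu(self, code, lat, lon):
        return AmuRecord(code, code, area_km2=1, census_nc=10, centroid_lat=lat, centroid_lon=lon)

    def test_identical_centroids_zero(self):
        d = geographic_distances([self.amu("A", 50, 8), self.amu("B", 50, 8)])
        assert d.values[0, 1] == 0.0

    def test_reported_minimum_pair(self):
        d = great_circle_km(50.81799, 8.24233, 50.87741, 8.18805)
        assert d == pytest.approx(7.64, abs=0.05)

    def test_reported_maximum_pair(self):
        d = great_circle_km(49.53840, 8.97384, 51.74323, 6.03374)
        assert d == pytest.approx(321.41, abs=1.0)

    def test_missing_coordinate_undefined(self):
        a = AmuRecord("A", "a", area_km2=1, census_nc=10)
        d = geographic_distances([a, self.amu("B", 50, 8)])
        assert np.isnan(d.values[0, 1])


def random_symmetric(n, rng):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return m


class TestMantel:
    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        labels = list("ABCDEF")
        m1 = PairwiseMatrix(labels, random_symmetric(6, rng), "km")
        m2 = PairwiseMatrix(labels, 3 * m1.values + 7, "fst")
        r, _ = mantel_test(m1, m2, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_exact_enumeration_for_four_labels(self):
        """With 4 labels the permutation p equals the exhaustive p over all
        4! relabelings, checked against an independent enumeration."""
        rng = np.random.default_rng(7)
        labels = list("ABCD")
        m1 = PairwiseMatrix(labels, random_symmetric(4, rng), "km")
        m2 = PairwiseMatrix(labels, random_symmetric(4, rng), "fst")
        r, p = mantel_test(m1, m2, n_perm=9999, seed=0)

        iu = np.triu_indices(4, 1)
        x = m1.values[iu]
        count = 0
        for perm in itertools.permutations(range(4)):
            pv = m2.values[np.ix_(perm, perm)][iu]
            rp = np.corrcoef(x, pv)[0, 1]
            count += rp >= r - 1e-12
        assert p == pytest.approx(count / math.factorial(4))

    def test_too_few_labels_rejected(self):
        labels = list("ABC")
        rng = np.random.default_rng(0)
        m = PairwiseMatrix(labels, random_symmetric(3, rng), "km")
        with pytest.raises(ValueError, match="at least 4"):
            mantel_test(m, m, n_perm=99, seed=0)

    def test_type_one_error_calibrated(self):
        """On independent random matrices the test rejects at ~5%."""
        rng = np.random.default_rng(3)
        labels = list("ABCDEFGH")
        rejections = 0
        n_sets = 400
        for _ in range(n_sets):
            m1 = PairwiseMatrix(labels, random_symmetric(8, rng), "km")
            m2 = PairwiseMatrix(labels, random_symmetric(8, rng), "fst")
            _, p = mantel_test(m1, m2, n_perm=199, seed=int(rng.integers(2**31)))
            rejections += p <= 0.05
        assert 0.03 <= rejections / n_sets <= 0.07


class TestMantelCorrelogram:
    def test_single_class_reduces_to_plain_mantel(self):
        rng = np.random.default_rng(5)
        labels = list("ABCDEF")
        gen = PairwiseMatrix(labels, random_symmetric(6, rng), "fst")
        km = PairwiseMatrix(labels, 50 * random_symmetric(6, rng), "km")
        out = mantel_correlogram(gen, km, class_width_km=1e6, n_perm=99, seed=0)
        r_plain, _ = mantel_test(gen, km, n_perm=99, seed=0)
        assert len(out) == 1
        assert out.iloc[0]["r"] == pytest.approx(r_plain)

    def test_stepping_stone_first_class_positive(self):
        table, samples, amus, _ = simulate_demes(
            8, deme_size=80, migration=0.05, n_generations=120, sample_size=25, seed=31
        )
        fst = pairwise_fst(table, samples, n_boot=0)
        km = geographic_distances(amus).reorder(fst.labels)
        out = mantel_correlogram(linearize(fst), km, class_width_km=40, n_perm=199, seed=0)
        assert out.iloc[0]["r"] > 0
        assert out.iloc[0]["p"] < 0.05

    def test_unstructured_data_shows_no_signal(self):
        """Panmictic metapopulation: no distance class stays significant
        after Holm correction in >=90% of replicates."""
        clean = 0
        n_reps = 10
        for rep in range(n_reps):
            M = np.full((6, 6), 1 / 6)
            table, samples, amus, _ = simulate_demes(
                6, deme_size=60, migration=M, n_generations=30, sample_size=25,
                seed=800 + rep,
            )
            fst = pairwise_fst(table, samples, n_boot=0)
            km = geographic_distances(amus).reorder(fst.labels)
            out = mantel_correlogram(fst, km, class_width_km=30, n_perm=199, seed=rep)
            if len(out) == 0:
                clean += 1
                continue
            pvals = np.sort(out["p"].to_numpy())
            m = len(pvals)
            holm_sig = np.any(pvals <= 0.05 / (m - np.arange(m)))
            clean += not holm_sig
        assert clean >= 9
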