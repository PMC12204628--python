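"""Diversity statistics: frequencies, He/Ho/Fis, richness, null alleles, HWE,
allelic potential."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import gammaln

from amupopgen.diversity import (
    allele_frequencies,
    allelic_potential,
    allelic_richness,
    basic_stats,
    hwe_exact_mc,
    null_allele_brookfield,
    private_alleles,
)
from amupopgen.simulate import inject_null_alleles
from tests.conftest import make_table


class TestAlleleFrequencies:
    def test_counts_and_normalisation(self):
        table = make_table([[(100, 100)], [(100, 102)]])
        freqs = allele_frequencies(table)
        assert freqs.freqs("all", "L1") == {100: 0.75, 102: 0.25}
        assert freqs.n_genes[("all", "L1")] == 4

    def test_missing_calls_excluded_from_gene_count(self):
        table = make_table([[(100, 100)], [(100, 102)], [(0, 0)]])
        freqs = allele_frequencies(table)
        assert freqs.n_genes[("all", "L1")] == 4

    def test_order_invariance(self):
        calls = [[(100, 102)], [(104, 104)], [(100, 100)]]
        t1, g1 = make_table(calls, amus=["A", "A", "B"])
        t2, g2 = make_table(calls[::-1], ids=["i3", "i2", "i1"], amus=["B", "A", "A"])
        f1, f2 = allele_frequencies(t1, g1), allele_frequencies(t2, g2)
        assert f1.counts == f2.counts

    def test_untyped_locus_flagged(self):
        table, grouping = make_table([[(100, 100), (0, 0)]], amus=["A"])
        freqs = allele_frequencies(table, grouping)
        assert ("A", "L2") in freqs.undefined


class TestBasicStats:
    def test_hand_computed_he_ho_fis(self):
        # {100,102},{100,100}: Ho=0.5; He=(4/3)(1-(0.75^2+0.25^2))=0.5; Fis=0
        table = make_table([[(100, 102)], [(100, 100)]])
        row = basic_stats(table, n_boot=50, seed=1).iloc[0]
        assert row["Ho"] == pytest.approx(0.5)
        assert row["He"] == pytest.approx(0.5)
        assert row["Fis"] == pytest.approx(0.0, abs=1e-12)

    def test_all_homozygous_signature(self):
        table = make_table([[(100, 100)], [(102, 102)], [(100, 100)], [(102, 102)]])
        row = basic_stats(table, n_boot=50, seed=1).iloc[0]
        assert row["Ho"] == 0.0
        assert row["Fis"] == pytest.approx(1.0)

    def test_monomorphic_population_reports_nan_fis(self):
        table = make_table([[(100, 100)], [(100, 100)]])
        row = basic_stats(table, n_boot=10, seed=1).iloc[0]
        assert row["He"] == 0.0
        assert np.isnan(row["Fis"])

    def test_mean_alleles_per_marker_from_total(self):
        """An alleles over 16 loci reproduce the reported per-marker mean of
        the smallest survey unit (85/16 = 5.3)."""
        assert round(85 / 16, 1) == 5.3

    def test_relabelling_alleles_leaves_he_ho_unchanged(self):
        calls = [[(100, 102)], [(102, 104)], [(100, 100)]]
        relabeled = [[(200, 250)], [(250, 300)], [(200, 200)]]
        a = basic_stats(make_table(calls), n_boot=0, seed=0).iloc[0]
        b = basic_stats(make_table(relabeled), n_boot=0, seed=0).iloc[0]
        assert a["He"] == b["He"] and a["Ho"] == b["Ho"]

    def test_he_estimator_is_unbiased_in_n(self):
        """Sampling genotypes from fixed frequencies: mean He at n=10 and
        n=1000 both converge on 1 - sum p^2."""
        rng = np.random.default_rng(0)
        p = np.array([0.5, 0.3, 0.2])
        target = 1 - np.sum(p**2)
        for n in (10, 1000):
            vals = []
            for _ in range(200 if n == 10 else 20):
                draws = rng.choice([100, 102, 104], p=p, size=(n, 1, 2))
                vals.append(basic_stats(make_table(draws), n_boot=0).iloc[0]["He"])
            assert np.mean(vals) == pytest.approx(target, abs=0.02)


class TestAllelicRichness:
    def test_binomial_hand_computation(self):
        # counts (3,1), N=4, g=2 -> 1 + 0.5 = 1.5
        table = make_table([[(100, 100)], [(100, 102)]])
        freqs = allele_frequencies(table)
        assert allelic_richness(freqs, g=2).iloc[0]["Ar"] == pytest.approx(1.5)

    def test_g_equal_n_recovers_observed_count(self):
        table = make_table([[(100, 102)], [(104, 100)]])
        freqs = allele_frequencies(table)
        assert allelic_richness(freqs, g=4).iloc[0]["Ar"] == pytest.approx(3.0)

    def test_monomorphic_locus_is_one(self):
        table = make_table([[(100, 100)], [(100, 100)]])
        freqs = allele_frequencies(table)
        assert allelic_richness(freqs, g=2).iloc[0]["Ar"] == pytest.approx(1.0)

    def test_monotone_in_g(self):
        table = make_table([[(100, 102)], [(104, 106)], [(100, 100)]])
        freqs = allele_frequencies(table)
        vals = [allelic_richness(freqs, g=g).iloc[0]["Ar"] for g in range(2, 7)]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_oversized_g_names_population(self):
        table, grouping = make_table([[(100, 102)], [(104, 104)]], amus=["A", "B"])
        freqs = allele_frequencies(table, grouping)
        with pytest.raises(ValueError, match="'A'|'B'"):
            allelic_richness(freqs, g=4)


class TestPrivateAlleles:
    def test_engineered_private_allele_per_deme(self):
        calls = [
            [(100, 102)], [(100, 100)],  # A carries 102 privately
            [(100, 104)], [(100, 100)],  # B carries 104 privately
            [(100, 106)], [(100, 100)],  # C carries 106 privately
        ]
        table, grouping = make_table(calls, amus=["A", "A", "B", "B", "C", "C"])
        out = private_alleles(allele_frequencies(table, grouping))
        assert out["private_alleles"].tolist() == [1, 1, 1]

    def test_shared_allele_counted_for_neither(self):
        table, grouping = make_table(
            [[(100, 102)], [(102, 100)]], amus=["A", "B"]
        )
        out = private_alleles(allele_frequencies(table, grouping))
        assert out["private_alleles"].sum() == 0

    def test_single_population_rejected(self):
        table = make_table([[(100, 102)]])
        with pytest.raises(ValueError):
            private_alleles(allele_frequencies(table))


class TestBrookfield:
    def test_direct_formula(self):
        # He=0.5, Ho=0.4 -> r = 0.1/1.5
        # construct: 10 individuals, alleles at 0.5/0.5, 4 heterozygotes
        calls = [[(100, 102)]] * 4 + [[(100, 100)]] * 3 + [[(102, 102)]] * 3
        table = make_table(calls)
        out = null_allele_brookfield(table, n_boot=50, seed=0)
        he = 20 / 19 * 0.5  # unbiased correction at n=10
        assert out.iloc[0]["estimate"] == pytest.approx((he - 0.4) / (1 + he))

    def test_sign_follows_het_deficit(self):
        excess = make_table([[(100, 102)]] * 8 + [[(100, 100)]] * 2)
        deficit = make_table([[(100, 100)]] * 5 + [[(102, 102)]] * 5)
        assert null_allele_brookfield(excess, n_boot=10, seed=0).iloc[0]["estimate"] < 0
        assert null_allele_brookfield(deficit, n_boot=10, seed=0).iloc[0]["estimate"] > 0

    def test_monomorphic_locus_degenerate(self):
        table = make_table([[(100, 100)]] * 5)
        row = null_allele_brookfield(table, n_boot=10, seed=0).iloc[0]
        assert row["estimate"] == 0.0 and not row["significant"]

    def test_detects_and_tracks_injected_null_frequency(self):
        """With nulls injected at r=0.2 into HWE genotypes, the estimator
        flags the locus (CI excludes 0) and its CI covers the estimator's
        own asymptotic target.

        Under the observation model (null/visible scored as visible
        homozygote, null/null missing), the apparent heterozygosities obey
        He_app = Hv and Ho_app = Hv (1-r)/(1+r), so (He-Ho)/(1+He)
        converges to Hv * 2r/((1+r)(1+Hv)) — below r itself, the
        estimator's documented downward bias for large null frequencies.
        """
        rng = np.random.default_rng(11)
        k, r = 8, 0.2
        p = np.ones(k) / k
        alleles = 100 + 2 * np.arange(k)
        hv = 1 - np.sum(p**2)
        target = hv * 2 * r / ((1 + r) * (1 + hv))
        detected = covered = 0
        for rep in range(20):
            draws = alleles[rng.choice(k, p=p, size=(200, 1, 2))]
            nulled = inject_null_alleles(make_table(draws), "L1", freq=r, seed=100 + rep)
            row = null_allele_brookfield(nulled, n_boot=500, seed=rep).iloc[0]
            detected += bool(row["significant"]) and row["estimate"] > 0
            covered += row["ci_low"] <= target <= row["ci_high"]
        assert detected >= 18
        assert covered >= 18


class TestHweExactMc:
    def test_monomorphic_locus_p_one(self):
        table = make_table([[(100, 100)]] * 5)
        assert hwe_exact_mc(table, locus="L1", n_perm=100, seed=0) == 1.0

    def test_extreme_heterozygote_deficit(self):
        table = make_table([[(100, 100)]] * 10 + [[(102, 102)]] * 10)
        assert hwe_exact_mc(table, locus="L1", n_perm=1000, seed=0) < 0.01

    def test_matches_exhaustive_enumeration_on_toy(self):
        """MC p on a 3-individual toy within 2 MC standard errors of the
        exact p over all orderings of the allele pool."""
        table = make_table([[(100, 102)], [(100, 100)], [(102, 102)]])
        pool = [100, 102, 100, 100, 102, 102]

        def log_prob(arr):
            arr = np.sort(np.asarray(arr).reshape(-1, 2), axis=1)
            n = arr.shape[0]
            h = int(np.sum(arr[:, 0] != arr[:, 1]))
            _, ac = np.unique(arr.ravel(), return_counts=True)
            pairs = [tuple(r) for r in arr]
            _, gc = np.unique([f"{a}-{b}" for a, b in pairs], return_counts=True)
            return (
                gammaln(n + 1) + h * math.log(2) + np.sum(gammaln(ac + 1))
                - gammaln(2 * n + 1) - np.sum(gammaln(gc + 1))
            )

        obs = log_prob([100, 102, 100, 100, 102, 102])
        hits = total = 0
        for perm in itertools.permutations(pool):
            total += 1
            hits += log_prob(perm) <= obs + 1e-9
        p_exact = hits / total
        n_perm = 2000
        p_mc = hwe_exact_mc(table, locus="L1", n_perm=n_perm, seed=3)
        se = math.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_mc - p_exact) <= 2 * se + 1 / n_perm


class TestAllelicPotential:
    @pytest.mark.parametrize(
        "an,n,nc,expected",
        [
            (85, 19, 146, 115),     # smallest unit
            (152, 48, 3488, 353),   # largest potential
            (260, 2490, 40431, 409),  # whole study area
        ],
    )
    def test_reported_values(self, an, n, nc, expected):
        assert round(allelic_potential(an, n, nc)) == expected

    def test_domain_errors(self):
        with pytest.raises(ValueError, match="domain"):
            allelic_potential(100, 1, 10000)  # x ~ 0.01 below the pole
        with pytest.raises(ValueError):
            allelic_potential(100, 0, 100)
        assert allelic_potential(0, 10, 100) == 0.0

    @given(
        an=st.integers(1, 300),
        x=st.floats(0.1, 88.0),
    )
    def test_extrapolation_never_below_observed(self, an, x):
        """For any realistic sampling fraction (below ~88%) the potential is
        at least the observed allele count."""
        nc = 10000.0
        n = max(1, round(x / 100 * nc))
        x_eff = 100 * n / nc
        if not 0.06 < x_eff <= 88.0:
            return
        assert allelic_potential(an, n, nc) >= an - 1e-9
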