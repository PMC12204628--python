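"""Per-population diversity statistics for microsatellite genotypes.

Implements the per-management-unit panel of descriptive statistics: allele
frequencies, total and mean allele counts (An, Na), Nei's unbiased expected
heterozygosity He, observed heterozygosity Ho, the multi-locus inbreeding
coefficient Fis = 1 - Ho/He with a bootstrap-over-loci CI, rarefied allelic
richness Ar, private alleles, Brookfield null-allele frequencies with a
bootstrap-over-individuals CI, a Monte-Carlo exact Hardy-Weinberg test, and
the allelic potential Na(p), an extrapolation of the observed allele count
to the full census population given the sampling fraction.

Estimator choices:

* He is Nei's sample-size-corrected estimator (2n/(2n-1))(1 - sum p^2),
  averaged over loci (monomorphic loci included in the average).
* Multi-locus Fis is the ratio of locus-averaged Ho and He rather than the
  average of per-locus ratios; the ratio form is stable when some loci are
  nearly monomorphic.
* The Hardy-Weinberg test orders genotype arrays by their conditional
  probability given the allele counts (arrays at most as probable as the
  observed one count as extreme), with the (b+1)/(n+1) permutation
  correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from amupopgen.io import GenotypeTable

__all__ = [
    "AlleleFrequencyTable",
    "allele_frequencies",
    "allelic_potential",
    "allelic_richness",
    "basic_stats",
    "hwe_exact_mc",
    "null_allele_brookfield",
    "private_alleles",
]

# Allelic potential Na(p) = An * 100 / (13.69 ln x + 38.685), where x is the
# percentage of the census that was sampled.  The denominator is the expected
# percentage of alleles detected at sampling fraction x, an empirical
# detection curve calibrated on red-deer microsatellite panels; x must exceed
# exp(-38.685/13.69) for the curve to be positive.
_NAP_SLOPE = 13.69
_NAP_INTERCEPT = 38.685


@dataclass
class AlleleFrequencyTable:
    """Allele frequencies and gene-copy counts per (population, locus).

    ``counts[(pop, locus)]`` maps allele size to its copy count among typed
    individuals; ``n_genes[(pop, locus)]`` is twice the number of typed
    individuals.  Loci with zero typed individuals in a population are
    recorded in ``undefined``.
    """

    populations: list[str]
    locus_names: list[str]
    counts: dict[tuple[str, str], dict[int, int]]
    n_genes: dict[tuple[str, str], int]
    undefined: list[tuple[str, str]]

    def freqs(self, pop: str, locus: str) -> dict[int, float]:
        n = self.n_genes[(pop, locus)]
        return {a: c / n for a, c in self.counts[(pop, locus)].items()}


def _groups(table: GenotypeTable, grouping: pd.DataFrame | None) -> dict[str, np.ndarray]:
    """Map population code -> row indices, in first-appearance order."""
    if grouping is None:
        return {"all": np.arange(table.n_individuals)}
    amu_of = dict(zip(grouping["individual_id"], grouping["amu_code"]))
    out: dict[str, list[int]] = {}
    for i, iid in enumerate(table.individual_ids):
        if iid not in amu_of:
            raise ValueError(f"individual {iid!r} missing from grouping")
        out.setdefault(amu_of[iid], []).append(i)
    return {k: np.asarray(v) for k, v in out.items()}


def allele_frequencies(
    table: GenotypeTable, grouping: pd.DataFrame | None = None
) -> AlleleFrequencyTable:
    """Count alleles per (population, locus), excluding missing calls."""
    groups = _groups(table, grouping)
    counts: dict[tuple[str, str], dict[int, int]] = {}
    n_genes: dict[tuple[str, str], int] = {}
    undefined: list[tuple[str, str]] = []
    for pop, rows in groups.items():
        sub = table.calls[rows]
        for j, locus in enumerate(table.locus_names):
            col = sub[:, j, :]
            typed = col[(col > 0).all(axis=1)]
            alleles, c = np.unique(typed.ravel(), return_counts=True)
            counts[(pop, locus)] = dict(zip(alleles.tolist(), c.tolist()))
            n_genes[(pop, locus)] = int(typed.size)
            if typed.size == 0:
                undefined.append((pop, locus))
    return AlleleFrequencyTable(
        populations=list(groups),
        locus_names=list(table.locus_names),
        counts=counts,
        n_genes=n_genes,
        undefined=undefined,
    )


def _per_locus_he_ho(
    table: GenotypeTable, rows: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Nei-unbiased He and observed Ho per locus for one population subset.

    Loci with no typed individual come back as NaN.
    """
    sub = table.calls[rows]
    n_loci = table.n_loci
    he = np.full(n_loci, np.nan)
    ho = np.full(n_loci, np.nan)
    for j in range(n_loci):
        col = sub[:, j, :]
        typed = col[(col > 0).all(axis=1)]
        n = typed.shape[0]
        if n == 0:
            continue
        ho[j] = float(np.mean(typed[:, 0] != typed[:, 1]))
        _, c = np.unique(typed.ravel(), return_counts=True)
        p = c / (2 * n)
        gene_div = 1.0 - float(np.sum(p**2))
        he[j] = gene_div * (2 * n) / (2 * n - 1) if n > 1 else gene_div
    return he, ho


def basic_stats(
    table: GenotypeTable,
    grouping: pd.DataFrame | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-population An, Na, He, Ho and Fis with a bootstrap CI over loci.

    ``Fis = 1 - mean(Ho)/mean(He)``; where a population is monomorphic at
    every locus He is 0 and Fis is reported as NaN, not 0.  The CI is a
    percentile interval over ``n_boot`` resamples of loci.
    """
    groups = _groups(table, grouping)
    freqs = allele_frequencies(table, grouping)
    rng = np.random.default_rng(seed)
    rows_out = []
    for pop, rows in groups.items():
        he, ho = _per_locus_he_ho(table, rows)
        ok = ~np.isnan(he)
        an = sum(len(freqs.counts[(pop, l)]) for l in table.locus_names)
        na = an / table.n_loci
        mean_he = float(np.mean(he[ok])) if ok.any() else np.nan
        mean_ho = float(np.mean(ho[ok])) if ok.any() else np.nan
        if mean_he and mean_he > 0:
            fis = 1.0 - mean_ho / mean_he
            idx = np.flatnonzero(ok)
            boots = np.empty(n_boot)
            for b in range(n_boot):
                pick = rng.choice(idx, size=idx.size, replace=True)
                bhe = he[pick].mean()
                boots[b] = 1.0 - ho[pick].mean() / bhe if bhe > 0 else np.nan
            if n_boot:
                lo, hi = np.nanpercentile(boots, [2.5, 97.5])
            else:
                lo, hi = np.nan, np.nan
        else:
            fis, lo, hi = np.nan, np.nan, np.nan
        rows_out.append(
            {
                "population": pop,
                "n": int(rows.size),
                "An": int(an),
                "Na": na,
                "He": mean_he,
                "Ho": mean_ho,
                "Fis": fis,
                "Fis_ci_low": lo,
                "Fis_ci_high": hi,
            }
        )
    return pd.DataFrame(rows_out)


def _rarefied_richness(counts: dict[int, int], g: int) -> float:
    """Expected allele count in a sample of g gene copies (hypergeometric)."""
    N = sum(counts.values())
    if g > N:
        raise ValueError(f"rarefaction size g={g} exceeds gene count {N}")
    # 1 - C(N - Na, g)/C(N, g) per allele, via log binomials for stability
    def log_comb(n: int, k: int) -> float:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    total = 0.0
    denom = log_comb(N, g)
    for na in counts.values():
        if N - na < g:
            total += 1.0
        else:
            total += 1.0 - math.exp(log_comb(N - na, g) - denom)
    return total


def allelic_richness(
    freqs: AlleleFrequencyTable, g: int | None = None
) -> pd.DataFrame:
    """Rarefied allelic richness Ar per population, averaged over loci.

    ``g`` is the rarefaction size in gene copies; by default the smallest
    per-(population, locus) typed gene count across the table, so every
    population is rarefied to a common footing.
    """
    if g is None:
        avail = [n for n in freqs.n_genes.values() if n > 0]
        if not avail:
            raise ValueError("no typed genotypes anywhere")
        g = min(avail)
    if g < 2:
        raise ValueError("rarefaction size must be at least 2 gene copies")
    rows = []
    for pop in freqs.populations:
        vals = []
        for locus in freqs.locus_names:
            n = freqs.n_genes[(pop, locus)]
            if n == 0:
                continue
            if g > n:
                raise ValueError(
                    f"rarefaction size g={g} exceeds gene count {n} for population "
                    f"{pop!r} at locus {locus!r}"
                )
            vals.append(_rarefied_richness(freqs.counts[(pop, locus)], g))
        rows.append({"population": pop, "Ar": float(np.mean(vals)), "g": g})
    return pd.DataFrame(rows)


def private_alleles(freqs: AlleleFrequencyTable) -> pd.DataFrame:
    """Count alleles present in exactly one population, per population."""
    if len(freqs.populations) < 2:
        raise ValueError("private alleles need at least 2 populations")
    carriers: dict[tuple[str, int], set[str]] = {}
    for (pop, locus), counts in freqs.counts.items():
        for allele in counts:
            carriers.setdefault((locus, allele), set()).add(pop)
    tally = {pop: 0 for pop in freqs.populations}
    for pops in carriers.values():
        if len(pops) == 1:
            tally[next(iter(pops))] += 1
    return pd.DataFrame(
        [{"population": p, "private_alleles": n} for p, n in tally.items()]
    )


def null_allele_brookfield(
    table: GenotypeTable,
    grouping: pd.DataFrame | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Brookfield null-allele frequency r = (He - Ho)/(1 + He) per locus.

    The 95% CI comes from ``n_boot`` bootstrap resamples of individuals
    within the population; the estimate is flagged significant when the CI
    excludes zero.  Monomorphic loci report r = 0 with a degenerate CI.
    """
    groups = _groups(table, grouping)
    rng = np.random.default_rng(seed)
    out = []
    for pop, rows in groups.items():
        he, ho = _per_locus_he_ho(table, rows)
        with np.errstate(invalid="ignore"):
            est = (he - ho) / (1.0 + he)
        boots = np.empty((n_boot, table.n_loci))
        for b in range(n_boot):
            pick = rng.choice(rows, size=rows.size, replace=True)
            bhe, bho = _per_locus_he_ho(table, pick)
            with np.errstate(invalid="ignore"):
                boots[b] = (bhe - bho) / (1.0 + bhe)
        lo = np.nanpercentile(boots, 2.5, axis=0)
        hi = np.nanpercentile(boots, 97.5, axis=0)
        for j, locus in enumerate(table.locus_names):
            mono = not np.isnan(he[j]) and he[j] == 0
            out.append(
                {
                    "population": pop,
                    "locus": locus,
                    "estimate": 0.0 if mono else est[j],
                    "ci_low": 0.0 if mono else lo[j],
                    "ci_high": 0.0 if mono else hi[j],
                    "significant": (not mono)
                    and not np.isnan(est[j])
                    and (lo[j] > 0 or hi[j] < 0),
                }
            )
    return pd.DataFrame(out)


def _log_array_prob(genotypes: np.ndarray) -> float:
    """Log conditional probability of a genotype array given allele counts.

    ``genotypes``: (n, 2) sorted allele pairs.  Uses the standard
    permutational formula P = n! 2^h prod(c_a!) / ((2n)! prod(n_ij!)).
    """
    n = genotypes.shape[0]
    h = int(np.sum(genotypes[:, 0] != genotypes[:, 1]))
    _, allele_counts = np.unique(genotypes.ravel(), return_counts=True)
    pairs = genotypes[:, 0] * 100000 + genotypes[:, 1]
    _, geno_counts = np.unique(pairs, return_counts=True)
    return float(
        gammaln(n + 1)
        + h * math.log(2.0)
        + np.sum(gammaln(allele_counts + 1))
        - gammaln(2 * n + 1)
        - np.sum(gammaln(geno_counts + 1))
    )


def hwe_exact_mc(
    table: GenotypeTable,
    population: str | None = None,
    locus: str | None = None,
    grouping: pd.DataFrame | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Monte-Carlo exact Hardy-Weinberg test for one (population, locus).

    Permutes the allele pool ``n_perm`` times, re-pairs alleles into
    genotypes, and counts permuted arrays with conditional probability at
    most that of the observed array; p = (b + 1)/(n_perm + 1).
    Monomorphic loci return p = 1.
    """
    if locus is None:
        raise ValueError("locus must be given")
    groups = _groups(table, grouping)
    if population is None:
        if len(groups) != 1:
            raise ValueError("population must be given when several are present")
        population = next(iter(groups))
    rows = groups[population]
    j = table.locus_names.index(locus)
    col = table.calls[rows][:, j, :]
    typed = col[(col > 0).all(axis=1)]
    if typed.shape[0] < 2:
        raise ValueError("need at least 2 typed individuals")
    if np.unique(typed.ravel()).size < 2:
        return 1.0
    obs = _log_array_prob(np.sort(typed, axis=1))
    pool = typed.ravel().copy()
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        rng.shuffle(pool)
        arr = np.sort(pool.reshape(-1, 2), axis=1)
        if _log_array_prob(arr) <= obs + 1e-9:
            b += 1
    return (b + 1) / (n_perm + 1)


def allelic_potential(an: int, n_samples: int, census_nc: float) -> float:
    """Allelic potential Na(p): extrapolated allele count at full census.

    ``x = 100 * n_samples / census_nc`` is the sampled percentage of the
    population; the detection curve 13.69 ln(x) + 38.685 gives the expected
    percentage of alleles already found, so Na(p) = An * 100 / curve.
    Report-rounded to the nearest integer by callers.
    """
    if an < 0:
        raise ValueError("allele count must be non-negative")
    if an == 0:
        return 0.0
    if n_samples <= 0 or census_nc <= 0:
        raise ValueError("sample count and census must be positive")
    x = 100.0 * n_samples / census_nc
    x_min = math.exp(-_NAP_INTERCEPT / _NAP_SLOPE)
    if not x_min < x <= 100.0:
        raise ValueError(
            f"sampling percentage x={x:.4g} outside the valid domain ({x_min:.4g}, 100]"
        )
    return an * 100.0 / (_NAP_SLOPE * math.log(x) + _NAP_INTERCEPT)
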