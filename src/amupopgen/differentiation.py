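"""Pairwise differentiation, geography and isolation by distance.

Pairwise Weir-Cockerham theta (Fst) and Jost's D between management units,
with bootstrap-over-loci significance; great-circle distances between unit
centroids; the Mantel permutation test and a distance-class Mantel
correlogram.

Conventions:

* theta is the multi-locus ratio of summed variance components (sum a over
  sum a+b+c); negative pair estimates are reported as computed, never
  truncated, so averages stay unbiased.
* Jost's D uses the Nei-Chesser sample-size-corrected heterozygosities per
  locus and the arithmetic mean over loci.
* The Mantel test permutes the label order of one matrix; when the number
  of labels is small enough that all permutations fit inside the requested
  count, the exact enumeration is used instead of sampling.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from amupopgen.diversity import _groups
from amupopgen.io import AmuRecord, GenotypeTable

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


@dataclass
class PairwiseMatrix:
    """Symmetric labelled matrix of one pairwise metric."""

    labels: list[str]
    values: np.ndarray
    metric: str
    pvalues: np.ndarray | None = None
    significant: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(
            np.nan_to_num(self.values), np.nan_to_num(self.values.T), atol=1e-9
        ):
            raise ValueError("matrix must be symmetric")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def reorder(self, labels: list[str]) -> "PairwiseMatrix":
        idx = [self.labels.index(l) for l in labels]
        return PairwiseMatrix(
            list(labels),
            self.values[np.ix_(idx, idx)],
            self.metric,
            None if self.pvalues is None else self.pvalues[np.ix_(idx, idx)],
            None if self.significant is None else self.significant[np.ix_(idx, idx)],
        )


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def _wc_components_pair(
    calls_a: np.ndarray, calls_b: np.ndarray
) -> tuple[float, float]:
    """Per-locus Weir-Cockerham variance components for two samples.

    ``calls_*``: (n, 2) allele pairs at one locus, missing already removed.
    Returns (sum_a, sum_abc) over alleles, or (nan, nan) when undefined.
    """
    r = 2
    n1, n2 = calls_a.shape[0], calls_b.shape[0]
    if n1 == 0 or n2 == 0:
        return np.nan, np.nan
    nbar = (n1 + n2) / r
    if nbar <= 1:
        return np.nan, np.nan
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    alleles = np.unique(np.concatenate([calls_a.ravel(), calls_b.ravel()]))
    if alleles.size < 2:
        return 0.0, 0.0
    sum_a = 0.0
    sum_abc = 0.0
    for allele in alleles:
        p1 = float(np.mean(calls_a == allele))
        p2 = float(np.mean(calls_b == allele))
        h1 = float(np.mean(np.sum(calls_a == allele, axis=1) == 1))
        h2 = float(np.mean(np.sum(calls_b == allele, axis=1) == 1))
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        sum_a += a
        sum_abc += a + b + c
    return sum_a, sum_abc


def _typed(calls: np.ndarray, j: int) -> np.ndarray:
    col = calls[:, j, :]
    return col[(col > 0).all(axis=1)]


def pairwise_fst(
    table: GenotypeTable,
    grouping: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> PairwiseMatrix:
    """Pairwise multi-locus Weir-Cockerham theta with bootstrap-over-loci CI.

    A pair is flagged significant when the bootstrap 95% CI of theta
    excludes zero.  Pairs with no shared typed polymorphic locus are NaN.
    """
    groups = _groups(table, grouping)
    labels = list(groups)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 populations")
    rng = np.random.default_rng(seed)
    values = np.zeros((n, n))
    sig = np.zeros((n, n), dtype=bool)
    for i, j in itertools.combinations(range(n), 2):
        ca, cb = table.calls[groups[labels[i]]], table.calls[groups[labels[j]]]
        comp = np.array(
            [_wc_components_pair(_typed(ca, l), _typed(cb, l)) for l in range(table.n_loci)]
        )
        ok = ~np.isnan(comp[:, 0])
        if not ok.any() or comp[ok, 1].sum() == 0:
            values[i, j] = values[j, i] = np.nan
            logger.warning("Fst undefined for pair (%s, %s)", labels[i], labels[j])
            continue
        theta = comp[ok, 0].sum() / comp[ok, 1].sum()
        values[i, j] = values[j, i] = theta
        if n_boot:
            idx = np.flatnonzero(ok)
            boots = np.empty(n_boot)
            for b in range(n_boot):
                pick = rng.choice(idx, size=idx.size, replace=True)
                denom = comp[pick, 1].sum()
                boots[b] = comp[pick, 0].sum() / denom if denom else np.nan
            lo, hi = np.nanpercentile(boots, [2.5, 97.5])
            sig[i, j] = sig[j, i] = bool(lo > 0 or hi < 0)
    return PairwiseMatrix(labels, values, "fst", significant=sig)


# ---------------------------------------------------------------------------
# Jost's D
# ---------------------------------------------------------------------------

def _jost_d_locus(calls_a: np.ndarray, calls_b: np.ndarray) -> float:
    """Jost's D at one locus for two samples (Nei-Chesser corrections)."""
    r = 2
    n1, n2 = calls_a.shape[0], calls_b.shape[0]
    if n1 == 0 or n2 == 0:
        return np.nan
    ntilde = r / (1.0 / n1 + 1.0 / n2)
    alleles = np.unique(np.concatenate([calls_a.ravel(), calls_b.ravel()]))
    p1 = np.array([np.mean(calls_a == a) for a in alleles])
    p2 = np.array([np.mean(calls_b == a) for a in alleles])
    hs = 1.0 - (np.sum(p1**2) + np.sum(p2**2)) / 2.0
    pbar = (p1 + p2) / 2.0
    ht = 1.0 - float(np.sum(pbar**2))
    hs_est = (2 * ntilde / (2 * ntilde - 1)) * hs
    ht_est = ht + hs_est / (2 * ntilde * r)
    if hs_est >= 1.0:
        return np.nan
    return (ht_est - hs_est) / (1.0 - hs_est) * r / (r - 1)


def pairwise_jost_d(
    table: GenotypeTable,
    grouping: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> PairwiseMatrix:
    """Pairwise Jost's D, arithmetic mean over loci, bootstrap over loci."""
    groups = _groups(table, grouping)
    labels = list(groups)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 populations")
    rng = np.random.default_rng(seed)
    values = np.zeros((n, n))
    sig = np.zeros((n, n), dtype=bool)
    for i, j in itertools.combinations(range(n), 2):
        ca, cb = table.calls[groups[labels[i]]], table.calls[groups[labels[j]]]
        per_locus = np.array(
            [_jost_d_locus(_typed(ca, l), _typed(cb, l)) for l in range(table.n_loci)]
        )
        ok = ~np.isnan(per_locus)
        if not ok.any():
            values[i, j] = values[j, i] = np.nan
            logger.warning("Jost's D undefined for pair (%s, %s)", labels[i], labels[j])
            continue
        values[i, j] = values[j, i] = float(per_locus[ok].mean())
        if n_boot:
            idx = np.flatnonzero(ok)
            boots = np.array(
                [per_locus[rng.choice(idx, size=idx.size, replace=True)].mean() for _ in range(n_boot)]
            )
            lo, hi = np.percentile(boots, [2.5, 97.5])
            sig[i, j] = sig[j, i] = bool(lo > 0 or hi < 0)
    return PairwiseMatrix(labels, values, "jost_d", significant=sig)


def linearize(fst: PairwiseMatrix) -> PairwiseMatrix:
    """Elementwise Fst/(1 - Fst); entries equal to 1 become +inf (flagged)."""
    vals = fst.values.copy()
    out = np.where(vals >= 1.0, np.inf, vals / (1.0 - vals))
    if np.isinf(out).any():
        logger.warning("linearize: %d entries at fixation mapped to inf", int(np.isinf(out).sum()))
    np.fill_diagonal(out, 0.0)
    return PairwiseMatrix(list(fst.labels), out, "linearized_fst")


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------

def great_circle_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine distance on a sphere of radius 6371 km."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(h))


def geographic_distances(amus: list[AmuRecord]) -> PairwiseMatrix:
    """Centre-to-centre great-circle distances (km) between unit centroids."""
    labels = [a.code for a in amus]
    n = len(labels)
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = amus[i], amus[j]
        if not (np.isfinite(a.centroid_lat) and np.isfinite(b.centroid_lat)):
            values[i, j] = values[j, i] = np.nan
            continue
        values[i, j] = values[j, i] = great_circle_km(
            a.centroid_lat, a.centroid_lon, b.centroid_lat, b.centroid_lon
        )
    return PairwiseMatrix(labels, values, "km")


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def _upper(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = math.sqrt(float(np.sum(x**2) * np.sum(y**2)))
    if denom == 0:
        return np.nan
    return float(np.sum(x * y) / denom)


def mantel_test(
    m1: PairwiseMatrix,
    m2: PairwiseMatrix,
    n_perm: int = 9999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel correlation of two distance matrices with a permutation p.

    One-sided (r as or more positive).  All n! relabelings are enumerated
    when n! <= n_perm, giving the exact p (the identity permutation
    included); otherwise ``n_perm`` random relabelings are sampled with the
    (b+1)/(n_perm+1) correction.
    """
    if m1.labels != m2.labels:
        raise ValueError("matrices must share labels in the same order")
    n = len(m1.labels)
    if n < 4:
        raise ValueError("Mantel test needs at least 4 labels")
    x = _upper(m1.values)
    r_obs = _pearson(x, _upper(m2.values))
    if math.factorial(n) <= n_perm:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            pv = m2.values[np.ix_(perm, perm)]
            if _pearson(x, _upper(pv)) >= r_obs - 1e-12:
                count += 1
            total += 1
        return r_obs, count / total
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pv = m2.values[np.ix_(perm, perm)]
        if _pearson(x, _upper(pv)) >= r_obs - 1e-12:
            b += 1
    return r_obs, (b + 1) / (n_perm + 1)


def mantel_correlogram(
    genetic: PairwiseMatrix,
    km: PairwiseMatrix,
    class_width_km: float = 20.0,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Distance-class correlogram of genetic vs geographic distance.

    For each class (lower, upper] of geographic distance, computes the
    Pearson correlation of genetic and geographic distance over the pairs
    inside the class, with a permutation p from relabelling the genetic
    matrix (class membership kept fixed).  A single class covering every
    distance therefore reduces to the plain Mantel statistic.  Empty or
    near-empty classes are skipped and logged.

    Returns a frame with ``class_upper, n_pairs, r, p`` plus the attribute
    ``positive_up_to_km``: the largest class upper edge up to which classes
    are contiguously positive with p < 0.05.
    """
    if genetic.labels != km.labels:
        raise ValueError("matrices must share labels in the same order")
    n = len(genetic.labels)
    iu = np.triu_indices(n, k=1)
    gvals = genetic.values[iu]
    kvals = km.values[iu]
    max_km = float(np.nanmax(kvals))
    n_classes = max(1, int(math.ceil(max_km / class_width_km)))
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_classes):
        lo, hi = c * class_width_km, (c + 1) * class_width_km
        mask = (kvals > lo) & (kvals <= hi) if c > 0 else (kvals >= 0) & (kvals <= hi)
        if mask.sum() < 3:
            logger.info("correlogram: class (%.0f, %.0f] km has <3 pairs, skipped", lo, hi)
            continue
        r = _pearson(gvals[mask], kvals[mask])
        b = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            pg = genetic.values[np.ix_(perm, perm)][iu]
            rp = _pearson(pg[mask], kvals[mask])
            if not np.isnan(rp) and rp >= r - 1e-12:
                b += 1
        rows.append(
            {"class_upper": hi, "n_pairs": int(mask.sum()), "r": r, "p": (b + 1) / (n_perm + 1)}
        )
    out = pd.DataFrame(rows)
    positive_up_to = 0.0
    for _, row in out.iterrows():
        if row["r"] > 0 and row["p"] < 0.05:
            positive_up_to = row["class_upper"]
        else:
            break
    out.attrs["positive_up_to_km"] = positive_up_to
    return out
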