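"""Cluster-prevalence connectivity, distance decay, region merging, isolation.

Connectivity between two management units is the percentage agreement of
their cluster-prevalence distributions: 100 times the sum over clusters of
the elementwise minimum of the two prevalence vectors.  Identical
prevalences give 100, disjoint cluster use gives 0 — the natural bounded
overlap of two probability vectors, which matches reported within-region
values near 80-100.  The kernel is pluggable.

Downstream rules:

* only neighbour pairs within a maximum centre-to-centre distance
  (default 40 km, the realistic dispersal range of young deer) enter the
  connectivity analysis;
* mean connectivity decays with distance as a power law y = a x^b fitted
  on log-log scale;
* pairs deviating by at least +-10 percentage points from the fitted decay
  are classed higher/lower than expected;
* neighbour pairs are linked into regions when at least two of three
  criteria hold (admixture-clustering connectivity > 40, DAPC connectivity
  > 40, Fst < 0.05; thresholds strict); regions are the connected
  components of the link graph (transitive merging);
* a unit is classified by the best combined connectivity among its
  neighbours: >= 40 connected, < 40 isolated, <= 20 highly isolated; a
  unit with no neighbour inside the radius is isolated by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from amupopgen.differentiation import PairwiseMatrix
from amupopgen.io import AmuRecord

logger = logging.getLogger(__name__)


def pair_connectivity(prev_a: np.ndarray, prev_b: np.ndarray) -> float:
    """Percentage overlap of two cluster-prevalence vectors (0-100)."""
    prev_a = np.asarray(prev_a, dtype=float)
    prev_b = np.asarray(prev_b, dtype=float)
    if prev_a.shape != prev_b.shape:
        raise ValueError(f"prevalence K mismatch: {prev_a.shape} vs {prev_b.shape}")
    for v, name in ((prev_a, "a"), (prev_b, "b")):
        if not math.isclose(float(v.sum()), 1.0, abs_tol=1e-6):
            raise ValueError(f"prevalence vector {name} must sum to 1")
    return 100.0 * float(np.minimum(prev_a, prev_b).sum())


def connectivity_matrix(prevalence: pd.DataFrame, method: str = "connectivity") -> PairwiseMatrix:
    """All-pairs connectivity from a per-AMU prevalence table (rows sum to 1)."""
    labels = prevalence.index.tolist()
    arr = prevalence.to_numpy(dtype=float)
    n = len(labels)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = pair_connectivity(arr[i], arr[j])
    return PairwiseMatrix(labels, values, "connectivity")


def combine_methods(matrices: list[PairwiseMatrix]) -> tuple[PairwiseMatrix, np.ndarray]:
    """Unweighted mean connectivity across methods, NaN-aware.

    Each method's matrix lives in its own cluster space; only the final
    percentages are averaged.  Returns the combined matrix and the count of
    contributing methods per pair.
    """
    if not matrices:
        raise ValueError("no matrices to combine")
    labels = matrices[0].labels
    stack = []
    for m in matrices:
        if m.labels != labels:
            m = m.reorder(labels)
        stack.append(m.values)
    arr = np.stack(stack)
    counts = np.sum(~np.isnan(arr), axis=0)
    with np.errstate(invalid="ignore"):
        combined = np.nanmean(arr, axis=0)
    combined[counts == 0] = np.nan
    np.fill_diagonal(combined, 100.0)
    return PairwiseMatrix(list(labels), combined, "connectivity"), counts


def neighbour_pairs(
    amus: list[AmuRecord], km: PairwiseMatrix, max_km: float = 40.0
) -> list[tuple[str, str, float]]:
    """Unordered AMU pairs with centre-to-centre distance <= ``max_km``."""
    codes = [a.code for a in amus]
    out = []
    for i in range(len(codes)):
        for j in range(i + 1, len(codes)):
            d = km.get(codes[i], codes[j])
            if not np.isnan(d) and 0 < d <= max_km:
                out.append((codes[i], codes[j], float(d)))
    return out


@dataclass
class DecayFit:
    """Power-law fit y = a x^b of connectivity vs distance."""

    a: float
    b: float
    r_squared: float
    binned: pd.DataFrame  # columns bin_upper, mean_km, mean_connectivity, n_pairs

    def predict(self, km: float | np.ndarray) -> float | np.ndarray:
        return self.a * np.power(km, self.b)


# distance bins: 10-km steps to 40 km, 20-km steps to 200 km, then one open
# bin; bins are (lower, upper] and labelled by the upper edge, so a pair at
# 41 km falls in the (40, 60] bin labelled 60 and one at 80 km in (60, 80]
BIN_EDGES = [0.0, 10.0, 20.0, 30.0, 40.0] + [40.0 + 20.0 * i for i in range(1, 9)] + [math.inf]


def fit_distance_decay(pairs: list[tuple[float, float]]) -> DecayFit:
    """Least-squares power-law fit of connectivity on distance (log-log).

    ``pairs`` are (km, connectivity%) tuples; zero-connectivity pairs are
    excluded from the log fit (logged), as are non-positive distances.
    R-squared is reported on the log scale.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (km, connectivity) tuples")
    ok = (arr[:, 0] > 0) & (arr[:, 1] > 0)
    if (~ok).any():
        logger.warning("distance-decay fit: %d non-positive pairs excluded", int((~ok).sum()))
    arr = arr[ok]
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 usable pairs for the decay fit")
    lx = np.log(arr[:, 0])
    ly = np.log(arr[:, 1])
    b, loga = np.polyfit(lx, ly, 1)
    pred = loga + b * lx
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    bins = []
    for lo, hi in zip(BIN_EDGES[:-1], BIN_EDGES[1:]):
        mask = (arr[:, 0] > lo) & (arr[:, 0] <= hi)
        if not mask.any():
            continue
        bins.append(
            {
                "bin_upper": hi,
                "mean_km": float(arr[mask, 0].mean()),
                "mean_connectivity": float(arr[mask, 1].mean()),
                "n_pairs": int(mask.sum()),
            }
        )
    return DecayFit(float(np.exp(loga)), float(b), float(r2), pd.DataFrame(bins))


def classify_deviation(actual: float, predicted: float, margin: float = 10.0) -> str:
    """Class of actual minus fitted connectivity: higher / lower / as_expected.

    Boundaries inclusive: a difference of exactly +-10 points is already
    higher/lower.
    """
    for v, name in ((actual, "actual"), (predicted, "predicted")):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} connectivity {v} outside [0, 100]")
    d = actual - predicted
    if d >= margin:
        return "higher"
    if d <= -margin:
        return "lower"
    return "as_expected"


@dataclass
class RegionPartition:
    """Partition of AMUs into merged regions plus the per-pair criteria."""

    assignment: dict[str, str]  # amu_code -> region_id
    regions: dict[str, list[str]]  # region_id -> member codes
    pair_flags: pd.DataFrame  # a, b, conn_structure, conn_dapc, fst, flags, linked


def merge_regions(
    conn_structure: PairwiseMatrix,
    conn_dapc: PairwiseMatrix,
    fst: PairwiseMatrix,
    pairs: list[tuple[str, str, float]],
    conn_threshold: float = 40.0,
    fst_threshold: float = 0.05,
) -> RegionPartition:
    """Link neighbour pairs meeting >=2 of 3 criteria; regions = components.

    Criteria (strict): admixture-clustering connectivity > 40, DAPC
    connectivity > 40, Fst < 0.05.  Pairs with a missing matrix entry are
    skipped and logged.  Singletons remain their own region.
    """
    labels = conn_structure.labels
    g = nx.Graph()
    g.add_nodes_from(labels)
    rows = []
    for a, b, _km in pairs:
        cs = conn_structure.get(a, b)
        cd = conn_dapc.get(a, b)
        f = fst.get(a, b)
        if any(np.isnan(v) for v in (cs, cd, f)):
            logger.warning("merge: pair (%s, %s) skipped, missing matrix entry", a, b)
            continue
        flags = (cs > conn_threshold, cd > conn_threshold, f < fst_threshold)
        linked = sum(flags) >= 2
        if linked:
            g.add_edge(a, b)
        rows.append(
            {
                "a": a,
                "b": b,
                "conn_structure": cs,
                "conn_dapc": cd,
                "fst": f,
                "structure_ok": flags[0],
                "dapc_ok": flags[1],
                "fst_ok": flags[2],
                "linked": linked,
            }
        )
    assignment: dict[str, str] = {}
    regions: dict[str, list[str]] = {}
    comps = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    for k, comp in enumerate(comps, start=1):
        rid = f"R{k:02d}"
        members = sorted(comp)
        regions[rid] = members
        for code in members:
            assignment[code] = rid
    return RegionPartition(assignment, regions, pd.DataFrame(rows))


def classify_isolation(
    combined: PairwiseMatrix,
    pairs: list[tuple[str, str, float]],
    isolation_threshold: float = 40.0,
    high_isolation_threshold: float = 20.0,
) -> pd.DataFrame:
    """Per-AMU isolation status from the best neighbour connectivity.

    Status: ``connected`` (best >= 40), ``isolated`` (best < 40),
    ``highly_isolated`` (best <= 20).  Units without any neighbour inside
    the radius are isolated by default and flagged.
    """
    best: dict[str, float] = {code: np.nan for code in combined.labels}
    for a, b, _km in pairs:
        v = combined.get(a, b)
        if np.isnan(v):
            continue
        for code in (a, b):
            if np.isnan(best[code]) or v > best[code]:
                best[code] = v
    rows = []
    for code in combined.labels:
        v = best[code]
        if np.isnan(v):
            status, no_nbr = "isolated", True
        elif v <= high_isolation_threshold:
            status, no_nbr = "highly_isolated", False
        elif v < isolation_threshold:
            status, no_nbr = "isolated", False
        else:
            status, no_nbr = "connected", False
        rows.append(
            {
                "amu_code": code,
                "best_neighbour_connectivity": v,
                "status": status,
                "no_neighbour_within_radius": no_nbr,
            }
        )
    return pd.DataFrame(rows)
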