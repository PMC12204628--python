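"""Effective population size and heterozygosity-decay threat classification.

Two routes to Ne:

* the linkage-disequilibrium (Burrows composite r^2) single-sample
  estimator with random-mating bias corrections: mean r^2 over inter-locus
  allele pairs (alleles screened at a critical frequency Pcrit), minus the
  expected sampling contribution E[r^2|S], inverted to Ne.  The Pcrit rule
  follows sample size: 0.02 below 50 genotyped individuals, 0.01 at 50 or
  more.
* demographic formulas from the counts of reproducing animals: the harem-
  polygamy form Ne = 4 Nm Nf / (2 Nm + Nf) and the lottery-polygyny form
  Ne = 4 m f N / (1 + m/n), with m and f the sex proportions and n the
  lifetime breeding success of females.

Bookkeeping per management unit: the consensus Ne is the three-way mean of
the two demographic values and the LD estimate at the rule's Pcrit; the
"taken" Ne is the LD estimate for clearly isolated small units
(Nc < 1000), the consensus otherwise.  Ne/Nc uses the consensus; the
expected loss of heterozygosity per generation is ELHG = 100/(2 Ne_taken) %.

Threat classification: generations until observed heterozygosity decays to
the empirical 0.54 threshold under Ht = Ho (1 - 1/(2Ne))^t; t <= 10 / 50 /
100 mark critically endangered / endangered / vulnerable.  The class is
directly applicable only to isolated units; for connected ones it is
conditional on future isolation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from amupopgen.diversity import _groups
from amupopgen.io import GenotypeTable

__all__ = [
    "DemographicInput",
    "LdNeResult",
    "NeSummary",
    "ThreatRecord",
    "classify_threat",
    "generations_to_threshold",
    "ld_ne",
    "ne_caballero",
    "ne_summary",
    "ne_wang",
    "pcrit_rule",
]

HET_THRESHOLD = 0.54  # empirical 25% quantile of microsatellite heterozygosity
THREAT_BOUNDS = (10.0, 50.0, 100.0)


def pcrit_rule(n_samples: int) -> float:
    """Critical allele frequency by sample size: <50 -> 0.02, >=50 -> 0.01."""
    if n_samples < 1:
        raise ValueError("sample size must be at least 1")
    return 0.02 if n_samples < 50 else 0.01


@dataclass
class LdNeResult:
    """LD-method Ne estimate and its ingredients."""

    ne: float  # math.inf when the corrected r^2 is non-positive
    r2_mean: float
    r2_expected: float
    r2_prime: float
    s_harmonic: float
    n_comparisons: int
    pcrit: float

    @property
    def infinite(self) -> bool:
        return not math.isfinite(self.ne)


def _ld_ne_from_r2(r2_mean: float, s: float) -> tuple[float, float, float]:
    """Bias correction and inversion; returns (ne, expected, r2_prime)."""
    if s >= 30:
        expected = 1.0 / s + 3.19 / s**2
    else:
        expected = 0.0018 + 0.907 / s + 4.44 / s**2
    r2p = r2_mean - expected
    if r2p <= 0:
        return math.inf, expected, r2p
    if s >= 30:
        disc = max(0.0, 1.0 / 9.0 - 2.76 * r2p)
        ne = (1.0 / 3.0 + math.sqrt(disc)) / (2.0 * r2p)
    else:
        disc = max(0.0, 0.308**2 - 2.08 * r2p)
        ne = (0.308 + math.sqrt(disc)) / (2.0 * r2p)
    return ne, expected, r2p


def ld_ne(
    table: GenotypeTable,
    grouping: pd.DataFrame | None = None,
    population: str | None = None,
    pcrit: float = 0.02,
) -> LdNeResult:
    """Single-sample LD Ne for one population at one Pcrit.

    For every pair of loci and every retained allele pair, the Burrows
    composite disequilibrium is estimated from the individuals typed at
    both loci (with the S/(S-1) small-sample factor) and squared against
    the product of allele variances; comparisons are weighted by their
    sample size and S is their harmonic mean.  Biallelic loci contribute a
    single allele to avoid duplicate comparisons.
    """
    groups = _groups(table, grouping)
    if population is None:
        if len(groups) != 1:
            raise ValueError("population must be given when several are present")
        population = next(iter(groups))
    rows = groups[population]
    calls = table.calls[rows]

    # per locus: retained alleles (freq >= pcrit) and per-individual dosage
    use: list[tuple[int, list[int]]] = []  # (locus index, allele values used)
    dosages: dict[tuple[int, int], np.ndarray] = {}
    typed_mask: dict[int, np.ndarray] = {}
    for j in range(table.n_loci):
        col = calls[:, j, :]
        typed = (col > 0).all(axis=1)
        typed_mask[j] = typed
        if typed.sum() < 2:
            continue
        alleles, counts = np.unique(col[typed].ravel(), return_counts=True)
        freqs = counts / counts.sum()
        # single-copy alleles are always excluded (the screening exists to
        # remove them); pcrit additionally removes rare alleles
        retained = alleles[(freqs >= pcrit) & (counts >= 2)]
        if retained.size < 2:
            continue
        used = [int(retained[0])] if retained.size == 2 else [int(a) for a in retained]
        use.append((j, used))
        for a in used:
            dosages[(j, a)] = (col == a).sum(axis=1).astype(float)
    if len(use) < 2:
        raise ValueError(
            f"population {population!r}: fewer than 2 usable loci at pcrit={pcrit}"
        )

    r2_vals: list[float] = []
    weights: list[float] = []
    inv_s: list[float] = []
    for (j1, al1), (j2, al2) in itertools.combinations(use, 2):
        both = typed_mask[j1] & typed_mask[j2]
        s = int(both.sum())
        if s < 3:
            continue
        for a in al1:
            x = dosages[(j1, a)][both]
            pa = x.mean() / 2.0
            va = pa * (1 - pa)
            if va <= 0:
                continue
            for b in al2:
                y = dosages[(j2, b)][both]
                pb = y.mean() / 2.0
                vb = pb * (1 - pb)
                if vb <= 0:
                    continue
                delta = float(np.mean(x * y)) / 2.0 - 2.0 * pa * pb
                delta *= s / (s - 1)
                r2 = delta**2 / (va * vb)
                r2_vals.append(r2)
                weights.append(s)
                inv_s.append(1.0 / s)
    if not r2_vals:
        raise ValueError(f"population {population!r}: no usable locus-pair comparisons")
    w = np.asarray(weights)
    r2_mean = float(np.average(r2_vals, weights=w))
    s_harm = len(inv_s) / float(np.sum(inv_s))
    ne, expected, r2p = _ld_ne_from_r2(r2_mean, s_harm)
    return LdNeResult(ne, r2_mean, expected, r2p, s_harm, len(r2_vals), pcrit)


# ---------------------------------------------------------------------------
# Demographic formulas
# ---------------------------------------------------------------------------

def ne_wang(nm: float, nf: float) -> float:
    """Harem-polygamy effective size Ne = 4 Nm Nf / (2 Nm + Nf)."""
    if nm < 0 or nf < 0:
        raise ValueError("reproducing counts must be non-negative")
    if nm + nf == 0:
        raise ValueError("at least one reproducing animal required")
    denom = 2 * nm + nf
    return 4.0 * nm * nf / denom if denom > 0 else 0.0


def ne_caballero(m: float, f: float, n: float, n_lbs: float) -> float:
    """Lottery-polygyny effective size Ne = 4 m f N / (1 + m/n_lbs)."""
    if not math.isclose(m + f, 1.0, abs_tol=1e-9):
        raise ValueError("sex proportions m + f must equal 1")
    if n_lbs <= 0:
        raise ValueError("lifetime breeding success must be positive")
    return 4.0 * m * f * n / (1.0 + m / n_lbs)


@dataclass
class DemographicInput:
    """Counts of reproducing animals and derived proportions for one unit."""

    nm: float  # reproducing males
    nf: float  # reproducing females
    n: float  # census used in the lottery-polygyny formula
    m: float | None = None  # proportion of males; default Nm/(Nm+Nf)
    f: float | None = None
    n_lbs: float = 1.0  # lifetime breeding success of females

    def __post_init__(self) -> None:
        if self.nm < 0 or self.nf < 0:
            raise ValueError("reproducing counts must be non-negative")
        if self.m is None or self.f is None:
            total = self.nm + self.nf
            if total <= 0:
                raise ValueError("cannot derive sex proportions from zero counts")
            self.m = self.nm / total
            self.f = self.nf / total
        if self.n_lbs <= 0:
            raise ValueError("lifetime breeding success must be positive")


@dataclass
class NeSummary:
    """Per-unit effective-size bookkeeping."""

    amu_code: str
    ld_ne: dict[float, float]  # pcrit -> estimate
    ne_wang: float
    ne_caballero: float
    ne_consensus: float
    ne_taken: float
    source_taken: str  # "ld" or "consensus"
    ne_nc: float
    elhg_percent: float
    pcrit_used: float
    isolated: bool


def ne_summary(
    amu_code: str,
    ld_estimates: dict[float, float],
    demographic: DemographicInput,
    isolated: bool,
    census_nc: float,
    n_samples: int,
) -> NeSummary:
    """Combine LD and demographic estimates into the per-unit summary.

    The consensus is the three-way mean of the Wang and Caballero values
    and the LD estimate at the sample-size Pcrit; the taken Ne is the LD
    estimate only for isolated units with Nc < 1000.  Ne/Nc (consensus
    over census) is rounded to 2 decimals; ELHG = 100/(2 Ne_taken) %.
    """
    wang = ne_wang(demographic.nm, demographic.nf)
    caballero = ne_caballero(demographic.m, demographic.f, demographic.n, demographic.n_lbs)
    pcrit = pcrit_rule(n_samples)
    if pcrit not in ld_estimates:
        raise ValueError(f"AMU {amu_code}: no LD estimate at the rule's pcrit {pcrit}")
    ld_at_rule = ld_estimates[pcrit]
    if not math.isfinite(ld_at_rule):
        consensus = float("nan")
    else:
        consensus = (wang + caballero + ld_at_rule) / 3.0
    if isolated and census_nc < 1000:
        taken, source = ld_at_rule, "ld"
    else:
        taken, source = consensus, "consensus"
    if not math.isfinite(taken) or taken <= 0:
        raise ValueError(f"AMU {amu_code}: taken Ne undefined (infinite LD estimate needed)")
    return NeSummary(
        amu_code=amu_code,
        ld_ne=dict(ld_estimates),
        ne_wang=wang,
        ne_caballero=caballero,
        ne_consensus=consensus,
        ne_taken=taken,
        source_taken=source,
        ne_nc=round(consensus / census_nc, 2),
        elhg_percent=100.0 / (2.0 * taken),
        pcrit_used=pcrit,
        isolated=isolated,
    )


# ---------------------------------------------------------------------------
# Threat classification
# ---------------------------------------------------------------------------

def generations_to_threshold(ho: float, ne: float, ht: float = HET_THRESHOLD) -> float:
    """Generations until heterozygosity decays from Ho to the Ht threshold.

    Solves Ht = Ho (1 - 1/(2 Ne))^t; populations already at or below the
    threshold return 0.
    """
    if not 0.0 < ho <= 1.0:
        raise ValueError("Ho must lie in (0, 1]")
    if ne <= 0.5:
        raise ValueError("Ne must exceed 0.5 for the decay factor to be positive")
    if ho <= ht:
        return 0.0
    return math.log(ht / ho) / math.log(1.0 - 1.0 / (2.0 * ne))


@dataclass
class ThreatRecord:
    """Threat class of one unit under the heterozygosity-decay criterion."""

    amu_code: str
    ho: float
    ne_taken: float
    t_generations: float
    category: str
    isolated: bool
    applies: bool  # directly applicable only to isolated units


def classify_threat(
    t: float,
    isolated: bool,
    amu_code: str = "",
    ho: float = float("nan"),
    ne: float = float("nan"),
) -> ThreatRecord:
    """Map t to a class: <=10 critical, <=50 endangered, <=100 vulnerable."""
    if t < 0:
        raise ValueError("t must be non-negative")
    crit, endg, vuln = THREAT_BOUNDS
    if t <= crit:
        category = "critically_endangered"
    elif t <= endg:
        category = "endangered"
    elif t <= vuln:
        category = "vulnerable"
    else:
        category = "not_threatened"
    return ThreatRecord(
        amu_code=amu_code,
        ho=ho,
        ne_taken=ne,
        t_generations=t,
        category=category,
        isolated=isolated,
        applies=bool(isolated),
    )
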