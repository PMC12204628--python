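"""Worked-example reference values: German red-deer management units.

Printed per-unit inputs and expected outputs from the red-deer survey of
two German federal states (North Rhine-Westphalia, NRW, and Hesse, HE)
that the package's design is modelled on.  They serve as golden worked
examples: the functions in :func:`amupopgen.pipeline.verify_reference_values`
recompute every expected number from the inputs at run time.

All values are survey inputs (allele counts, sample counts, census
estimates, centroids, heterozygosities, effective-size estimates), not
anything this package computes from raw genotypes.
"""

from __future__ import annotations

# --- allelic potential -----------------------------------------------------
# code -> (An observed alleles, n_samples, census Nc, expected Na(p))
ALLELIC_POTENTIAL_CASES: dict[str, tuple[int, int, float, int]] = {
    "NRW": (250, 1199, 18080, 387),
    "HE": (194, 1291, 22351, 309),
    "ALL": (260, 2490, 18080 + 22351, 409),
    "RK": (85, 19, 146, 115),
    "EZM": (152, 48, 3488, 353),
}

# --- effective-size bookkeeping --------------------------------------------
# code -> dict with the unit's LD estimates per Pcrit, demographic Ne values,
# census, sample count, isolation status and the expected derived numbers.
NE_BOOKKEEPING_CASES: dict[str, dict] = {
    "RK": {
        "ld": {0.00: 8.7, 0.01: 8.7, 0.02: 8.7, 0.05: 13.4},
        "wang": 43.80,
        "caballero": 25.76,
        "census_nc": 146,
        "n_samples": 19,
        "isolated": True,
        "expected_consensus": 26.09,
        "expected_taken": 8.7,
        "expected_ne_nc": 0.18,
        "expected_elhg": 5.75,
    },
    "EI": {
        "ld": {0.00: 154.8, 0.01: 313.5, 0.02: 328.9, 0.05: 343.3},
        "wang": 2226.21,
        "caballero": 1352.18,
        "census_nc": 8217,
        "n_samples": 353,
        "isolated": False,
        "expected_consensus": 1297.30,
        "expected_taken": 1297.30,
        "expected_ne_nc": 0.16,
        "expected_elhg": 0.04,
    },
    "NS": {
        "ld": {0.00: 17.7, 0.01: 17.7, 0.02: 17.7, 0.05: 6.8},
        "wang": 19.38,
        "caballero": 11.59,
        "census_nc": 67,
        "n_samples": 12,
        "isolated": True,
        "expected_consensus": 16.22,
        "expected_taken": 17.7,
        "expected_ne_nc": 0.24,
        "expected_elhg": 2.82,
    },
}

# --- threat classification -------------------------------------------------
# Isolated units with both printed inputs available:
# code -> (observed heterozygosity Ho, taken Ne).
ISOLATED_THREAT_INPUTS: dict[str, tuple[float, float]] = {
    "RK": (0.55, 8.7),
    "HX": (0.65, 53.4),
    "EB": (0.70, 19.3),
    "NS": (0.67, 17.7),
    "MI": (0.65, 52.5),
    "WH": (0.70, 99.7),
    "SE": (0.69, 110.8),
    "WW": (0.69, 31.5),
    "RW": (0.66, 161.1),
}
EXPECTED_CRITICALLY_ENDANGERED = 3

# --- geography --------------------------------------------------------------
# code -> (centroid latitude, centroid longitude), degrees
AMU_CENTROIDS: dict[str, tuple[float, float]] = {
    "DB": (50.81799, 8.24233),
    "SIO": (50.87741, 8.18805),
    "OD": (49.53840, 8.97384),
    "RK": (51.74323, 6.03374),
}
EXPECTED_MIN_DISTANCE_KM = 7.64  # DB - SIO
EXPECTED_MAX_DISTANCE_KM = 321.41  # OD - RK

# --- misc worked values ------------------------------------------------------
# RK row of the survey's AMU description table
RK_AMU_ROW = {
    "code": "RK",
    "area_km2": 41.3,
    "census_nc": 146,
    "n_samples": 19,
    "lat": 51.74323,
    "lon": 6.03374,
}
# RK diversity row: An alleles over 16 loci gives the printed mean Na
RK_DIVERSITY = {"An": 85, "n_loci": 16, "expected_Na": 5.3}
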