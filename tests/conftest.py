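"""Shared fixtures: tiny hand-built genotype tables and simulation helpers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from amupopgen.io import GenotypeTable
from amupopgen.simulate import SimConfig, simulate_metapopulation

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_table(calls, locus_names=None, ids=None, amus=None):
    """Build a GenotypeTable (and optional grouping) from nested call lists.

    ``calls``: list per individual of (a, b) pairs per locus; 0 = missing.
    """
    calls = np.asarray(calls, dtype=np.int64)
    n, n_loci = calls.shape[0], calls.shape[1]
    ids = ids or [f"i{k + 1}" for k in range(n)]
    locus_names = locus_names or [f"L{j + 1}" for j in range(n_loci)]
    table = GenotypeTable(ids, locus_names, calls)
    if amus is None:
        return table
    grouping = pd.DataFrame({"individual_id": ids, "amu_code": amus})
    return table, grouping


@pytest.fixture
def two_pop_toy():
    """Two populations of 2 individuals at 2 loci, no missing data."""
    return make_table(
        [
            [(100, 102), (140, 140)],
            [(100, 100), (140, 142)],
            [(104, 104), (144, 144)],
            [(104, 106), (144, 146)],
        ],
        amus=["A", "A", "B", "B"],
    )


def simulate_demes(
    n_demes,
    deme_size=50,
    migration=0.0,
    n_generations=60,
    sample_size=30,
    seed=0,
    missing_rate=0.02,
    **kwargs,
):
    """Convenience wrapper used across the suite."""
    cfg = SimConfig(
        n_demes=n_demes,
        deme_sizes=[deme_size] * n_demes,
        migration=migration,
        n_loci=kwargs.pop("n_loci", 16),
        n_generations=n_generations,
        sample_sizes=[sample_size] * n_demes,
        missing_rate=missing_rate,
        seed=seed,
        **kwargs,
    )
    return simulate_metapopulation(cfg)


@pytest.fixture(scope="session")
def separated_three_demes():
    """Three demes with no gene flow — strongly separable structure."""
    return simulate_demes(3, n_generations=60, seed=901)
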