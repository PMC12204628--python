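"""End-to-end orchestration and golden-value verification.

:func:`run_pipeline` executes the stages in dependency order —
I/O -> diversity -> differentiation -> clustering -> connectivity ->
demography — from a single :class:`PipelineConfig`, writing deterministic
TSV tables.  Every threshold is configuration with the study's standard
values as defaults; a single seed expands into per-stage seeds through a
documented counter scheme so each stage is independently reproducible.

:func:`verify_reference_values` recomputes the shipped worked-example
numbers (allelic potential, effective-size bookkeeping, threat counts,
centroid distances) from their inputs and reports pass/fail per check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from amupopgen import clustering, connectivity, demography, differentiation, diversity
from amupopgen import reference
from amupopgen.io import AmuRecord, GenotypeTable, write_results

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of one pipeline run; defaults are the study's values."""

    n_boot: int = 1000
    n_perm: int = 9999
    k_min: int = 1
    k_max: int = 8
    em_replicates: int = 3
    max_km: float = 40.0
    merge_conn_threshold: float = 40.0
    merge_fst_threshold: float = 0.05
    isolation_threshold: float = 40.0
    high_isolation_threshold: float = 20.0
    threat_bounds: tuple[float, float, float] = (10.0, 50.0, 100.0)
    het_threshold: float = 0.54
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_km < 0 or self.n_boot < 0 or self.n_perm < 0:
            raise ValueError("counts and distances must be non-negative")
        if not (0 < self.high_isolation_threshold <= self.isolation_threshold):
            raise ValueError("isolation thresholds must be positive and ordered")

    def stage_seed(self, stage: int) -> int:
        """Per-stage seed: deterministic counter expansion of the base seed."""
        return int(np.random.default_rng([self.seed, stage]).integers(2**31))


def run_pipeline(
    table: GenotypeTable,
    samples: pd.DataFrame,
    amus: list[AmuRecord],
    config: PipelineConfig | None = None,
    demographics: dict[str, demography.DemographicInput] | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Run every stage on one dataset; optionally write the report tables.

    Returns the tables keyed by name (diversity, fst, jost_d, km, mantel,
    prevalence_em, prevalence_dapc, connectivity, regions, isolation and —
    when per-unit demographic inputs are supplied — ne_summary, threat).
    """
    cfg = config or PipelineConfig()
    results: dict[str, pd.DataFrame] = {}

    # -- diversity ----------------------------------------------------------
    freqs = diversity.allele_frequencies(table, samples)
    stats = diversity.basic_stats(table, samples, n_boot=cfg.n_boot, seed=cfg.stage_seed(1))
    richness = diversity.allelic_richness(freqs)
    div = stats.merge(richness[["population", "Ar"]], on="population")
    if len(freqs.populations) > 1:
        div = div.merge(diversity.private_alleles(freqs), on="population")
    nap = []
    amu_by_code = {a.code: a for a in amus}
    for _, row in div.iterrows():
        a = amu_by_code.get(row["population"])
        try:
            nap.append(
                round(diversity.allelic_potential(int(row["An"]), a.n_samples, a.census_nc))
                if a is not None
                else np.nan
            )
        except ValueError:
            nap.append(np.nan)
    div["Na_p"] = nap
    results["diversity"] = div
    logger.info("diversity: %d populations", len(div))

    # -- differentiation ----------------------------------------------------
    fst = differentiation.pairwise_fst(table, samples, n_boot=cfg.n_boot, seed=cfg.stage_seed(2))
    jost = differentiation.pairwise_jost_d(table, samples, n_boot=cfg.n_boot, seed=cfg.stage_seed(3))
    km = differentiation.geographic_distances(amus).reorder(fst.labels)
    results["fst"] = fst.to_frame().reset_index(names="amu")
    results["jost_d"] = jost.to_frame().reset_index(names="amu")
    results["km"] = km.to_frame().reset_index(names="amu")
    if len(fst.labels) >= 4:
        lin = differentiation.linearize(fst)
        r, p = differentiation.mantel_test(lin, km, n_perm=cfg.n_perm, seed=cfg.stage_seed(4))
        results["mantel"] = pd.DataFrame([{"r": r, "p": p, "n_labels": len(fst.labels)}])

    # -- clustering ---------------------------------------------------------
    n_demes_hint = len(fst.labels)
    k_em = min(max(cfg.k_min, n_demes_hint), cfg.k_max)
    q_em = clustering.em_admixture(table, K=k_em, seed=cfg.stage_seed(5))
    q_dapc, _rep = clustering.dapc_cluster(
        table, k_range=range(cfg.k_min, min(cfg.k_max, table.n_individuals - 1) + 1),
        seed=cfg.stage_seed(6),
    )
    prev_em = clustering.amu_prevalence(q_em, samples)
    prev_dapc = clustering.amu_prevalence(q_dapc, samples)
    results["prevalence_em"] = prev_em.reset_index()
    results["prevalence_dapc"] = prev_dapc.reset_index()

    # -- connectivity ---------------------------------------------------------
    conn_em = connectivity.connectivity_matrix(prev_em)
    conn_dapc = connectivity.connectivity_matrix(prev_dapc)
    combined, _counts = connectivity.combine_methods(
        [conn_em.reorder(fst.labels), conn_dapc.reorder(fst.labels)]
    )
    pairs = connectivity.neighbour_pairs(amus, km, max_km=cfg.max_km)
    results["connectivity"] = combined.to_frame().reset_index(names="amu")
    if pairs:
        regions = connectivity.merge_regions(
            conn_em.reorder(fst.labels), conn_dapc.reorder(fst.labels), fst, pairs,
            conn_threshold=cfg.merge_conn_threshold, fst_threshold=cfg.merge_fst_threshold,
        )
        results["regions"] = pd.DataFrame(
            [{"amu_code": c, "region": r} for c, r in sorted(regions.assignment.items())]
        )
    else:
        logger.info("connectivity: no neighbour pairs within %.0f km", cfg.max_km)
        results["regions"] = pd.DataFrame(columns=["amu_code", "region"])
    isolation = connectivity.classify_isolation(
        combined, pairs,
        isolation_threshold=cfg.isolation_threshold,
        high_isolation_threshold=cfg.high_isolation_threshold,
    )
    results["isolation"] = isolation

    # -- demography -----------------------------------------------------------
    if demographics:
        iso_by_code = dict(zip(isolation["amu_code"], isolation["status"]))
        ne_rows, threat_rows = [], []
        div_by_pop = div.set_index("population")
        for a in amus:
            if a.code not in demographics:
                continue
            pcrits = (0.00, 0.01, 0.02, 0.05)
            ld = {}
            for pc in pcrits:
                try:
                    ld[pc] = demography.ld_ne(table, samples, a.code, pcrit=pc).ne
                except ValueError:
                    ld[pc] = float("nan")
            isolated = iso_by_code.get(a.code, "isolated") != "connected"
            try:
                summ = demography.ne_summary(
                    a.code, ld, demographics[a.code], isolated, a.census_nc, a.n_samples
                )
            except ValueError as exc:
                logger.warning("demography: %s", exc)
                continue
            ne_rows.append(
                {
                    "amu_code": a.code,
                    **{f"ld_pcrit_{pc:g}": ld[pc] for pc in pcrits},
                    "ne_wang": summ.ne_wang,
                    "ne_caballero": summ.ne_caballero,
                    "ne_consensus": summ.ne_consensus,
                    "ne_taken": summ.ne_taken,
                    "source_taken": summ.source_taken,
                    "ne_nc": summ.ne_nc,
                    "elhg_percent": summ.elhg_percent,
                }
            )
            ho = float(div_by_pop.loc[a.code, "Ho"]) if a.code in div_by_pop.index else np.nan
            if np.isfinite(ho) and ho > 0:
                t = demography.generations_to_threshold(ho, summ.ne_taken, cfg.het_threshold)
                rec = demography.classify_threat(t, isolated, a.code, ho, summ.ne_taken)
                threat_rows.append(
                    {
                        "amu_code": a.code,
                        "Ho": ho,
                        "ne_taken": summ.ne_taken,
                        "t_generations": t,
                        "category": rec.category,
                        "applies": rec.applies,
                    }
                )
        results["ne_summary"] = pd.DataFrame(ne_rows)
        results["threat"] = pd.DataFrame(threat_rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        for name, df in results.items():
            write_results(df, out_dir / f"{name}.tsv")
        cfg_echo = pd.DataFrame([{k: str(v) for k, v in vars(cfg).items()}])
        write_results(cfg_echo, out_dir / "config_echo.tsv")
    return results


def verify_reference_values() -> pd.DataFrame:
    """Recompute every shipped worked-example number and report pass/fail."""
    checks = []

    for code, (an, n, nc, expected) in reference.ALLELIC_POTENTIAL_CASES.items():
        got = round(diversity.allelic_potential(an, n, nc))
        checks.append(("allelic_potential", code, got, expected, got == expected))

    for code, case in reference.NE_BOOKKEEPING_CASES.items():
        pcrit = demography.pcrit_rule(case["n_samples"])
        ld_at_rule = case["ld"][pcrit]
        consensus = (case["wang"] + case["caballero"] + ld_at_rule) / 3.0
        taken = ld_at_rule if case["isolated"] and case["census_nc"] < 1000 else consensus
        elhg = 100.0 / (2.0 * taken)
        ne_nc = round(consensus / case["census_nc"], 2)
        checks.append(
            ("ne_consensus", code, round(consensus, 2), case["expected_consensus"],
             round(consensus, 2) == case["expected_consensus"])
        )
        checks.append(
            ("ne_taken", code, round(taken, 2), case["expected_taken"],
             abs(taken - case["expected_taken"]) < 0.01)
        )
        checks.append(("ne_nc", code, ne_nc, case["expected_ne_nc"], ne_nc == case["expected_ne_nc"]))
        checks.append(
            ("elhg_percent", code, round(elhg, 2), case["expected_elhg"],
             round(elhg, 2) == case["expected_elhg"])
        )

    n_critical = 0
    for code, (ho, ne) in reference.ISOLATED_THREAT_INPUTS.items():
        t = demography.generations_to_threshold(ho, ne)
        if t <= demography.THREAT_BOUNDS[0]:
            n_critical += 1
    checks.append(
        ("critically_endangered_count", "isolated", n_critical,
         reference.EXPECTED_CRITICALLY_ENDANGERED,
         n_critical == reference.EXPECTED_CRITICALLY_ENDANGERED)
    )

    d_min = differentiation.great_circle_km(
        *reference.AMU_CENTROIDS["DB"], *reference.AMU_CENTROIDS["SIO"]
    )
    d_max = differentiation.great_circle_km(
        *reference.AMU_CENTROIDS["OD"], *reference.AMU_CENTROIDS["RK"]
    )
    checks.append(
        ("min_distance_km", "DB-SIO", round(d_min, 2), reference.EXPECTED_MIN_DISTANCE_KM,
         abs(d_min - reference.EXPECTED_MIN_DISTANCE_KM) <= 0.05)
    )
    checks.append(
        ("max_distance_km", "OD-RK", round(d_max, 2), reference.EXPECTED_MAX_DISTANCE_KM,
         abs(d_max - reference.EXPECTED_MAX_DISTANCE_KM) <= 1.0)
    )

    na = reference.RK_DIVERSITY["An"] / reference.RK_DIVERSITY["n_loci"]
    checks.append(
        ("mean_alleles_per_locus", "RK", round(na, 1), reference.RK_DIVERSITY["expected_Na"],
         round(na, 1) == reference.RK_DIVERSITY["expected_Na"])
    )

    return pd.DataFrame(checks, columns=["check", "case", "computed", "expected", "passed"])
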