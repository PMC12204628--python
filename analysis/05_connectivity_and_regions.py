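"""Cluster-prevalence connectivity, distance decay, region merging and
isolation status for the simulated management units."""

from pathlib import Path

import pandas as pd

from amupopgen import read_tables, write_results
from amupopgen.clustering import amu_prevalence, read_q_matrix
from amupopgen.connectivity import (
    classify_deviation,
    classify_isolation,
    combine_methods,
    connectivity_matrix,
    fit_distance_decay,
    merge_regions,
    neighbour_pairs,
)
from amupopgen.differentiation import geographic_distances, pairwise_fst

DATA = Path("results/sim_data")
SEED = 404

table, samples, amus = read_tables(DATA / "genotypes.csv", DATA / "samples.csv", DATA / "amus.csv")
q_em = read_q_matrix("results/q_em.tsv", dialect="tsv", known_ids=table.individual_ids)
q_dapc = read_q_matrix("results/q_dapc.tsv", dialect="tsv", known_ids=table.individual_ids)

conn_em = connectivity_matrix(amu_prevalence(q_em, samples))
conn_dapc = connectivity_matrix(amu_prevalence(q_dapc, samples))
combined, counts = combine_methods([conn_em, conn_dapc.reorder(conn_em.labels)])
write_results(combined.to_frame().reset_index(names="amu"), "results/connectivity.tsv")

km = geographic_distances(amus).reorder(combined.labels)
pairs = neighbour_pairs(amus, km, max_km=40)
print(f"{len(pairs)} neighbour pairs within 40 km")

decay_rows = [(d, combined.get(a, b)) for a, b, d in pairs if combined.get(a, b) > 0]
fit = fit_distance_decay(decay_rows)
print(f"distance decay: connectivity = {fit.a:.1f} * km^{fit.b:.2f}  (R^2 = {fit.r_squared:.2f})")
deviations = pd.DataFrame(
    [
        {
            "a": a, "b": b, "km": d,
            "actual": combined.get(a, b),
            "predicted": float(fit.predict(d)),
            "class": classify_deviation(
                combined.get(a, b), min(100.0, float(fit.predict(d)))
            ),
        }
        for a, b, d in pairs
    ]
)
write_results(deviations, "results/deviations.tsv")

fst = pairwise_fst(table, samples, n_boot=0).reorder(combined.labels)
partition = merge_regions(conn_em, conn_dapc.reorder(conn_em.labels), fst, pairs)
regions = pd.DataFrame(
    [{"amu_code": c, "region": r} for c, r in sorted(partition.assignment.items())]
)
write_results(regions, "results/regions.tsv")
print("regions (>=2 of: clustering connectivity >40, DAPC connectivity >40, Fst <0.05):")
for rid, members in partition.regions.items():
    print(f"  {rid}: {', '.join(members)}")

isolation = classify_isolation(combined, pairs)
write_results(isolation, "results/isolation.tsv")
print(isolation.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
print("wrote results/connectivity.tsv, deviations.tsv, regions.tsv, isolation.tsv")
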