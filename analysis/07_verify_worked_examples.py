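"""Recompute the shipped worked-example numbers (allelic potential,
effective-size bookkeeping, threat counts, centroid distances) and report
pass/fail for each."""

from amupopgen import write_results
from amupopgen.pipeline import verify_reference_values

report = verify_reference_values()
write_results(report, "results/reference_checks.tsv")
print(report.to_string(index=False))
n_fail = int((~report["passed"]).sum())
print(f"\n{len(report) - n_fail}/{len(report)} checks passed")
raise SystemExit(1 if n_fail else 0)
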