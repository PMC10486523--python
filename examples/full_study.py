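"""End-to-end synthetic study: simulate, analyze, report.

Runs the complete pipeline on a seeded 14-patient synthetic cohort (one
patient lacking post-treatment tissue, as is common in window-of-opportunity
designs), printing the TIL shift test, the strongest feature-TIL
correlations and the provenance block that makes the run reproducible.
"""

from immunomri import CohortSpec, StudyConfig, run_pipeline

config = StudyConfig(simulate=True, cohort=CohortSpec(n_patients=14, seed=3), seed=3)
report = run_pipeline(config)

t = report.til_paired_test
print(f"TIL shift (paired t, n={t['n']}): mean delta {t['mean_diff']:+.2f} deciles, "
      f"p = {t['p']:.3g}")

rho = report.correlation_table["delta_til_rho"].dropna()
print("\nstrongest feature correlations with the TIL change:")
for row, val in rho.abs().sort_values(ascending=False).head(4).items():
    print(f"  {row:10s} rho = {report.correlation_table.loc[row, 'delta_til_rho']:+.2f} "
          f"(n = {int(report.correlation_table.loc[row, 'delta_til_n'])})")

print(f"\ncluster labels: {report.cluster_labels.value_counts().to_dict()}")
print(f"provenance: version {report.provenance['package_version']}, "
      f"config {report.provenance['config_hash']}, seed {report.provenance['seed']}")
# Rerunning with the same config reproduces every number byte-identically.
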