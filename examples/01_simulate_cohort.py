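"""Simulate a two-arm trial cohort and look at its survival structure.

Builds the default synthetic world: 246 control and 234 treatment patients,
baseline covariates (age, sex, ECOG, extent of disease, pain intensity),
15 log-normal plasma biomarkers, Weibull baseline hazard tuned to a ~5.9-month
control median, and right censoring.
"""

import survchart as sc

cfg = sc.SimConfig(seed=1)
cohort = sc.simulate_cohort(cfg)
df = cohort.to_frame()

print(f"cohort: {len(cohort)} patients "
      f"({(df['arm'] == 'control').sum()} control / "
      f"{(df['arm'] == 'treatment').sum()} treatment)")
print(f"events observed: {df['event'].mean():.1%} of patients")

for arm in ("control", "treatment"):
    sub = df[df["arm"] == arm]
    km = sc.km_curve(sub["time_months"], sub["event"])
    print(f"{arm:>9}-arm median OS: {km.median:.2f} months")

print(f"biomarkers: {', '.join(cohort.marker_names)}")
print("\nThe control median sits near 5.9 months and the treatment arm a few")
print("tenths above it - the small overall benefit the monitored trial saw.")
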