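"""Validate a predictive biomarker with per-subgroup risk-adjusted charts.

Patients are split at the marker cut-point; each class gets its own Phase-I
fit (its control arm), freshly calibrated limits, and a chart over its
treatment-arm patients.  If the marker is truly predictive, low-side signals
(survival better than the control-arm model predicts) concentrate in the
benefiting class.
"""

import math

import survchart as sc

cfg = sc.SimConfig(
    seed=14,
    treatment_loghr=math.log(1.341),
    interactions=[sc.Interaction("HER2", 0.5, math.log(0.659 / 1.341), side="high")],
)
cohort = sc.simulate_cohort(cfg)
cut = sc.max_logrank_cutpoint(cohort, "HER2").cutpoint

charts = sc.subgroup_charts(
    cohort, "HER2", cut,
    sc.ChartConfig(alpha=0.005, calibration_reps=300, seed=14),
    censoring=cfg.censoring,
)
for label, series in charts.items():
    tab = series.table
    print(f"{label}-expression class: {len(series)} monitored cases, "
          f"low-side signals at {series.signal_low_indices.tolist()}, "
          f"high-side at {series.signal_high_indices.tolist()}, "
          f"mean chart statistic {tab['ewma'].mean():+.2f}")

print("\nLow-side alarms in the high-HER2 class mark treatment-sensitive")
print("patients; the low class runs hotter (larger chart statistic, high-side")
print("alarms), consistent with the treatment doing harm below the cut.")
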