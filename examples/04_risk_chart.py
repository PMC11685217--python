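"""Monitor treatment-arm survival risk against a control-arm Cox model.

Phase I fits a Cox model (ECOG, extent of disease, pain intensity) with a
Breslow baseline on the control arm.  Phase II scores each treatment-arm
patient by a standardized martingale residual - observed minus model-expected
cumulative hazard - smooths the sequence with an EWMA (lambda = 0.1), and
compares it with Monte-Carlo control limits calibrated to a 0.5% per-case
false-alarm rate.  A low-side signal = survival significantly better than the
control-arm model predicts.
"""

import survchart as sc

cfg = sc.SimConfig(seed=1)
cohort = sc.simulate_cohort(cfg)
control = cohort.subset(cohort.to_frame()["arm"] == "control")
test = cohort.subset(cohort.to_frame()["arm"] == "treatment")

fit = sc.fit_cox(control, ["ecog", "eod", "pi"])
chart_cfg = sc.ChartConfig(ewma_lambda=0.1, alpha=0.005, calibration_reps=500, seed=1)
limits = sc.calibrate_limits(fit, control, len(test), chart_cfg, censoring=cfg.censoring)
series = sc.monitor_sequence(test, fit, limits, chart_cfg)

print(f"monitored {len(series)} treatment-arm cases")
print(f"low-side signals (better survival than expected): "
      f"{series.signal_low_indices.tolist()}")
print(f"high-side signals (worse survival than expected): "
      f"{series.signal_high_indices.tolist()}")

oc = sc.oc_study(fit, control, [0.0, -0.69], chart_cfg, limits=limits,
                 n_sequence=234, n_reps=100, censoring=cfg.censoring)
print("\noperating characteristics (per-case signal rates):")
print(oc.round(4).to_string(index=False))
print("\nAt shift 0 the total rate sits near the 0.5% design target; halving")
print("every hazard (shift -0.69) sends the low-side rate far above it.")
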