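"""End-to-end orchestration of the analysis.

Stages, in order: cohort (load or simulate) -> baseline comparison table ->
Cox screening of baseline covariates (univariate + multivariable with BH
adjustment and a Schoenfeld PH check) -> global risk-adjusted EWMA chart
(control arm = Phase I, treatment arm monitored) -> biomarker cut-point
search -> interaction models -> bootstrap stability of the significant
markers -> subgroup-level charts.  Each stage writes a CSV/JSON artifact into
the output directory and is recorded, with its seed, in ``manifest.json`` so
any stage can be reproduced or re-run from intermediate files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_io
from .chart import ChartConfig, calibrate_limits, monitor_sequence
from .cohort import TrialCohort, baseline_table
from .cox import bh_adjust, fit_cox, schoenfeld_ph_test
from .cutpoints import bootstrap_cutpoint_stability, screen_markers, subgroup_charts
from .simulate import SimConfig, simulate_cohort

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "baseline", "cox", "chart", "cutpoints", "interactions", "bootstrap",
    "subgroup_charts",
)


@dataclass
class PipelineConfig:
    """Full pipeline parameterization.

    Exactly one of ``cohort_path`` (CSV in the documented schema) or
    ``sim_config`` must be provided.
    """

    output_dir: str | Path
    cohort_path: str | Path | None = None
    sim_config: SimConfig | None = None
    covariates: tuple = ("age", "sex", "ecog", "eod", "pi")
    markers: tuple | None = None  # None = all markers in the cohort
    chart: ChartConfig = field(default_factory=ChartConfig)
    bootstrap_reps: int = 1000
    minprop: float = 0.1
    significance: float = 0.05
    stages: tuple = ALL_STAGES
    subset: str | None = None  # e.g. "sex==1" or "age<=65" (sensitivity refit)
    seed: int = 0

    def __post_init__(self):
        if (self.cohort_path is None) == (self.sim_config is None):
            raise ValueError("exactly one of cohort_path and sim_config must be set")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the manifest dict.

    Stage artifacts land in ``config.output_dir``; any stage failure aborts
    with the stage name while earlier artifacts remain on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}

    if config.cohort_path is not None:
        cohort = cohort_io.read_cohort(config.cohort_path)
        manifest["input"] = {"cohort_path": str(config.cohort_path)}
    else:
        cohort = simulate_cohort(config.sim_config, seed=config.seed)
        cohort_io.write_cohort(cohort, out / "cohort.csv")
        manifest["input"] = {"simulated": True, "seed": config.seed,
                            "path": str(out / "cohort.csv")}
    if config.subset:
        n0 = len(cohort)
        cohort = cohort.subset(cohort.to_frame().eval(config.subset).to_numpy(bool))
        manifest["subset"] = {"expr": config.subset, "n_before": n0, "n_after": len(cohort)}

    markers = list(config.markers) if config.markers else list(cohort.marker_names)
    prognostic = None  # set by the cox stage; chart stages fall back to defaults

    def _record(stage, path, **extra):
        manifest["stages"][stage] = {"seed": config.seed, **extra}
        manifest["outputs"][stage] = str(path)

    try:
        if "baseline" in config.stages:
            tab = baseline_table(cohort, list(config.covariates))
            tab.to_csv(out / "baseline_table.csv", index=False)
            _record("baseline", out / "baseline_table.csv")

        if "cox" in config.stages:
            # covariates constant in the (possibly subset) cohort are skipped
            screenable = [
                cv for cv in config.covariates
                if np.ptp(cohort.covariate_matrix([cv])) > 0
            ]
            uni_rows = []
            for cv in screenable:
                r = fit_cox(cohort, [cv]).hazard_ratios().iloc[0]
                uni_rows.append({**r.to_dict(), "model": "univariate"})
            uni = pd.DataFrame(uni_rows)
            sig_uni = uni.loc[uni["p"] < config.significance, "covariate"].tolist()
            multi_covs = sig_uni or screenable
            mfit = fit_cox(cohort, multi_covs)
            multi = mfit.hazard_ratios()
            multi["adjusted_p"] = bh_adjust(multi["p"].to_numpy())
            multi["model"] = "multivariable"
            screening = pd.concat([uni, multi], ignore_index=True)
            screening.to_csv(out / "cox_screening.csv", index=False)
            ph = schoenfeld_ph_test(mfit, cohort)
            ph.to_csv(out / "ph_check.csv", index=False)
            prognostic = multi.loc[
                multi["adjusted_p"] < config.significance, "covariate"
            ].tolist() or multi_covs
            _record("cox", out / "cox_screening.csv",
                    multivariable=multi_covs, prognostic=prognostic)

        phase1_covs = tuple(prognostic or ("ecog", "eod", "pi"))
        ctrl = cohort.subset(cohort.to_frame()["arm"] == "control")
        test = cohort.subset(cohort.to_frame()["arm"] == "treatment")
        censoring = config.sim_config.censoring if config.sim_config else None

        if "chart" in config.stages:
            fit = fit_cox(ctrl, list(phase1_covs))
            limits = calibrate_limits(fit, ctrl, len(test), config.chart,
                                      censoring=censoring)
            series = monitor_sequence(test, fit, limits, config.chart)
            series.to_csv(out / "chart_series.csv")
            _record("chart", out / "chart_series.csv",
                    phase1_covariates=list(phase1_covs),
                    limit_multiplier=limits.multiplier, sigma_u=limits.sigma_u,
                    signal_low=series.signal_low_indices.tolist(),
                    signal_high=series.signal_high_indices.tolist())

        cut_table = None
        if "cutpoints" in config.stages or "interactions" in config.stages:
            cut_table = screen_markers(cohort, markers, minprop=config.minprop,
                                       adjust=phase1_covs)
        if "cutpoints" in config.stages:
            cut_table[["marker", "cutpoint", "max_logrank_stat"]].to_csv(
                out / "cutpoints.csv", index=False)
            _record("cutpoints", out / "cutpoints.csv")
        if "interactions" in config.stages:
            cut_table.to_csv(out / "interactions.csv", index=False)
            sig = cut_table.loc[
                cut_table["interaction_p"] < config.significance, "marker"
            ].tolist()
            _record("interactions", out / "interactions.csv", significant=sig)

        if "bootstrap" in config.stages:
            if cut_table is None:
                raise RuntimeError("bootstrap stage requires the cutpoints stage")
            sig = cut_table[cut_table["interaction_p"] < config.significance]
            rows = []
            for _, r in sig.iterrows():
                prop, skipped = bootstrap_cutpoint_stability(
                    cohort, r["marker"], r["cutpoint"],
                    n_boot=config.bootstrap_reps, seed=config.seed,
                    adjust=phase1_covs, alpha=config.significance,
                )
                rows.append({"marker": r["marker"], "cutpoint": r["cutpoint"],
                             "stability_proportion": prop, "skipped": skipped,
                             "n_boot": config.bootstrap_reps})
            pd.DataFrame(rows).to_csv(out / "bootstrap_stability.csv", index=False)
            _record("bootstrap", out / "bootstrap_stability.csv",
                    n_boot=config.bootstrap_reps)

        if "subgroup_charts" in config.stages:
            if cut_table is None:
                raise RuntimeError("subgroup_charts stage requires the cutpoints stage")
            sig = cut_table[cut_table["interaction_p"] < config.significance]
            summary = []
            for _, r in sig.iterrows():
                try:
                    charts = subgroup_charts(cohort, r["marker"], r["cutpoint"],
                                             config.chart,
                                             phase1_covariates=phase1_covs,
                                             censoring=censoring)
                except ValueError as exc:
                    logger.warning("subgroup chart skipped: %s", exc)
                    continue
                for label, series in charts.items():
                    path = out / f"subgroup_chart_{r['marker']}_{label}.csv"
                    series.to_csv(path)
                    summary.append(
                        {"marker": r["marker"], "class": label, "n": len(series),
                         "signal_low": series.signal_low_indices.tolist(),
                         "signal_high": series.signal_high_indices.tolist(),
                         "path": str(path)}
                    )
            with open(out / "subgroup_charts.json", "w") as fh:
                json.dump(summary, fh, indent=2)
            _record("subgroup_charts", out / "subgroup_charts.json")
    except Exception as exc:
        manifest["error"] = {"stage": _current_stage(manifest), "message": str(exc)}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _current_stage(manifest: dict) -> str:
    done = list(manifest["stages"])
    for st in ALL_STAGES:
        if st not in done:
            return st
    return "finalize"
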