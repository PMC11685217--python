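"""Predictive-biomarker identification.

For each continuous biomarker: (1) find the cut-point maximizing the absolute
standardized log-rank statistic between the induced low/high groups
(maximally selected rank statistic); (2) test whether the dichotomized marker
modifies the treatment effect via a Cox model with a treatment x marker-class
interaction term; (3) assess stability by refitting the interaction model on
bootstrap resamples with the cut-point held fixed; (4) validate by running the
risk-adjusted EWMA chart separately within the high- and low-expression
subgroups.

The "high" class is defined as marker value strictly greater than the
cut-point.  No selection-adjusted p-value (Lausen-Schumacher) is applied to
the maximally selected statistic, and no multiplicity adjustment is applied
across markers by default; both are documented limitations / options.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chart import ChartConfig, ChartSeries, calibrate_limits, monitor_sequence
from .cohort import TrialCohort
from .cox import fit_cox, km_curve, logrank_test
from .simulate import CensoringConfig

DEFAULT_ADJUST = ("ecog", "eod", "pi")


@dataclass(frozen=True)
class CutpointResult:
    """Outcome of the maximal log-rank cut-point search for one marker."""

    marker: str
    cutpoint: float  # an observed marker value
    max_statistic: float  # |standardized log-rank| at the cut-point
    candidates: np.ndarray = field(repr=False)  # candidate cut values
    statistics: np.ndarray = field(repr=False)  # signed standardized profile
    minprop: float = 0.1

    @property
    def profile(self) -> pd.DataFrame:
        return pd.DataFrame({"cutpoint": self.candidates, "statistic": self.statistics})


def _logrank_profile(x, time, event, candidates):
    """Signed standardized log-rank statistic for every candidate cut.

    Vectorized over candidates: at each distinct event time the at-risk and
    event counts of the high group (marker > cut) are computed for all cuts at
    once.  Returns ``z`` with NaN where a candidate leaves a side without any
    event (statistic undefined there).
    """
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    high = x[order][:, None] > candidates[None, :]  # (n, m)
    n, m = high.shape

    starts = np.flatnonzero(np.concatenate([[True], t[1:] != t[:-1]]))
    d = np.add.reduceat(e, starts).astype(float)  # events per distinct time
    ev = d > 0
    n_risk = (n - starts).astype(float)

    # high-group at-risk (suffix sums) and high-group events per time
    nb = np.cumsum(high[::-1].astype(np.float64), axis=0)[::-1][starts]  # (G, m)
    db = np.add.reduceat(e[:, None] * high, starts, axis=0).astype(float)

    use = ev & (n_risk > 1)
    frac = nb[use] / n_risk[use, None]
    o_minus_e = (db[use] - d[use, None] * frac).sum(axis=0)
    var = (
        (d[use, None] * frac * (1.0 - frac))
        * ((n_risk[use] - d[use]) / (n_risk[use] - 1.0))[:, None]
    ).sum(axis=0)

    ev_high = db[ev].sum(axis=0)
    ev_low = d[ev].sum() - ev_high
    z = np.full(m, np.nan)
    ok = (var > 0) & (ev_high >= 1) & (ev_low >= 1)
    z[ok] = o_minus_e[ok] / np.sqrt(var[ok])
    return z


def max_logrank_cutpoint(cohort, marker: str, minprop: float = 0.1) -> CutpointResult:
    """Maximally selected log-rank cut-point for one biomarker.

    Candidates are the unique observed marker values whose low (<= value) /
    high (> value) split leaves at least ``minprop`` of the patients on each
    side and at least one event on each side.  Returns the candidate
    maximizing the absolute standardized log-rank statistic; ties break
    toward the smaller cut value.
    """
    if not 0.0 < minprop < 0.5:
        raise ValueError("minprop must lie in (0, 0.5)")
    df = cohort.to_frame() if isinstance(cohort, TrialCohort) else cohort
    x = df[marker].to_numpy(float)
    time = df["time_months"].to_numpy(float)
    event = df["event"].to_numpy(int)
    if np.ptp(x) == 0:
        raise ValueError(f"marker {marker!r} is constant")
    n = x.size
    uniq = np.unique(x)
    lo_count = np.searchsorted(np.sort(x), uniq, side="right")
    keep = (lo_count >= minprop * n) & ((n - lo_count) >= minprop * n)
    candidates = uniq[keep]
    if candidates.size == 0:
        raise ValueError(f"no valid candidate cut-point for marker {marker!r}")
    z = _logrank_profile(x, time, event, candidates)
    valid = ~np.isnan(z)
    if not valid.any():
        raise ValueError(f"no valid candidate cut-point for marker {marker!r}")
    candidates, z = candidates[valid], z[valid]
    best = int(np.argmax(np.abs(z)))  # first argmax = smallest cut on ties
    return CutpointResult(
        marker=marker, cutpoint=float(candidates[best]),
        max_statistic=float(abs(z[best])),
        candidates=candidates, statistics=z, minprop=minprop,
    )


@dataclass
class InteractionResult:
    """Treatment-by-marker-class interaction model summary."""

    marker: str
    cutpoint: float
    interaction_coef: float
    interaction_hr: float
    ci_low: float
    ci_high: float
    p_value: float
    subgroups: pd.DataFrame = field(repr=False)  # per-class treatment effect
    adjusted_for: tuple = ()
    bootstrap_proportion: float | None = None

    def to_row(self) -> dict:
        return {
            "marker": self.marker, "cutpoint": self.cutpoint,
            "interaction_HR": self.interaction_hr,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "interaction_p": self.p_value,
            "bootstrap_proportion": self.bootstrap_proportion,
        }


def _high_indicator(df: pd.DataFrame, marker: str, cutpoint: float) -> np.ndarray:
    return (df[marker].to_numpy(float) > cutpoint).astype(float)


def interaction_cox(
    cohort,
    marker: str,
    cutpoint: float,
    adjust=DEFAULT_ADJUST,
    ties_method: str = "efron",
) -> InteractionResult:
    """Cox model {treatment, 1{marker > cut}, treatment x class} + adjusters.

    Also reports the within-class (unadjusted) treatment hazard ratio and the
    Kaplan-Meier median OS per arm, mirroring the usual subgroup forest-plot
    presentation.
    """
    df = cohort.to_frame() if isinstance(cohort, TrialCohort) else cohort.copy()
    high = _high_indicator(df, marker, cutpoint)
    treat = (df["arm"] == "treatment").to_numpy(float)
    cells = pd.crosstab(treat, high)
    if cells.shape != (2, 2) or (cells.to_numpy() == 0).any():
        raise ValueError(
            f"empty arm x marker-class cell for {marker!r} at cut {cutpoint:g}"
        )
    work = df.copy()
    work["marker_high"] = high
    work["trt_x_high"] = treat * high
    covs = ["treatment", "marker_high", "trt_x_high", *adjust]
    fit = fit_cox(work, covs, ties_method=ties_method)
    tab = fit.hazard_ratios().set_index("covariate")
    row = tab.loc["trt_x_high"]

    sub_rows = []
    for label, mask in (("high", high == 1), ("low", high == 0)):
        sub = work[mask]
        sfit = fit_cox(sub, ["treatment"], ties_method=ties_method)
        srow = sfit.hazard_ratios().iloc[0]
        med = {
            arm: km_curve(sub.loc[sub["arm"] == arm, "time_months"],
                          sub.loc[sub["arm"] == arm, "event"]).median
            for arm in ("control", "treatment")
        }
        sub_rows.append(
            {"class": label, "n": int(mask.sum()),
             "treatment_HR": srow["HR"], "ci_low": srow["ci_low"],
             "ci_high": srow["ci_high"], "p": srow["p"],
             "median_os_control": med["control"],
             "median_os_treatment": med["treatment"]}
        )
    return InteractionResult(
        marker=marker, cutpoint=float(cutpoint),
        interaction_coef=float(row["coef"]), interaction_hr=float(row["HR"]),
        ci_low=float(row["ci_low"]), ci_high=float(row["ci_high"]),
        p_value=float(row["p"]), subgroups=pd.DataFrame(sub_rows),
        adjusted_for=tuple(adjust),
    )


def bootstrap_cutpoint_stability(
    cohort,
    marker: str,
    cutpoint: float,
    n_boot: int = 1000,
    seed: int = 0,
    adjust=DEFAULT_ADJUST,
    alpha: float = 0.05,
    reestimate_cutpoint: bool = False,
    minprop: float = 0.1,
) -> tuple[float, int]:
    """Fraction of bootstrap resamples with a significant interaction.

    Patients are resampled with replacement ``n_boot`` times; each resample is
    dichotomized at the FIXED ``cutpoint`` (or, with ``reestimate_cutpoint``,
    at a freshly selected one - the stricter variant) and the interaction
    model refitted.  Returns ``(significant_fraction, n_skipped)`` where
    skipped replicates had an empty arm-by-class cell or a failed fit.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    df = cohort.to_frame() if isinstance(cohort, TrialCohort) else cohort
    rng = np.random.default_rng(seed)
    n = len(df)
    hits = 0
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        boot = df.iloc[idx].reset_index(drop=True)
        try:
            cut = cutpoint
            if reestimate_cutpoint:
                cut = max_logrank_cutpoint(boot, marker, minprop=minprop).cutpoint
            res = _interaction_p_only(boot, marker, cut, adjust)
        except (ValueError, RuntimeError):
            skipped += 1
            continue
        hits += res < alpha
    n_used = n_boot - skipped
    if n_used == 0:
        raise ValueError("every bootstrap replicate was skipped")
    return hits / n_used, skipped


def _interaction_p_only(df: pd.DataFrame, marker: str, cutpoint: float, adjust) -> float:
    """Interaction Wald p without the subgroup summaries (bootstrap hot path)."""
    high = _high_indicator(df, marker, cutpoint)
    treat = (df["arm"] == "treatment").to_numpy(float)
    if len(np.unique(high)) < 2 or len(np.unique(treat)) < 2:
        raise ValueError("degenerate dichotomization")
    if (pd.crosstab(treat, high).to_numpy() == 0).any():
        raise ValueError("empty arm x class cell")
    work = df.copy()
    work["marker_high"] = high
    work["trt_x_high"] = treat * high
    fit = fit_cox(work, ["treatment", "marker_high", "trt_x_high", *adjust])
    tab = fit.hazard_ratios().set_index("covariate")
    return float(tab.loc["trt_x_high", "p"])


def screen_markers(
    cohort,
    markers=None,
    minprop: float = 0.1,
    adjust=DEFAULT_ADJUST,
    bh: bool = False,
) -> pd.DataFrame:
    """Cut-point search + interaction test for every marker; one row each.

    With ``bh=True`` a Benjamini-Hochberg-adjusted interaction p column is
    added (off by default: the reference analysis reports unadjusted p)."""
    from .cox import bh_adjust

    markers = list(markers) if markers is not None else list(cohort.marker_names)
    rows = []
    for mk in markers:
        cp = max_logrank_cutpoint(cohort, mk, minprop=minprop)
        res = interaction_cox(cohort, mk, cp.cutpoint, adjust=adjust)
        row = res.to_row()
        row["max_logrank_stat"] = cp.max_statistic
        rows.append(row)
    out = pd.DataFrame(rows)
    if bh:
        out["interaction_p_bh"] = bh_adjust(out["interaction_p"].to_numpy())
    return out


def subgroup_charts(
    cohort: TrialCohort,
    marker: str,
    cutpoint: float,
    config: ChartConfig,
    phase1_covariates=DEFAULT_ADJUST,
    min_events: int = 10,
    censoring: CensoringConfig | None = None,
) -> dict[str, ChartSeries]:
    """Risk-adjusted EWMA charts run separately in the high/low marker classes.

    Per class: Phase I refits the Cox model on that class's control arm,
    limits are recalibrated against it, and the class's treatment-arm patients
    are monitored in row order.  Requires at least ``min_events`` control-arm
    events per class.
    """
    df = cohort.to_frame()
    high = _high_indicator(df, marker, cutpoint)
    out: dict[str, ChartSeries] = {}
    for label, mask in (("high", high == 1), ("low", high == 0)):
        sub = cohort.subset(mask)
        ctrl = sub.subset(sub.to_frame()["arm"] == "control")
        n_ev = int(ctrl.event.sum())
        if n_ev < min_events:
            raise ValueError(
                f"subgroup {marker}:{label} has {n_ev} control-arm events "
                f"(< {min_events}); Phase-I fit not attempted"
            )
        fit = fit_cox(ctrl, list(phase1_covariates))
        test = sub.subset(sub.to_frame()["arm"] == "treatment")
        limits = calibrate_limits(fit, ctrl, max(len(test), 1), config,
                                  censoring=censoring)
        out[label] = monitor_sequence(test, fit, limits, config)
    return out
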