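# survchart

Risk-adjusted EWMA monitoring of survival outcomes and predictive-biomarker
discovery for two-arm clinical trials.

## The problem

A randomized trial can show only a modest average benefit for a new
combination therapy while individual patients respond very differently. Two
questions follow. First: *which individual patients* in the test arm did
significantly better (or worse) than an identical patient on the control
therapy would have? Second: *is there a baseline biomarker* whose level
predicts who benefits — a predictive marker, as opposed to a prognostic one
that shifts outcome regardless of treatment?

`survchart` answers both for right-censored survival data, in the setting of
an advanced-pancreatic-cancer trial of gemcitabine with or without an EGFR
inhibitor (two arms of ~246/234 patients, median overall survival around six
months, baseline covariates and a 15-protein plasma biomarker panel). Since
such trial datasets are rarely public, a synthetic-cohort generator with the
same statistical structure makes every stage runnable and testable at desk
scale.

## The method

**Risk-adjusted EWMA chart (RAES chart).** Phase I fits a Cox proportional-
hazards model λ(t|x) = λ₀(t)·exp(βᵀx) to the control arm, with the Breslow
baseline cumulative hazard Λ̂₀. Phase II scores each test-arm patient by the
standardized martingale residual

    U_i = (δ_i − Λ̂_i)/√Λ̂_i,   Λ̂_i = Λ̂₀(t_i)·exp(β̂ᵀx_i)

(observed minus model-expected deaths), smooths the sequence with an EWMA
Z_t = λU_t + (1−λ)Z_{t−1}, and compares it with two-sided, time-varying
control limits calibrated by Monte Carlo so that an in-control case signals
with probability α (default 0.5%). A case below the lower limit had
significantly *better* survival than the control-arm model predicts.

**Predictive biomarkers.** For each marker, the cut-point maximizing the
standardized log-rank statistic between the induced low/high groups is
selected (maximally selected rank statistic); a Cox model with a
treatment × 1{marker > cut} interaction term (adjusted for the prognostic
covariates) tests whether the marker modifies the treatment effect; the
interaction's stability is assessed on bootstrap resamples; and per-subgroup
RAES charts validate the marker by showing where the treatment-sensitive
patients live.

## Worked example

`examples/05_biomarker_cutpoints.py` plants a predictive marker — treatment
hazard ratio 1.341 below the HER2 median, 0.659 above it, the pattern the
motivating study reported — and recovers it:

```
selected HER2 cut-point: 6102 (true threshold 7000; 44% of patients below)
max |standardized log-rank|: 3.91

interaction HR 0.559 (95% CI 0.386-0.812), p = 0.0022

within-class treatment effect:
class   n  treatment_HR  ci_low  ci_high     p  median_os_control  median_os_treatment
 high 271         0.771   0.602    0.988 0.039              6.477                8.121
  low 209         1.321   0.999    1.747 0.051              6.127                5.522

bootstrap stability: interaction significant in 87.6% of 500 resamples (0 skipped)
```

Reading: the search put the cut near the true median; the interaction hazard
ratio 0.559 (p = 0.002) says the treatment effect differs between marker
classes; above the cut the treatment helps (HR 0.77, median OS 8.1 vs 6.5
months), below it the point estimate goes the other way; and the finding
survives 87.6% of bootstrap resamples. The other examples cover cohort
simulation (`01`), the baseline table (`02`), Cox screening with the
proportional-hazards check (`03`), the global chart and its operating
characteristics (`04`), per-subgroup charts (`06`), and the end-to-end
pipeline with a reproducibility manifest (`07`). Each prints what it computes
and one line on what the numbers mean.

## Library layout

| module | contents |
|---|---|
| `survchart.cohort` | `TrialCohort` data model, CSV schema I/O, Fisher/Mann-Whitney baseline table |
| `survchart.cox` | Cox fitter, Breslow baseline, martingale residuals, Schoenfeld PH test, KM, log-rank, BH |
| `survchart.simulate` | `SimConfig`, Weibull-PH cohort generator, in-control sequence generator |
| `survchart.chart` | case scores, EWMA, Monte-Carlo limit calibration, monitoring, OC studies |
| `survchart.cutpoints` | maximal log-rank cut-points, interaction models, bootstrap stability, subgroup charts |
| `survchart.pipeline` | `run_pipeline`: all stages, CSV/JSON artifacts, seed-recording manifest |

The cohort CSV schema is documented in `survchart.cohort`: columns
`id, arm, time_months, event, age, sex, ecog, eod, pi`, then one column per
biomarker (UTF-8, `.` decimals).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the chart's empirical per-case false-alarm rate:
it simulates a default control arm, fits the Phase-I model, calibrates the
EWMA limits to the 0.5% target by Monte Carlo, then monitors 200 fresh
in-control sequences of 234 cases drawn from a disjoint random substream and
reports the observed signal percentage.

See `docs/methods.md` for the model details, the calibration design, the
synthetic world's assumptions, and known limitations.
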