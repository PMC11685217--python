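# Methods

`survchart` implements a two-stage analysis for two-arm survival trials:
risk-adjusted sequential monitoring of individual treatment-arm outcomes
against a control-arm Cox model, and predictive-biomarker discovery via
maximally selected log-rank cut-points with treatment-by-marker interaction
models. A synthetic-cohort generator reproduces the statistical structure the
analysis assumes, so every stage can be exercised with known ground truth.

## The risk-adjusted EWMA chart

**Phase I.** A Cox proportional-hazards model is fitted to the control arm
(reference therapy) by Newton-Raphson maximization of the partial likelihood
(Efron tie handling by default, Breslow selectable; step-halving line search;
convergence at infinity-norm gradient < 1e-8, at most 100 iterations;
covariates are standardized internally and a standardized coefficient
exceeding 10 is reported as a monotone-likelihood/separation error). The
baseline cumulative hazard is the Breslow estimator, increments
d_j / Σ_{i∈R(t_j)} exp(β̂ᵀx_i).

**Phase II.** Each treatment-arm patient i, taken in dataset row order, is
scored by the standardized martingale residual

    U_i = (δ_i − Λ̂_i) / sqrt(max(Λ̂_i, ε)),    Λ̂_i = Λ̂₀(t_i) e^{β̂ᵀx_i},

with ε = 1e-8 a division floor; patients censored before the first reference
event (Λ̂ = 0) score exactly 0. Positive scores mean worse-than-expected
survival. A variance component V_i = (M_i² − Λ̂_i)/sqrt(max(2Λ̂_i², ε)), with
M_i the martingale residual, is available behind
`ChartConfig(statistic="variance")` for monitoring over-dispersion (a nonzero
frailty variance) rather than the mean risk level. Follow-up beyond the
baseline's support is scored at the last baseline value (with a warning),
since the reference model carries no information there.

The score sequence is smoothed with an EWMA, Z_t = λU_t + (1−λ)Z_{t−1},
Z₀ = 0, λ = 0.1 by default (the standard choice for detecting persistent
small shifts; the reference analysis does not state its value).

**Control limits.** Limits are time-varying,

    L_{l,u}(t) = z₀ ∓ L_{l,u} · σ̂_U · sqrt( λ/(2−λ) · (1 − (1−λ)^{2t}) ),

so early cases are not over-flagged while the EWMA variance is still
inflating. The multipliers are calibrated by Monte Carlo: `calibration_reps`
(default 500) in-control sequences are simulated from the Phase-I model
(covariates resampled from the control arm, event times by piecewise-constant
inversion of the Breslow baseline, the configured censoring law applied),
each EWMA path is standardized by the exact time-varying EWMA standard
deviation, and L_l, L_u are set to the α/2 and 1−α/2 quantiles of the pooled
signed standardized values. The per-case false-alarm rate under in-control
data is therefore α (default 0.5%, i.e. one false alarm per 200 cases) by
construction, split equally between the sides.

*Why equal-tailed rather than one symmetric multiplier.* U is strongly
right-skewed: an early death with small expected hazard scores (1−Λ̂)/√Λ̂ ≫ 0,
while the most negative achievable score is −√Λ̂_max. A single symmetric
multiplier calibrated to the total rate places essentially all in-control
exceedances on the high side and makes low-side signals — the chart's
mechanism for finding patients who do *better* than the reference model
predicts — practically unreachable. Equal-tailed calibration restores both
alarms at α/2 each.

*The score's mean is not zero.* Although E[δ − Λ̂] = 0 under the reference
model (and Σ M_i = 0 exactly on the training data, for both tie methods),
the *standardized* score has positive expectation: for an uncensored subject
under the true model, E[(1−V)/√V] with V ~ Exp(1) equals Γ(½) − Γ(3/2) ≈
0.886. The Monte-Carlo calibration absorbs this drift and skew, so the
false-alarm guarantee is unaffected; but the chart is *not* symmetric — the
low- and high-side detection powers for hazard shifts of equal magnitude
differ. Tests therefore check directional monotonicity of the operating
characteristics and the calibrated null split, not mirror symmetry.

*What the calibration conditions on.* The guarantee is conditional on the
fitted Phase-I model. Monitoring a fresh cohort adds Phase-I estimation
error; at subgroup sizes around 120 control patients this inflates the
realized in-control signal rate to roughly 1-2% against the 0.5% nominal
(measured by simulation). With the full 246-patient control arm the
validation rate stays inside [0.3%, 0.7%].

## Biomarker cut-points and interaction models

For each continuous marker, candidate cut-points are the unique observed
values whose low (≤ c) / high (> c) split leaves at least `minprop`
(default 0.1, the convention of the standard cut-point tool) of the patients
and at least one event on each side. The selected cut-point maximizes the
absolute standardized log-rank statistic (O−E)/√V between the induced groups,
computed over all candidates simultaneously; ties break toward the smaller
value. "High" means strictly greater than the cut-point. No
selection-adjusted p-value (Lausen-Schumacher) is attached to the maximal
statistic — the selected cut-point is validated downstream instead — and no
multiplicity adjustment is applied across markers by default (a BH option
exists); both follow the reference analysis and are documented limitations.

The interaction model is a Cox fit with terms {treatment, 1{marker > c},
treatment × class} plus adjustment covariates (default: ECOG performance
status, extent of disease, pain intensity — the reference analysis is
ambiguous on adjustment; an unadjusted option exists). Within-class treatment
hazard ratios (unadjusted) and Kaplan-Meier median OS per arm are reported
alongside, matching the usual forest-plot presentation.

**Bootstrap stability.** Patients are resampled with replacement B times
(B = 1000 by default); each resample is dichotomized at the *fixed* cut-point
and the interaction model refitted; the reported proportion is the fraction
of resamples with interaction p < 0.05. Replicates with an empty
arm-by-class cell are skipped and counted. Re-estimating the cut-point per
replicate (`reestimate_cutpoint=True`) is the stricter variant.

**Subgroup charts.** Each marker class gets its own Phase-I fit (that class's
control arm, minimum 10 events), freshly calibrated limits, and a chart over
its treatment-arm patients. Recalibration per subgroup is the default (the
reference analysis does not say whether its subgroup charts reused global
limits).

## The synthetic cohort

The generator states one world and keeps it:

- Arms: 246 control / 234 treatment.
- Covariates: age ~ Normal(64, 11) clipped to [18, 100]; sex ~ Bern(0.53);
  ECOG = 1 (limited activity) ~ Bern(0.81); extent of disease = 1 (distant
  metastasis) ~ Bern(0.74); pain intensity ~ 100·Beta(0.9, 2.4) (median ≈ 23,
  right-skewed on [0, 100]). These match the published baseline table's
  medians/proportions.
- Biomarkers: 15 independent log-normals; medians are plausible assay-scale
  values (HER2 ≈ 7·10³, BMP2 ≈ 1.1·10⁵, CXCL6 ≈ 4·10⁵ sit near their
  published cut-point magnitudes), log-scale SDs 0.6-1.6. The true marginal
  laws are unpublished; log-normality is an assumption.
- Hazard: Weibull proportional hazards h(t) = λ_w k t^{k−1} e^η with k = 1.2
  and λ_w = 0.0715, tuned once by simulation so the control-arm KM median is
  ≈ 5.91 months under the default covariates, and not revisited. Prognostic
  log-HRs are the published multivariable estimates: ECOG log(0.521), extent
  of disease log(2.054), pain intensity log(1.004) per point. The default
  treatment effect −k·log(6.24/5.91) reproduces the published 6.24 vs 5.91
  month medians.
- Interactions: threshold effects — treatment-arm patients on one side of a
  marker's theoretical quantile receive an extra log-HR. A logistic-ramp
  variant (`smooth_scale`) and a prognostic variant (`arms="both"`) exist for
  robustness studies.
- Censoring: administrative at 36 months plus a 10% fraction with independent
  Uniform(0, 36) drop-out, giving ≈ 97% observed events — survival in this
  disease is short relative to trial follow-up, so near-complete event
  observation is realistic.
- Seeding: one integer seed expands into independent substreams (covariates,
  biomarkers, event times, censoring); biomarker draws are keyed to the
  sorted marker names so serialization round-trips cannot reorder them.

What the generator does **not** emulate: assay measurement error and batch
effects, correlated biomarkers, covariate-dependent censoring, enrollment
drift, or non-proportional hazards. A green test therefore establishes that
the *methods* behave as designed in a well-specified world — not that the
published trial's numbers are reproduced (its dataset is not public; the
published cut-points, case indices and bootstrap percentages are outside what
synthetic data can or should match).

## Numerical choices and degenerate inputs

- Fisher exact test: two-sided rule = sum of hypergeometric probabilities no
  larger than the observed table's (the mainstream-software convention);
  zero margins are errors.
- Mann-Whitney: exact null distribution up to combined n = 50 without ties,
  tie-corrected normal approximation otherwise; a fully tied comparison
  returns p = 1.
- Cox fit: errors on constant covariates (named), exact collinearity, empty
  risk sets, non-convergence and separation.
- Schoenfeld PH test: Grambsch-Therneau chi-square on scaled residuals with
  V(t_j) ≈ I/d; default time transform is `rank` (robust to the heavy right
  tail of survival times; `identity` runs conservative). The approximation
  itself runs conservative for coarse binary covariates at small n — a known
  property shared by the standard implementations.
- Benjamini-Hochberg: step-up, monotone, capped at 1, order preserved.
- EWMA with λ = 1 degenerates to the raw scores; an empty monitored arm gives
  an empty chart series.

## Known limitations

- The exact weighted score statistic of the published chart is not printed in
  its source; the standardized martingale residual is this package's default
  reading (it matches the published description "survival risk based on
  cumulative hazard"), with the variance component as the alternative.
- Monitoring order is dataset row order; true enrollment order, if different,
  changes which case indices signal.
- The cut-point search inherits maximal-selection optimism; interaction
  p-values at the selected cut-point are not adjusted for the search.
- Chart guarantees are conditional on the Phase-I model (see above).
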