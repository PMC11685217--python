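"""Cox machinery: fitter vs. independent oracle, baseline, residuals,
PH diagnostic, Kaplan-Meier, log-rank and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as ll_logrank
from lifelines.statistics import proportional_hazard_test
from scipy import stats

import survchart as sc
from survchart import SimConfig
from survchart.cox import ConvergenceError

from conftest import rng_seeds


def _random_survival_df(rng, n=80, p=2, tie_grid=None, censor=0.25):
    X = rng.normal(size=(n, p))
    beta = rng.uniform(-0.8, 0.8, p)
    t = rng.exponential(1.0 / np.exp(X @ beta))
    if tie_grid:
        t = np.ceil(t * tie_grid) / tie_grid
    e = (rng.random(n) > censor).astype(int)
    if e.sum() == 0:
        e[0] = 1
    cols = {"time_months": t, "event": e}
    cols.update({f"x{j}": X[:, j] for j in range(p)})
    return pd.DataFrame(cols)


class TestFitCox:
    def test_constant_covariate_rejected(self, control_arm):
        df = control_arm.to_frame().copy()
        df["flat"] = 3.0
        with pytest.raises(ValueError, match="flat"):
            sc.fit_cox(df, ["ecog", "flat"])

    def test_collinear_rejected(self, control_arm):
        df = control_arm.to_frame().copy()
        df["pi2"] = 2.0 * df["pi"]
        with pytest.raises(ValueError, match="collinear"):
            sc.fit_cox(df, ["pi", "pi2"])

    def test_agrees_with_lifelines(self):
        # oracle equivalence: 20 random small cohorts, tied and untied,
        # beta agreement to 4 decimals (lifelines fits the Efron likelihood)
        rng = np.random.default_rng(1234)
        for i in range(20):
            df = _random_survival_df(rng, tie_grid=8 if i % 2 else None)
            fit = sc.fit_cox(df, ["x0", "x1"])
            cph = CoxPHFitter().fit(df, "time_months", "event", formula="x0+x1")
            ref = cph.params_[["x0", "x1"]].to_numpy()
            assert np.abs(fit.beta - ref).max() < 1e-4
            assert np.abs(fit.se - cph.standard_errors_[["x0", "x1"]].to_numpy()).max() < 1e-4

    def test_parameter_recovery(self):
        # n=500, true beta=(0.7, -0.65), ~20% censoring
        rng = np.random.default_rng(99)
        n, beta = 500, np.array([0.7, -0.65])
        X = rng.normal(size=(n, 2))
        t = rng.exponential(1.0 / (0.15 * np.exp(X @ beta)))
        c = rng.exponential(np.quantile(t, 0.9) * 2.2, n)
        df = pd.DataFrame({"time_months": np.minimum(t, c), "event": (t <= c).astype(int),
                           "x0": X[:, 0], "x1": X[:, 1]})
        assert 0.7 <= df["event"].mean() <= 0.9
        fit = sc.fit_cox(df, ["x0", "x1"])
        assert np.abs(fit.beta - beta).max() < 0.15

    def test_wald_p_uniform_under_null(self):
        ps = []
        for seed in rng_seeds(2718, 500):
            rng = np.random.default_rng(seed)
            df = _random_survival_df(rng, n=200, p=1, censor=0.2)
            # regenerate times independent of x: null effect
            df["time_months"] = rng.exponential(1.0, 200)
            fit = sc.fit_cox(df, ["x0"])
            z = fit.beta[0] / fit.se[0]
            ps.append(2 * stats.norm.sf(abs(z)))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_monotone_likelihood_detected(self):
        # perfectly separating covariate: diverging coefficient must raise
        df = pd.DataFrame({
            "time_months": [1, 2, 3, 4, 5, 6.0],
            "event": [1, 1, 1, 0, 0, 0],
            "x": [1, 1, 1, 0, 0, 0.0],
        })
        with pytest.raises(ConvergenceError):
            sc.fit_cox(df, ["x"])


class TestBreslow:
    @given(st.integers(0, 10_000))
    def test_equals_nelson_aalen_at_beta_zero(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 40)
        t = rng.exponential(1.0, n)
        if rng.random() < 0.5:
            t = np.ceil(t * 4) / 4  # ties
        e = (rng.random(n) < 0.7).astype(int)
        if e.sum() == 0:
            e[:] = 1
        base = sc.breslow_cumhaz(t, e, 0.0)
        # Nelson-Aalen oracle: sum of d_j / n_j over distinct event times
        order = np.argsort(t)
        ts, es = t[order], e[order]
        cum, na_t, na_v = 0.0, [], []
        for tt in np.unique(ts[es == 1]):
            d = ((ts == tt) & (es == 1)).sum()
            at_risk = (ts >= tt).sum()
            cum += d / at_risk
            na_t.append(tt)
            na_v.append(cum)
        assert np.allclose(base.event_times, na_t)
        assert np.allclose(base.values, na_v)

    def test_single_subject(self):
        base = sc.breslow_cumhaz([4.0], [1], 0.0)
        assert base(4.0) == pytest.approx(1.0)

    def test_hand_risk_set(self):
        # 3 subjects, x=(0,1,0), beta=log2, first event from the x=1 subject:
        # increment = 1 / (1 + 2 + 1) = 0.25
        t = np.array([3.0, 1.0, 2.0])
        e = np.array([0, 1, 0])
        eta = np.log(2.0) * np.array([0.0, 1.0, 0.0])
        base = sc.breslow_cumhaz(t, e, eta)
        assert base.values[0] == pytest.approx(0.25)


class TestMartingaleResiduals:
    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_sum_zero_on_training_data(self, control_arm, ties):
        fit = sc.fit_cox(control_arm, ["ecog", "eod", "pi"], ties_method=ties)
        m = sc.martingale_residuals(fit, control_arm)
        assert abs(m.sum()) < 1e-6
        assert (m <= 1.0 + 1e-12).all()

    def test_censored_before_first_event_is_zero(self, phase1_fit, control_arm):
        df = control_arm.to_frame().iloc[:1].copy()
        df["time_months"] = phase1_fit.baseline.event_times[0] / 2
        df["event"] = 0
        assert sc.martingale_residuals(phase1_fit, df)[0] == 0.0

    def test_event_with_unit_cumhaz_is_zero(self):
        # single-subject fit: Lambda_hat at its own event time is exactly 1
        df = pd.DataFrame({"time_months": [2.0, 3.0], "event": [1, 1], "x": [0.1, -0.1]})
        fit = sc.fit_cox(df, ["x"])
        m = sc.martingale_residuals(fit, df)
        assert abs(m.sum()) < 1e-10


class TestSchoenfeld:
    def test_requires_two_events(self):
        df = pd.DataFrame({"time_months": [1.0, 2.0, 3.0], "event": [1, 0, 0],
                           "x": [0.5, -0.2, 0.1]})
        fit_df = pd.DataFrame({"time_months": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 0, 0],
                               "x": [0.5, -0.2, 0.1, 0.3]})
        fit = sc.fit_cox(fit_df, ["x"])
        with pytest.raises(ValueError):
            sc.schoenfeld_ph_test(fit, df)

    def test_matches_lifelines(self, control_arm):
        fit = sc.fit_cox(control_arm, ["ecog", "eod", "pi"])
        mine = sc.schoenfeld_ph_test(fit, control_arm, transform="rank").set_index("covariate")
        df = control_arm.to_frame()[["time_months", "event", "ecog", "eod", "pi"]]
        cph = CoxPHFitter().fit(df, "time_months", "event")
        ref = proportional_hazard_test(cph, df, time_transform="rank").summary
        ref = ref.reset_index()
        name_col = ref.columns[0]
        for cov in ("ecog", "eod", "pi"):
            ref_p = float(ref.loc[ref[name_col] == cov, "p"].iloc[0])
            assert mine.loc[cov, "p"] == pytest.approx(ref_p, abs=2e-2)

    def test_null_calibration(self):
        # PH-compliant world, continuous covariate: rejection near 5% with the
        # default rank transform (the chi-square approximation is known to run
        # conservative for coarse binary covariates at small n)
        rej = 0
        reps = 400
        for seed in rng_seeds(777, reps):
            rng = np.random.default_rng(seed)
            n = 300
            x = rng.normal(size=n)
            t = rng.exponential(1.0 / np.exp(0.5 * x))
            c = rng.exponential(np.quantile(t, 0.9) * 2, n)
            df = pd.DataFrame({"time_months": np.minimum(t, c),
                               "event": (t <= c).astype(int), "x": x})
            fit = sc.fit_cox(df, ["x"])
            tab = sc.schoenfeld_ph_test(fit, df).set_index("covariate")
            rej += tab.loc["x", "p"] < 0.05
        assert 0.03 <= rej / reps <= 0.07

    def test_power_under_crossing_hazards(self):
        # sign-crossing effect beta(t): early +1, late -1 for x=1
        rej = 0
        reps = 60
        for seed in rng_seeds(31337, reps):
            rng = np.random.default_rng(seed)
            n = 500
            x = rng.integers(0, 2, n).astype(float)
            tau, lam, b = 1.0, 1.0, 1.0
            # piecewise-exponential inversion with hazard exp(+b*x) then exp(-b*x)
            target = rng.exponential(1.0, n)
            h1 = lam * np.exp(b * x)
            h2 = lam * np.exp(-b * x)
            t = np.where(target < h1 * tau, target / h1, tau + (target - h1 * tau) / h2)
            df = pd.DataFrame({"time_months": t, "event": np.ones(n, int), "x": x})
            fit = sc.fit_cox(df, ["x"])
            tab = sc.schoenfeld_ph_test(fit, df).set_index("covariate")
            rej += tab.loc["x", "p"] < 0.05
        assert rej / reps > 0.5


class TestKaplanMeierLogrank:
    def test_no_censoring_matches_ecdf(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(3.0, 101)
        km = sc.km_curve(t, np.ones(101, int))
        # 1 - ECDF evaluated just after each event time
        for tt in np.quantile(t, [0.2, 0.5, 0.8]):
            assert km(tt) == pytest.approx((t > tt).mean(), abs=1e-12)
        assert km.median == pytest.approx(np.sort(t)[50])

    def test_hand_product_limit(self):
        km = sc.km_curve([1, 2, 3, 4, 5], [1, 1, 0, 1, 0])
        assert km(4.0) == pytest.approx(0.3)

    def test_logrank_matches_lifelines(self, default_cohort):
        df = default_cohort.to_frame()
        c, t = df[df["arm"] == "control"], df[df["arm"] == "treatment"]
        z, chi2, p = sc.logrank_test(c["time_months"], c["event"],
                                     t["time_months"], t["event"])
        ref = ll_logrank(c["time_months"], t["time_months"], c["event"], t["event"])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-6)
        assert p == pytest.approx(ref.p_value, rel=1e-6)
        assert chi2 == pytest.approx(z * z)

    def test_logrank_null_calibration(self):
        rej = 0
        for seed in rng_seeds(424242, 1000):
            rng = np.random.default_rng(seed)
            a, b = rng.exponential(1.0, 60), rng.exponential(1.0, 60)
            _, _, p = sc.logrank_test(a, np.ones(60, int), b, np.ones(60, int))
            rej += p < 0.05
        assert 0.035 <= rej / 1000 <= 0.065

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            sc.logrank_test([], [], [1.0], [1])


class TestBHAdjust:
    def test_stepup_hand_example(self):
        out = sc.bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert sc.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_unchanged(self):
        assert np.allclose(sc.bh_adjust([0.3, 0.3, 0.3]), 0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sc.bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_dominates_raw_and_capped(self, ps):
        out = sc.bh_adjust(ps)
        assert ((out >= np.asarray(ps) - 1e-12) & (out <= 1.0 + 1e-12)).all()
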