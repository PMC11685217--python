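"""Cox proportional-hazards machinery and classical survival statistics.

The partial-likelihood fitter (Newton-Raphson with step-halving, Efron or
Breslow ties), the Breslow baseline cumulative hazard, martingale residuals
and the Grambsch-Therneau proportional-hazards test are implemented here
because the monitoring chart is built directly from these quantities
(per-patient cumulative hazard Lambda_hat_i = Lambda0(t_i) * exp(beta' x_i)).
Kaplan-Meier estimation and Benjamini-Hochberg adjustment are delegated to
lifelines and statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import TrialCohort


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to reach the gradient tolerance."""


@dataclass(frozen=True)
class StepHazard:
    """Right-continuous step cumulative hazard: Lambda(t) = values[j] for
    event_times[j] <= t < event_times[j+1], and 0 before the first event."""

    event_times: np.ndarray  # strictly increasing
    values: np.ndarray  # nondecreasing cumulative hazard at each event time

    def __post_init__(self):
        t = np.asarray(self.event_times, float)
        v = np.asarray(self.values, float)
        if t.size != v.size:
            raise ValueError("event_times and values must have equal length")
        if t.size and (np.diff(t) <= 0).any():
            raise ValueError("event_times must be strictly increasing")
        if v.size and ((np.diff(v) < 0).any() or v[0] < 0):
            raise ValueError("cumulative hazard must be nondecreasing from 0")
        object.__setattr__(self, "event_times", t)
        object.__setattr__(self, "values", v)

    def __call__(self, t):
        """Evaluate Lambda(t); times beyond the support take the last value.

        Scalar in, scalar out; array in, array out.
        """
        idx = np.searchsorted(self.event_times, np.asarray(t, float), side="right")
        padded = np.concatenate([[0.0], self.values])
        out = padded[idx]
        return float(out) if np.ndim(t) == 0 else out

    @property
    def max_time(self) -> float:
        return float(self.event_times[-1]) if self.event_times.size else 0.0


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model (Phase-I reference model)."""

    covariate_names: list[str]
    beta: np.ndarray  # log hazard ratios
    covariance: np.ndarray  # inverse observed information
    baseline: StepHazard  # Breslow cumulative baseline hazard
    n: int
    n_events: int
    loglik: float
    ties_method: str  # 'efron' or 'breslow'

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def hazard_ratios(self) -> pd.DataFrame:
        """HR, 95% CI and Wald p per covariate (the screening-table shape)."""
        z = self.beta / self.se
        p = 2.0 * stats.norm.sf(np.abs(z))
        lo = np.exp(self.beta - 1.959963984540054 * self.se)
        hi = np.exp(self.beta + 1.959963984540054 * self.se)
        return pd.DataFrame(
            {"covariate": self.covariate_names, "coef": self.beta,
             "HR": np.exp(self.beta), "ci_low": lo, "ci_high": hi, "p": p}
        )

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != len(self.covariate_names):
            raise ValueError("covariate matrix does not match the fit")
        return X @ self.beta

    def expected_cumhaz(self, time, X) -> np.ndarray:
        """Model-expected cumulative hazard Lambda0(t_i) * exp(beta' x_i)."""
        return self.baseline(time) * np.exp(self.linear_predictor(X))


# ---------------------------------------------------------------------------
# Partial likelihood internals
# ---------------------------------------------------------------------------

def _prepare(time, event, X):
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != time.size:
        X = X.T
    order = np.argsort(time, kind="stable")
    return time[order], event[order], X[order], order


def _loglik_grad_hess(beta, time, event, X, ties):
    """Log partial likelihood, gradient and Hessian on time-sorted data.

    Vectorized over distinct event times; the Efron inner sum runs only for
    genuinely tied event groups (continuous times almost never tie).
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # guard overflow; partial likelihood is shift-invariant
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = np.einsum("i,ij,ik->ijk", w, X, X)
    # suffix sums: S0[i] = sum_{j >= i} w_j over ascending-time order
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    starts = np.flatnonzero(np.concatenate([[True], time[1:] != time[:-1]]))
    d_grp = np.add.reduceat(event, starts)
    ev_grp = np.flatnonzero(d_grp > 0)
    g0 = starts[ev_grp]  # risk-set start index per event group
    d = d_grp[ev_grp].astype(float)

    dead = event == 1
    ll = float(eta[dead].sum())
    grad = X[dead].sum(axis=0)
    # Breslow denominators for every event group (also the d == 1 Efron case)
    s0 = S0[g0]
    zbar = S1[g0] / s0[:, None]
    ll -= float(d @ np.log(s0))
    grad -= d @ zbar
    hess = -np.einsum("g,gjk->jk", d, S2[g0] / s0[:, None, None]) + np.einsum(
        "g,gj,gk->jk", d, zbar, zbar
    )

    tied = ev_grp[d_grp[ev_grp] > 1]
    if ties == "efron" and tied.size:
        # dead-only sums per group, then expand over within-tie rank ell
        we = w * event
        s0d_all = np.add.reduceat(we, starts)
        s1d_all = np.add.reduceat(wx * event[:, None], starts, axis=0)
        s2d_all = np.add.reduceat(wxx * event[:, None, None], starts, axis=0)
        gs = starts[tied]
        dd = d_grp[tied]
        s0r, s1r, s2r = S0[gs], S1[gs], S2[gs]
        # undo the Breslow contribution of the tied groups
        ddf = dd.astype(float)
        zb = s1r / s0r[:, None]
        ll += float(ddf @ np.log(s0r))
        grad += ddf @ zb
        hess += np.einsum("g,gjk->jk", ddf, s2r / s0r[:, None, None]) - np.einsum(
            "g,gj,gk->jk", ddf, zb, zb
        )
        # Efron terms over all (group, ell) pairs
        rep = np.repeat(np.arange(tied.size), dd)
        f = (np.concatenate([np.arange(d) for d in dd]) / np.repeat(dd, dd)).astype(float)
        phi = s0r[rep] - f * s0d_all[tied][rep]
        z = (s1r[rep] - f[:, None] * s1d_all[tied][rep]) / phi[:, None]
        ll -= float(np.log(phi).sum())
        grad -= z.sum(axis=0)
        hess -= np.einsum(
            "m,mjk->jk", 1.0 / phi, s2r[rep] - f[:, None, None] * s2d_all[tied][rep]
        ) - np.einsum("mj,mk->jk", z, z)
    return ll, grad, hess


def fit_cox(
    cohort_or_df,
    covariates: Sequence[str],
    ties_method: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Accepts a :class:`TrialCohort` or a DataFrame with ``time_months`` and
    ``event`` columns.  ``'treatment'`` is accepted as a covariate name and
    maps the arm label to a 0/1 indicator.  Raises on constant covariates and
    on failure to reach an infinity-norm gradient below ``tol``.
    """
    if ties_method not in ("efron", "breslow"):
        raise ValueError("ties_method must be 'efron' or 'breslow'")
    time, event, X, names = _design(cohort_or_df, covariates)
    if event.sum() < 1:
        raise ValueError("at least one event is required")
    const = [nm for nm, col in zip(names, X.T) if np.ptp(col) == 0]
    if const:
        raise ValueError(f"constant covariate(s): {', '.join(const)}")
    # exact collinearity check
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        raise ValueError("covariates are exactly collinear")

    # scale covariates for numerical stability; undo at the end
    loc, scale = X.mean(axis=0), X.std(axis=0)
    Xs = (X - loc) / scale
    ts, es, Xs_sorted, _ = _prepare(time, event, Xs)

    beta = np.zeros(X.shape[1])
    ll, grad, hess = _loglik_grad_hess(beta, ts, es, Xs_sorted, ties_method)
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        # step-halving line search on the log partial likelihood
        for half in range(31):
            cand = beta + step / (2**half)
            ll_new, g_new, h_new = _loglik_grad_hess(cand, ts, es, Xs_sorted, ties_method)
            if ll_new >= ll - 1e-12:
                beta, ll, grad, hess = cand, ll_new, g_new, h_new
                break
        else:
            raise ConvergenceError("step-halving failed to improve the likelihood")
        if np.max(np.abs(beta)) > 50:
            raise ConvergenceError(
                "diverging coefficients (monotone likelihood / complete separation?)"
            )
    else:
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations (|grad|_inf = {np.max(np.abs(grad)):.2e})"
        )
    if np.max(np.abs(beta)) > 10:
        # > 10 on standardized covariates = e^10 hazard ratio per SD: the
        # likelihood is monotone (complete or quasi-complete separation)
        raise ConvergenceError(
            "monotone partial likelihood (separation): standardized coefficient "
            f"reached {np.max(np.abs(beta)):.1f}"
        )

    cov_s = np.linalg.inv(-hess)
    cov_s = (cov_s + cov_s.T) / 2.0
    beta_u = beta / scale
    cov_u = cov_s / np.outer(scale, scale)
    baseline = _breslow_from_sorted(time, event, np.asarray(X, float) @ beta_u)
    return CoxFit(
        covariate_names=list(names), beta=beta_u, covariance=cov_u,
        baseline=baseline, n=time.size, n_events=int(event.sum()),
        loglik=float(ll), ties_method=ties_method,
    )


def _design(cohort_or_df, covariates):
    if isinstance(cohort_or_df, TrialCohort):
        df = cohort_or_df.to_frame()
        X = cohort_or_df.covariate_matrix(covariates)
    else:
        df = cohort_or_df
        cols = []
        for nm in covariates:
            if nm == "treatment" and "arm" in df.columns:
                cols.append((df["arm"] == "treatment").to_numpy(float))
            elif nm in df.columns:
                cols.append(df[nm].to_numpy(float))
            else:
                raise KeyError(f"unknown covariate {nm!r}")
        X = np.column_stack(cols)
    return df["time_months"].to_numpy(float), df["event"].to_numpy(int), X, list(covariates)


def _breslow_from_sorted(time, event, eta) -> StepHazard:
    """Breslow baseline increments d_j / sum_{R(t_j)} exp(eta) on sorted data."""
    order = np.argsort(time, kind="stable")
    t, e, w = time[order], event[order], np.exp(np.asarray(eta, float)[order])
    S0 = np.cumsum(w[::-1])[::-1]
    times, increments = [], []
    i, n = 0, t.size
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())
        if d:
            if S0[i] <= 0:
                raise ValueError("empty risk set at an event time")
            times.append(t[i])
            increments.append(d / S0[i])
        i = j
    return StepHazard(np.asarray(times), np.cumsum(increments))


def breslow_cumhaz(time, event, eta) -> StepHazard:
    """Breslow cumulative baseline hazard for given linear predictors.

    With ``eta = 0`` this is the Nelson-Aalen estimator.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    eta = np.broadcast_to(np.asarray(eta, float), time.shape).copy()
    if event.sum() == 0:
        raise ValueError("no events: baseline hazard undefined")
    return _breslow_from_sorted(time, event, eta)


def martingale_residuals(fit: CoxFit, cohort_or_df, covariates=None) -> np.ndarray:
    """Observed-minus-expected event counts M_i = delta_i - Lambda_hat_i."""
    covariates = covariates or fit.covariate_names
    if list(covariates) != list(fit.covariate_names):
        raise ValueError("covariates do not match the fit")
    time, event, X, _ = _design(cohort_or_df, covariates)
    return event - fit.expected_cumhaz(time, X)


# ---------------------------------------------------------------------------
# Proportional-hazards diagnostic (Grambsch-Therneau)
# ---------------------------------------------------------------------------

def schoenfeld_ph_test(fit: CoxFit, cohort_or_df, transform: str = "rank") -> pd.DataFrame:
    """Scaled-Schoenfeld-residual correlation-with-time test of the PH
    assumption; returns one chi-square/p row per covariate plus a GLOBAL row.

    ``transform`` rescales event times before correlating: ``'rank'``
    (default, robust to the heavy right tail of survival times), ``'identity'``
    or ``'km'`` (1 - Kaplan-Meier left-continuous survival).
    """
    time, event, X, _ = _design(cohort_or_df, fit.covariate_names)
    if event.sum() < 2:
        raise ValueError("at least two events are required")
    ts, es, Xs, _ = _prepare(time, event, X)
    eta = Xs @ fit.beta
    w = np.exp(eta - eta.max())
    wx = w[:, None] * Xs
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]

    resid, g = [], []
    i, n = 0, ts.size
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        for k in range(i, j):
            if es[k] == 1:
                resid.append(Xs[k] - S1[i] / S0[i])
                g.append(ts[i])
        i = j
    resid = np.asarray(resid)
    g = np.asarray(g, float)
    d = resid.shape[0]

    if transform == "rank":
        g = stats.rankdata(g, method="average")
    elif transform == "km":
        km = KaplanMeierFitter().fit(time, event)
        surv = km.survival_function_at_times(g).to_numpy()
        g = 1.0 - surv
    elif transform != "identity":
        raise ValueError("transform must be 'rank', 'km' or 'identity'")

    gc = g - g.mean()
    # Grambsch-Therneau with V(t_j) ~ I/d: per-covariate tests use the SCALED
    # residuals r* = s V (V = inverse information), the global test is
    # d * u' V u / sum(gc^2) with u = sum_j gc_j s_j
    V = fit.covariance
    u = gc @ resid  # p-vector
    denom = float(gc @ gc)
    vu = V @ u
    chi_each = d * vu**2 / (np.diag(V) * denom)
    chi_glob = d * (u @ vu) / denom

    p_names = fit.covariate_names
    rows = [
        {"covariate": nm, "chi2": c, "df": 1, "p": float(stats.chi2.sf(c, 1))}
        for nm, c in zip(p_names, chi_each)
    ]
    rows.append(
        {"covariate": "GLOBAL", "chi2": float(chi_glob), "df": len(p_names),
         "p": float(stats.chi2.sf(chi_glob, len(p_names)))}
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kaplan-Meier, log-rank, BH
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate with at-risk counts and median survival."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float  # NaN when the curve never falls to 0.5

    def __call__(self, t):
        idx = np.searchsorted(self.times, np.asarray(t, float), side="right")
        padded = np.concatenate([[1.0], self.survival])
        out = padded[idx]
        return float(out) if np.ndim(t) == 0 else out


def km_curve(time, event=None) -> KMCurve:
    """Kaplan-Meier estimate (via lifelines) of a single group."""
    if hasattr(time, "to_frame") and event is None:  # a TrialCohort
        event = time.event
        time = time.time
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if time.size == 0:
        raise ValueError("empty group")
    kmf = KaplanMeierFitter().fit(time, event)
    tab = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 else kmf.event_table
    times = tab.index.to_numpy(float)
    surv = kmf.survival_function_at_times(times).to_numpy()
    med = kmf.median_survival_time_
    return KMCurve(times, surv, tab["at_risk"].to_numpy(int), float(med))


def logrank_test(time_a, event_a, time_b, event_b):
    """Two-group log-rank test.

    Returns ``(z, chi2, p)`` where ``z`` is the standardized signed statistic
    (O_b - E_b)/sqrt(V): positive when group *b* has more events than expected,
    i.e. worse survival.  ``chi2 = z**2`` with 1 df.
    """
    ta, ea = np.asarray(time_a, float), np.asarray(event_a, int)
    tb, eb = np.asarray(time_b, float), np.asarray(event_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    time = np.concatenate([ta, tb])
    event = np.concatenate([ea, eb])
    grp = np.concatenate([np.zeros(ta.size, int), np.ones(tb.size, int)])
    o_minus_e, var = _logrank_terms(time, event, grp)
    if var <= 0:
        raise ValueError("log-rank variance is zero (no usable event times)")
    z = o_minus_e / np.sqrt(var)
    chi2 = z * z
    return float(z), float(chi2), float(stats.chi2.sf(chi2, 1))


def _logrank_terms(time, event, grp):
    """Sum over distinct event times of (O_b - E_b) and hypergeometric V."""
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], grp[order]
    n = t.size
    o_minus_e = 0.0
    var = 0.0
    n_at_risk = n
    nb_at_risk = int(g.sum())
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())
        if d and n_at_risk > 1:
            db = int(e[i:j][g[i:j] == 1].sum())
            exp_b = d * nb_at_risk / n_at_risk
            o_minus_e += db - exp_b
            var += (
                d * (nb_at_risk / n_at_risk) * (1 - nb_at_risk / n_at_risk)
                * (n_at_risk - d) / (n_at_risk - 1)
            )
        n_at_risk -= j - i
        nb_at_risk -= int(g[i:j].sum())
        i = j
    return o_minus_e, var


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
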