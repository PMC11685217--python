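"""Patient-level cohort container, CSV I/O and baseline-characteristics comparison.

A cohort is a two-arm (control vs. treatment) table of survival follow-up
(time in months, death indicator), baseline covariates (age, sex, ECOG
performance status, extent of disease, pain intensity) and a panel of
continuous biomarker concentrations.  Row order is meaningful: it is the
order in which treatment-arm patients are monitored by the control chart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ARMS = ("control", "treatment")

#: columns every cohort CSV must carry, in canonical order
CORE_COLUMNS = ["id", "arm", "time_months", "event", "age", "sex", "ecog", "eod", "pi"]

#: binary covariates and their admissible codes
_BINARY = {"event": (0, 1), "sex": (0, 1), "ecog": (0, 1), "eod": (0, 1)}


class SchemaError(ValueError):
    """A required column is missing or mis-named."""


class CohortValidationError(ValueError):
    """A cell violates the cohort domain (e.g. event not in {0,1})."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient: identifiers, follow-up, covariates and biomarker panel."""

    id: str
    arm: str
    time: float  # months of follow-up
    event: int  # 1 = death observed, 0 = censored
    age: float
    sex: int  # 0 female, 1 male
    ecog: int  # 0 fully active, 1 limited activity
    eod: int  # 0 locally advanced, 1 distant metastatic
    pi: float  # pain intensity, 0-100
    biomarkers: Mapping[str, float] = field(default_factory=dict)


class TrialCohort:
    """Ordered collection of patient records with a common biomarker panel.

    Backed by a :class:`pandas.DataFrame` whose row order is preserved and
    treated as the Phase-II monitoring order.
    """

    def __init__(self, frame: pd.DataFrame, marker_names: Sequence[str] | None = None):
        frame = frame.reset_index(drop=True)
        missing = [c for c in CORE_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        if marker_names is None:
            marker_names = [c for c in frame.columns if c not in CORE_COLUMNS]
        self.marker_names = list(marker_names)
        self._frame = frame[CORE_COLUMNS + self.marker_names].copy()
        self._validate()

    def _validate(self) -> None:
        df = self._frame
        if df["id"].astype(str).duplicated().any():
            dup = df.loc[df["id"].astype(str).duplicated(), "id"].iloc[0]
            raise CohortValidationError(f"duplicate patient id {dup!r}")
        bad_arm = ~df["arm"].isin(ARMS)
        if bad_arm.any():
            raise CohortValidationError(
                f"arm must be one of {ARMS}; offending row id "
                f"{df.loc[bad_arm, 'id'].iloc[0]!r}"
            )
        for col, codes in _BINARY.items():
            bad = ~df[col].isin(codes)
            if bad.any():
                raise CohortValidationError(
                    f"{col} must be in {set(codes)}; offending row id "
                    f"{df.loc[bad, 'id'].iloc[0]!r}"
                )
        if (df["time_months"] <= 0).any():
            rid = df.loc[df["time_months"] <= 0, "id"].iloc[0]
            raise CohortValidationError(f"time_months must be > 0; offending row id {rid!r}")
        if ((df["pi"] < 0) | (df["pi"] > 100)).any():
            rid = df.loc[(df["pi"] < 0) | (df["pi"] > 100), "id"].iloc[0]
            raise CohortValidationError(f"pi must lie in [0, 100]; offending row id {rid!r}")
        mk = df[self.marker_names]
        if len(self.marker_names) and not (
            np.isfinite(mk.to_numpy(float)).all() and (mk.to_numpy(float) > 0).all()
        ):
            raise CohortValidationError("biomarker values must be finite and > 0")

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._frame)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    @property
    def records(self) -> list[PatientRecord]:
        out = []
        for row in self._frame.itertuples(index=False):
            d = row._asdict()
            out.append(
                PatientRecord(
                    id=str(d["id"]),
                    arm=d["arm"],
                    time=float(d["time_months"]),
                    event=int(d["event"]),
                    age=float(d["age"]),
                    sex=int(d["sex"]),
                    ecog=int(d["ecog"]),
                    eod=int(d["eod"]),
                    pi=float(d["pi"]),
                    biomarkers={m: float(d[m]) for m in self.marker_names},
                )
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        """Copy of the underlying table (canonical column order)."""
        return self._frame.copy()

    # -- convenience views ---------------------------------------------------
    def arm_frame(self, arm: str) -> pd.DataFrame:
        if arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}")
        return self._frame[self._frame["arm"] == arm].reset_index(drop=True)

    def subset(self, mask) -> "TrialCohort":
        """Row subset (boolean mask over the frame), order preserved."""
        return TrialCohort(self._frame[np.asarray(mask, bool)], self.marker_names)

    @property
    def time(self) -> np.ndarray:
        return self._frame["time_months"].to_numpy(float)

    @property
    def event(self) -> np.ndarray:
        return self._frame["event"].to_numpy(int)

    def covariate_matrix(self, names: Sequence[str]) -> np.ndarray:
        """Design matrix for the named covariates; 'treatment' maps arm to 0/1."""
        cols = []
        for name in names:
            if name == "treatment":
                cols.append((self._frame["arm"] == "treatment").to_numpy(float))
            elif name in self._frame.columns:
                cols.append(self._frame[name].to_numpy(float))
            else:
                raise KeyError(f"unknown covariate {name!r}")
        return np.column_stack(cols) if cols else np.empty((len(self), 0))


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_cohort(
    path,
    schema: Mapping[str, str] | None = None,
    drop_missing_biomarkers: bool = True,
) -> TrialCohort:
    """Read a cohort CSV.

    ``schema`` maps canonical column names to the file's column names when the
    header deviates from the documented schema.  Records with any missing
    biomarker value are dropped (the count is logged); pass
    ``drop_missing_biomarkers=False`` to keep them with NaN markers instead.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    marker_names = [c for c in df.columns if c not in CORE_COLUMNS]
    bad_event = ~df["event"].isin((0, 1))
    if bad_event.any():
        rid = df.loc[bad_event, "id"].iloc[0]
        raise CohortValidationError(f"event must be 0 or 1; offending row id {rid!r}")
    if drop_missing_biomarkers and marker_names:
        complete = df[marker_names].notna().all(axis=1)
        n_drop = int((~complete).sum())
        if n_drop:
            logger.info("read_cohort: dropped %d record(s) with missing biomarkers", n_drop)
        df = df[complete]
    return TrialCohort(df, marker_names)


def write_cohort(cohort: TrialCohort, path) -> None:
    """Write the cohort in the documented CSV schema (UTF-8, '.' decimals)."""
    cohort.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Two-group baseline tests
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Two-sided rule: sum of hypergeometric probabilities of all tables with the
    observed margins that are no more probable than the observed table.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be a 2x2 array of nonnegative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("Fisher exact test undefined: a margin is zero")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def mann_whitney_u(x, y, exact_max_n: int = 50) -> float:
    """Two-sided Mann-Whitney (Wilcoxon rank-sum) p-value.

    Uses the exact null distribution when the combined sample size is at most
    ``exact_max_n`` and there are no ties; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0  # complete tie: no evidence either way
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= exact_max_n and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method)[1])


#: variables baseline_table knows how to summarize
CONTINUOUS_VARS = ("age", "pi", "time_months")
CATEGORICAL_VARS = ("sex", "ecog", "eod", "event")


def baseline_table(cohort: TrialCohort, variables: Sequence[str]) -> pd.DataFrame:
    """Between-arm baseline comparison: median (IQR) + Mann-Whitney p for
    continuous variables, count (proportion) + Fisher exact p for binary ones.

    Returns one row per variable level with columns
    ``variable, level, control, treatment, p_value``.
    """
    df = cohort.to_frame()
    ctrl = df[df["arm"] == "control"]
    trt = df[df["arm"] == "treatment"]
    if len(ctrl) == 0 or len(trt) == 0:
        raise ValueError("baseline comparison requires both arms to be non-empty")

    rows = []
    for var in variables:
        if var in CONTINUOUS_VARS or var in cohort.marker_names:
            p = mann_whitney_u(ctrl[var], trt[var])
            fmt = lambda s: (
                f"{s.median():.3f} ({s.quantile(0.25):.3f}-{s.quantile(0.75):.3f})"
            )
            rows.append(
                {"variable": var, "level": "median (IQR)",
                 "control": fmt(ctrl[var]), "treatment": fmt(trt[var]), "p_value": p}
            )
        elif var in CATEGORICAL_VARS:
            tab = np.array(
                [[(ctrl[var] == 1).sum(), (ctrl[var] == 0).sum()],
                 [(trt[var] == 1).sum(), (trt[var] == 0).sum()]]
            ).T  # rows = level, cols = arm
            p = fisher_exact_2x2(tab.T)
            for lev in (1, 0):
                nc, nt = (ctrl[var] == lev).sum(), (trt[var] == lev).sum()
                rows.append(
                    {"variable": var, "level": str(lev),
                     "control": f"{nc} ({nc / len(ctrl):.1%})",
                     "treatment": f"{nt} ({nt / len(trt):.1%})",
                     "p_value": p if lev == 1 else np.nan}
                )
        else:
            raise ValueError(f"unknown variable {var!r}")
    return pd.DataFrame(rows)
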