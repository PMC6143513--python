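"""Acute-phase running-maximum covariates and time-dependent Cox regression.

The prognostic covariate for a mediator is its running maximum over the
acute-phase sampling days 1, 2 and 4: the day-1 value, then the maximum of
days 1-2, then the maximum of days 1-4, carried forward to the end of the
28-day follow-up. Each subject contributes counting-process risk intervals
(0,2], (2,4], (4, min(T,28)] with the covariate value in force at the
interval's opening update. The Cox partial likelihood is maximised with the
Efron approximation for tied (integer-day) event times; hazard ratios are
reported on the Q1 -> Q3 scale, exp(beta * (Q3 - Q1)), with the quartiles
taken from the final (day-4) running-max distribution across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxTimeVaryingFitter
from lifelines.exceptions import ConvergenceError

from cytonet.errors import FitError, InsufficientData, ValidationError
from cytonet.io import Cohort
from cytonet.scoring import percentile75

ACUTE_UPDATE_DAYS: tuple[int, ...] = (1, 2, 4)
FOLLOWUP_DAYS = 28


def running_max(series: dict[int, float], update_days: tuple[int, ...] = ACUTE_UPDATE_DAYS) -> dict[int, float]:
    """Cumulative maximum of a subject's values at each update day.

    ``series`` maps measurement day to value; days with no measurement are
    skipped (the previous maximum carries forward). A day-1 value is
    required.
    """
    clean = {int(d): float(v) for d, v in series.items() if v is not None and np.isfinite(v)}
    if update_days[0] not in clean:
        raise InsufficientData(f"no day-{update_days[0]} value; subject excluded")
    out: dict[int, float] = {}
    current = -np.inf
    for d in update_days:
        eligible = [v for day, v in clean.items() if day <= d]
        current = max(eligible)
        out[d] = current
    return out


def marker_running_max(
    cohort: Cohort,
    marker: str,
    update_days: tuple[int, ...] = ACUTE_UPDATE_DAYS,
    log_scale: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-subject running-max table for one mediator (log10 scale by default).

    Returns (table indexed by subject with one column per update day,
    excluded subject ids -- those with no day-1 measurement).
    """
    meas = cohort.measurements
    sel = meas[(meas["group"] == "sepsis") & (meas["marker"] == marker)]
    table = {}
    excluded = []
    for sid, grp in sel.groupby("subject_id"):
        series = dict(zip(grp["day"].astype(int), grp["value"].astype(float)))
        try:
            table[sid] = running_max(series, update_days)
        except InsufficientData:
            excluded.append(sid)
    df = pd.DataFrame.from_dict(table, orient="index").sort_index()
    df.columns = [int(c) for c in df.columns]
    if log_scale and not df.empty:
        df = np.log10(df)  # max of log10 = log10 of max
    return df, sorted(excluded)


def score_running_max(
    cohort: Cohort,
    mediators: tuple[str, ...],
    update_days: tuple[int, ...] = ACUTE_UPDATE_DAYS,
) -> tuple[pd.DataFrame, list[str]]:
    """Combined-score covariate built from running-max mediator values.

    For each update day, every mediator's 75th-percentile cut point is
    recomputed on that day's running-max values across subjects, and the
    score is the usual >=-indicator sum. Subjects lacking a day-1 value for
    any mediator in the set are excluded (listwise) and reported.
    """
    per_marker: dict[str, pd.DataFrame] = {}
    excluded: set[str] = set()
    for m in mediators:
        tab, exc = marker_running_max(cohort, m, update_days)
        per_marker[m] = tab
        excluded.update(exc)
    common = sorted(set.intersection(*(set(t.index) for t in per_marker.values())))
    for m, tab in per_marker.items():
        excluded.update(set(tab.index) - set(common))
    scores = pd.DataFrame(0, index=pd.Index(common, name="subject_id"), columns=list(update_days))
    for m in mediators:
        tab = per_marker[m].loc[common]
        for d in update_days:
            cut = percentile75(tab[d])
            scores[d] += (tab[d] >= cut).astype(int)
    return scores, sorted(excluded)


def expand_intervals(
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame,
    update_days: tuple[int, ...] = ACUTE_UPDATE_DAYS,
    followup_days: int = FOLLOWUP_DAYS,
    adjusters: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Counting-process risk intervals with the covariate in force at each start.

    Boundaries follow the update schedule: with updates (1, 2, 4) the
    intervals are (0,2], (2,4], (4, min(T,28)], each carrying the covariate
    of its opening update (day-1 value, day-2 max, day-4 max). The event
    flag sits on the final interval only. Baseline adjusters (e.g. day-1
    SOFA) repeat on every interval.
    """
    cov = covariates.dropna()
    boundaries = list(update_days[1:]) + [followup_days]
    rows = []
    out = outcomes.set_index("subject_id")
    for sid in cov.index:
        if sid not in out.index:
            raise ValidationError(f"no outcome row for subject {sid}")
        t = float(out.loc[sid, "event_day"])
        ev = int(out.loc[sid, "event"])
        if t < 1:
            raise ValidationError(f"subject {sid}: event day {t} before day 1")
        if t > followup_days:
            raise ValidationError(f"subject {sid}: event day {t} beyond follow-up")
        start = 0.0
        for d, b in zip(update_days, boundaries):
            stop = min(float(b), t)
            if stop <= start:
                break
            last = stop >= t
            row = {
                "subject_id": sid,
                "start": start,
                "stop": stop,
                "event": ev if last else 0,
                "value": float(cov.loc[sid, d]),
            }
            if adjusters is not None and sid in adjusters.index:
                for c in adjusters.columns:
                    row[c] = float(adjusters.loc[sid, c])
            rows.append(row)
            start = stop
            if last:
                break
    df = pd.DataFrame(rows)
    if adjusters is not None and not df.empty:
        missing = df[list(adjusters.columns)].isna().any(axis=1)
        if missing.any():
            df = df[~missing]
    return df


@dataclass
class CoxTdFit:
    """Results of one time-dependent Cox fit, HR on the Q1 -> Q3 scale."""

    covariate: str
    beta: float
    se: float
    p: float
    q1: float
    q3: float
    hr_q1q3: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_events: int
    adjusters: tuple[str, ...] = ()
    ties: str = "efron"
    penalized: bool = False
    adjuster_betas: dict[str, float] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "covariate": self.covariate,
                    "adjusters": "+".join(self.adjusters) or "none",
                    "beta": self.beta,
                    "se": self.se,
                    "hr_q1q3": self.hr_q1q3,
                    "ci_low": self.ci_low,
                    "ci_high": self.ci_high,
                    "p": self.p,
                    "n_events": self.n_events,
                    "n_subjects": self.n_subjects,
                    "ties": self.ties,
                    "penalized": self.penalized,
                }
            ]
        )


def fit_td_cox(
    intervals: pd.DataFrame,
    covariate: str = "value",
    adjusters: tuple[str, ...] = (),
    quartiles: tuple[float, float] | None = None,
    name: str | None = None,
) -> CoxTdFit:
    """Time-dependent Cox proportional hazards fit (Efron tie handling).

    ``quartiles`` are the (Q1, Q3) used for the hazard-ratio scaling; by
    default they are taken from the covariate values on each subject's final
    risk interval (the day-4 running-max distribution). On monotone-
    likelihood separation the fit falls back to a small ridge penalty and is
    flagged ``penalized``.
    """
    if intervals.empty:
        raise FitError("empty interval table")
    n_events = int(intervals["event"].sum())
    if n_events == 0:
        raise FitError("zero events: Cox fit impossible")
    if intervals[covariate].nunique() < 2:
        raise FitError(f"covariate {covariate!r} has no variation across the risk set")
    cols = ["subject_id", "start", "stop", "event", covariate, *adjusters]
    data = intervals[cols].copy()

    if quartiles is None:
        final = data.loc[data.groupby("subject_id")["stop"].idxmax(), covariate]
        quartiles = (float(np.quantile(final, 0.25)), float(np.quantile(final, 0.75)))
    q1, q3 = quartiles

    penalized = False
    ctv = CoxTimeVaryingFitter(penalizer=0.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ctv.fit(
                data,
                id_col="subject_id",
                start_col="start",
                stop_col="stop",
                event_col="event",
            )
    except ConvergenceError:
        penalized = True
        ctv = CoxTimeVaryingFitter(penalizer=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ctv.fit(
                data,
                id_col="subject_id",
                start_col="start",
                stop_col="stop",
                event_col="event",
            )

    summ = ctv.summary
    beta = float(summ.loc[covariate, "coef"])
    se = float(summ.loc[covariate, "se(coef)"])
    p = float(summ.loc[covariate, "p"])
    width = q3 - q1
    z = 1.959963984540054
    return CoxTdFit(
        covariate=name or covariate,
        beta=beta,
        se=se,
        p=p,
        q1=q1,
        q3=q3,
        hr_q1q3=float(np.exp(beta * width)),
        ci_low=float(np.exp((beta - z * se) * width)),
        ci_high=float(np.exp((beta + z * se) * width)),
        n_subjects=int(data["subject_id"].nunique()),
        n_events=n_events,
        adjusters=tuple(adjusters),
        penalized=penalized,
        adjuster_betas={a: float(summ.loc[a, "coef"]) for a in adjusters},
    )


def baseline_adjusters(cohort: Cohort, columns: tuple[str, ...] = ("sofa",)) -> pd.DataFrame:
    """Day-1 severity values used as baseline adjustment covariates."""
    sev = cohort.severity
    day1 = sev[sev["day"] == 1].set_index("subject_id")
    return day1[list(columns)].astype(float)


def acute_phase_cox_table(
    cohort: Cohort,
    markers: tuple[str, ...],
    score_sets: dict[str, tuple[str, ...]] | None = None,
    adjust_by: tuple[tuple[str, ...], ...] = ((), ("sofa",)),
    update_days: tuple[int, ...] = ACUTE_UPDATE_DAYS,
    followup_days: int = FOLLOWUP_DAYS,
) -> pd.DataFrame:
    """Tidy survival table: one Cox fit per covariate per adjuster set."""
    adj_frame = baseline_adjusters(
        cohort, tuple(sorted({a for combo in adjust_by for a in combo}))
    ) if any(adjust_by) else None
    rows = []
    covs: list[tuple[str, pd.DataFrame]] = []
    for m in markers:
        tab, _ = marker_running_max(cohort, m, update_days)
        covs.append((m, tab))
    for name, mediators in (score_sets or {}).items():
        tab, _ = score_running_max(cohort, mediators, update_days)
        covs.append((f"score_{name}", tab))
    for label, tab in covs:
        for combo in adjust_by:
            try:
                ivals = expand_intervals(
                    cohort.outcomes,
                    tab,
                    update_days,
                    followup_days,
                    adjusters=adj_frame[list(combo)] if combo else None,
                )
                fit = fit_td_cox(ivals, adjusters=combo, name=label)
            except (FitError, InsufficientData) as exc:
                rows.append(
                    {
                        "covariate": label,
                        "adjuster": "+".join(combo) or "none",
                        "beta": np.nan,
                        "hr_q1q3": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "p": np.nan,
                        "n_events": np.nan,
                        "note": str(exc),
                    }
                )
                continue
            rows.append(
                {
                    "covariate": label,
                    "adjuster": "+".join(combo) or "none",
                    "beta": fit.beta,
                    "hr_q1q3": fit.hr_q1q3,
                    "ci_low": fit.ci_low,
                    "ci_high": fit.ci_high,
                    "p": fit.p,
                    "n_events": fit.n_events,
                    "note": "penalized" if fit.penalized else "",
                }
            )
    return pd.DataFrame(rows)
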