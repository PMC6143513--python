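"""Cohort containers, CSV round-trip, the log10 transform, and per-day matrices.

The on-disk representation is three UTF-8 comma-separated files ('.' decimal,
no thousands separators):

``measurements.csv``
    ``subject_id,group,day,marker,value,unit,below_limit,above_limit`` -- one
    row per analyte per subject per sampling day; ``day`` empty for controls
    (sampled once).
``severity.csv``
    ``subject_id,day,sofa,jaam,isth`` -- integer severity scores evaluated at
    the same times blood samples were taken (sepsis only).
``outcomes.csv``
    ``subject_id,event,event_day`` -- death within the 28-day follow-up
    (event 1) or censoring (event 0) at ``event_day``.

All mediator analyses run on common (base-10) logarithms of the
concentrations; raw-scale values are retained only for the fold-change
computation, which is defined on raw-scale means.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from cytonet.errors import DomainError, ValidationError
from cytonet.markers import MEDIATORS, SEVERITY_SCORES

MEASUREMENT_COLUMNS = [
    "subject_id",
    "group",
    "day",
    "marker",
    "value",
    "unit",
    "below_limit",
    "above_limit",
]
SEVERITY_COLUMNS = ["subject_id", "day", "sofa", "jaam", "isth"]
OUTCOME_COLUMNS = ["subject_id", "event", "event_day"]


@dataclass
class Cohort:
    """Long-format measurements plus severity scores and survival outcomes.

    ``measurements.day`` is a nullable integer: missing for control subjects,
    which are sampled exactly once outside the longitudinal schedule.
    """

    measurements: pd.DataFrame
    severity: pd.DataFrame
    outcomes: pd.DataFrame
    sampling_days: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.sampling_days:
            days = self.measurements["day"].dropna().astype(int).unique()
            self.sampling_days = tuple(sorted(days))

    @property
    def sepsis_ids(self) -> list[str]:
        m = self.measurements
        return sorted(m.loc[m["group"] == "sepsis", "subject_id"].unique())

    @property
    def control_ids(self) -> list[str]:
        m = self.measurements
        return sorted(m.loc[m["group"] == "control", "subject_id"].unique())

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the three cohort CSVs into ``out_dir``; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "measurements": out / "measurements.csv",
            "severity": out / "severity.csv",
            "outcomes": out / "outcomes.csv",
        }
        meas = self.measurements.copy()
        meas["day"] = meas["day"].astype("Int64")
        meas["below_limit"] = meas["below_limit"].astype(int)
        meas["above_limit"] = meas["above_limit"].astype(int)
        meas.to_csv(paths["measurements"], index=False)
        self.severity.to_csv(paths["severity"], index=False)
        self.outcomes.to_csv(paths["outcomes"], index=False)
        return paths


@dataclass
class DayMatrix:
    """Wide per-day analysis view: one row per subject measured that day.

    ``log10`` holds the transformed mediator panel (NaN = not measured, never
    imputed), ``raw`` the concentrations in native units (pg/mL cytokines,
    ng/mL PAI-1), ``severity`` the integer scores joined on (subject, day).
    ``day`` is None for the control matrix.
    """

    day: int | None
    log10: pd.DataFrame
    raw: pd.DataFrame
    severity: pd.DataFrame

    @property
    def subjects(self) -> list[str]:
        return list(self.log10.index)

    @property
    def markers(self) -> list[str]:
        return list(self.log10.columns)


def log10_transform(value):
    """Common logarithm of a positive concentration (scalar or array).

    Raises :class:`DomainError` on any non-positive input; NaN propagates
    (missing stays missing).
    """
    arr = np.asarray(value, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = arr <= 0
    if np.any(bad):
        raise DomainError(f"log10 requires positive concentrations; got {arr[bad][:5].tolist()}")
    result = np.log10(arr)
    return float(result) if np.isscalar(value) or result.ndim == 0 else result


def _require_columns(df: pd.DataFrame, expected: list[str], name: str) -> None:
    if list(df.columns) != expected:
        raise ValidationError(
            f"{name}: expected columns {expected}, found {list(df.columns)}"
        )


def read_cohort(
    measurements_path: str | Path,
    severity_path: str | Path | None = None,
    outcomes_path: str | Path | None = None,
    known_markers: tuple[str, ...] = MEDIATORS,
) -> Cohort:
    """Read and validate the three cohort CSVs written by :meth:`Cohort.write`.

    Every row is validated: headers must match the writer contract, markers
    must be known, values positive, detection flags mutually exclusive, and
    (subject, day, marker) unique.
    """
    meas = pd.read_csv(measurements_path, dtype={"subject_id": str})
    _require_columns(meas, MEASUREMENT_COLUMNS, "measurements")
    meas["day"] = meas["day"].astype("Int64")
    meas["value"] = meas["value"].astype(float)
    meas["below_limit"] = meas["below_limit"].astype(bool)
    meas["above_limit"] = meas["above_limit"].astype(bool)

    unknown = set(meas["marker"]) - set(known_markers)
    if unknown:
        raise ValidationError(f"unknown markers in measurements: {sorted(unknown)}")
    bad_group = set(meas["group"]) - {"sepsis", "control"}
    if bad_group:
        raise ValidationError(f"unknown group labels: {sorted(bad_group)}")
    nonpos = meas["value"] <= 0
    if nonpos.any():
        rows = meas.loc[nonpos, ["subject_id", "day", "marker", "value"]]
        raise ValidationError(f"non-positive concentrations:\n{rows.to_string(index=False)}")
    both = meas["below_limit"] & meas["above_limit"]
    if both.any():
        raise ValidationError("below_limit and above_limit set simultaneously")
    dup = meas.duplicated(subset=["subject_id", "day", "marker"], keep=False)
    if dup.any():
        keys = meas.loc[dup, ["subject_id", "day", "marker"]].drop_duplicates()
        raise ValidationError(
            f"duplicate (subject, day, marker) rows:\n{keys.to_string(index=False)}"
        )
    ctrl_with_day = (meas["group"] == "control") & meas["day"].notna()
    if ctrl_with_day.any():
        raise ValidationError("control rows must not carry a sampling day")
    sepsis_no_day = (meas["group"] == "sepsis") & meas["day"].isna()
    if sepsis_no_day.any():
        raise ValidationError("sepsis rows must carry a sampling day")

    if severity_path is not None:
        sev = pd.read_csv(severity_path, dtype={"subject_id": str})
        _require_columns(sev, SEVERITY_COLUMNS, "severity")
        if sev.duplicated(subset=["subject_id", "day"]).any():
            raise ValidationError("duplicate (subject, day) severity rows")
    else:
        sev = pd.DataFrame(columns=SEVERITY_COLUMNS)

    if outcomes_path is not None:
        out = pd.read_csv(outcomes_path, dtype={"subject_id": str})
        _require_columns(out, OUTCOME_COLUMNS, "outcomes")
        if out.duplicated(subset=["subject_id"]).any():
            raise ValidationError("duplicate subject outcome rows")
    else:
        out = pd.DataFrame(columns=OUTCOME_COLUMNS)

    return Cohort(measurements=meas, severity=sev, outcomes=out)


def _pivot(meas: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    raw = meas.pivot(index="subject_id", columns="marker", values="value")
    raw = raw.reindex(columns=[m for m in MEDIATORS if m in raw.columns])
    log10 = pd.DataFrame(
        np.log10(raw.to_numpy(dtype=float)), index=raw.index, columns=raw.columns
    )
    return log10, raw


def build_day_matrix(cohort: Cohort, day: int) -> DayMatrix:
    """Assemble the wide analysis matrix for one sampling day (sepsis arm).

    One row per septic subject with at least one measurement that day; absent
    analytes stay NaN. Severity scores are joined on (subject, day).
    """
    if day not in cohort.sampling_days:
        raise ValidationError(
            f"day {day} is not in the sampling schedule {cohort.sampling_days}"
        )
    meas = cohort.measurements
    sel = meas[(meas["group"] == "sepsis") & (meas["day"] == day)]
    if sel.empty:
        empty = pd.DataFrame(columns=list(MEDIATORS)).rename_axis("subject_id")
        sev = pd.DataFrame(columns=list(SEVERITY_SCORES)).rename_axis("subject_id")
        return DayMatrix(day=day, log10=empty, raw=empty.copy(), severity=sev)
    log10, raw = _pivot(sel)
    sev = (
        cohort.severity[cohort.severity["day"] == day]
        .set_index("subject_id")[list(SEVERITY_SCORES)]
        .reindex(log10.index)
    )
    return DayMatrix(day=day, log10=log10, raw=raw, severity=sev)


def control_matrix(cohort: Cohort) -> DayMatrix:
    """Wide matrix of the (once-sampled) healthy controls; ``day`` is None."""
    meas = cohort.measurements
    sel = meas[meas["group"] == "control"]
    log10, raw = _pivot(sel)
    sev = pd.DataFrame(
        index=log10.index, columns=list(SEVERITY_SCORES), dtype=float
    )
    return DayMatrix(day=None, log10=log10, raw=raw, severity=sev)
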