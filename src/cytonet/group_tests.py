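"""Per-day many-to-one comparisons against the healthy controls.

Septic patients (or the critical / non-critical strata, split at SOFA >= 12)
are compared with controls on the log10 scale using Dunnett's many-to-one
procedure: a pooled-variance t statistic per comparison with adjusted
p-values from the joint multivariate-t distribution of the max-|t| family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from cytonet.errors import InsufficientData, ValidationError
from cytonet.io import DayMatrix

#: Fixed stream for the quasi-Monte-Carlo evaluation of the multivariate-t
#: CDF inside the Dunnett adjustment, so results are reproducible run to run.
_DUNNETT_QMC_SEED = 20230917

SOFA_CRITICAL_CUTOFF = 12


@dataclass
class CriticalSplit:
    """Partition of the septic subjects measured on one day by SOFA severity."""

    day: int
    critical_ids: tuple[str, ...]
    noncritical_ids: tuple[str, ...]
    excluded_ids: tuple[str, ...]  # subjects with no SOFA score that day
    cutoff: int = SOFA_CRITICAL_CUTOFF


@dataclass
class Comparison:
    group: str
    estimate: float  # mean difference (group - control) on the log10 scale
    p_adjusted: float
    p_unadjusted: float
    n_group: int
    available: bool = True
    reason: str | None = None


@dataclass
class DunnettResult:
    """Many-to-one test family for one marker on one day."""

    day: int | None
    marker: str | None
    comparisons: list[Comparison]
    control_n: int
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "day": self.day,
                    "marker": self.marker,
                    "comparison": c.group,
                    "estimate": c.estimate,
                    "p_adjusted": c.p_adjusted,
                    "p_unadjusted": c.p_unadjusted,
                    "n_control": self.control_n,
                    "n_group": c.n_group,
                }
                for c in self.comparisons
            ]
        )


def split_by_sofa(day_matrix: DayMatrix, cutoff: int = SOFA_CRITICAL_CUTOFF) -> CriticalSplit:
    """Split subjects into critical (SOFA >= cutoff) and non-critical.

    Subjects with no SOFA score that day are excluded and reported in
    ``excluded_ids`` rather than silently dropped.
    """
    if day_matrix.day is None:
        raise ValidationError("SOFA split applies to sepsis day matrices only")
    sofa = day_matrix.severity["sofa"]
    missing = tuple(sorted(sofa.index[sofa.isna()]))
    present = sofa.dropna()
    critical = tuple(sorted(present.index[present >= cutoff]))
    noncritical = tuple(sorted(present.index[present < cutoff]))
    return CriticalSplit(
        day=day_matrix.day,
        critical_ids=critical,
        noncritical_ids=noncritical,
        excluded_ids=missing,
        cutoff=cutoff,
    )


def _pooled_sd(samples: list[np.ndarray]) -> tuple[float, int]:
    dof = sum(len(s) - 1 for s in samples)
    ss = sum(np.sum((s - s.mean()) ** 2) for s in samples)
    return float(np.sqrt(ss / dof)) if dof > 0 else np.nan, dof


def dunnett_many_to_one(
    groups: dict[str, np.ndarray],
    control: np.ndarray,
    day: int | None = None,
    marker: str | None = None,
) -> DunnettResult:
    """Two-sided Dunnett many-to-one comparisons of each group vs control.

    Adjusted p-values come from the joint multivariate-t null of the max-|t|
    statistic (quasi-Monte-Carlo evaluated with a fixed stream); unadjusted
    p-values are ordinary pooled-variance two-sample t tests with the same
    pooled variance across all groups. Groups with fewer than two
    observations are reported unavailable; the rest of the family is still
    computed (the family size counts only the computable comparisons).
    """
    control = np.asarray(control, dtype=float)
    if len(control) < 2:
        raise InsufficientData("control group needs at least 2 observations")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    usable = {g: v for g, v in arrays.items() if len(v) >= 2}
    notes: list[str] = []

    comparisons: list[Comparison] = []
    if usable:
        pooled_sd, dof = _pooled_sd([control, *usable.values()])
        if pooled_sd == 0:
            notes.append("zero pooled variance: all observations identical within groups")
        with warnings.catch_warnings():
            # near-identical samples (e.g. a stratum sitting at a detection
            # limit) trigger a harmless precision-loss warning inside scipy
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.dunnett(
                *usable.values(),
                control=control,
                alternative="two-sided",
                rng=_DUNNETT_QMC_SEED,
            )
        p_adj = np.atleast_1d(res.pvalue)
        for k, (g, sample) in enumerate(usable.items()):
            diff = sample.mean() - control.mean()
            se = pooled_sd * np.sqrt(1.0 / len(sample) + 1.0 / len(control))
            if se > 0:
                t = diff / se
                p_raw = float(2.0 * stats.t.sf(abs(t), dof))
            else:
                p_raw = 1.0 if diff == 0 else 0.0
            # QMC error in the multivariate-t CDF can nudge the adjusted p a
            # hair under the unadjusted one in the single-comparison limit;
            # the exact inequality p_adj >= p_raw is restored here.
            comparisons.append(
                Comparison(
                    group=g,
                    estimate=float(diff),
                    p_adjusted=float(max(p_adj[k], p_raw)),
                    p_unadjusted=p_raw,
                    n_group=len(sample),
                )
            )
    for g, v in arrays.items():
        if g not in usable:
            comparisons.append(
                Comparison(
                    group=g,
                    estimate=np.nan,
                    p_adjusted=np.nan,
                    p_unadjusted=np.nan,
                    n_group=len(v),
                    available=False,
                    reason="fewer than 2 observations",
                )
            )
    return DunnettResult(
        day=day,
        marker=marker,
        comparisons=comparisons,
        control_n=len(control),
        warnings=notes,
    )


def compare_day_to_controls(
    day_matrix: DayMatrix,
    controls: DayMatrix,
    split: CriticalSplit | None = None,
) -> pd.DataFrame:
    """Tidy per-marker Dunnett comparisons for one day.

    Without a split: one family per marker, sepsis vs control. With a split:
    critical and non-critical strata vs control in a single family per
    marker (three-group pooled variance).
    """
    rows = []
    for m in day_matrix.markers:
        ctrl = controls.log10[m].dropna().to_numpy()
        col = day_matrix.log10[m].dropna()
        if split is None:
            groups = {"sepsis": col.to_numpy()}
        else:
            groups = {
                "critical": col.reindex(list(split.critical_ids)).dropna().to_numpy(),
                "noncritical": col.reindex(list(split.noncritical_ids)).dropna().to_numpy(),
            }
        try:
            res = dunnett_many_to_one(groups, ctrl, day=day_matrix.day, marker=m)
        except InsufficientData:
            continue
        rows.append(res.to_frame())
    if not rows:
        return pd.DataFrame(
            columns=[
                "day",
                "marker",
                "comparison",
                "estimate",
                "p_adjusted",
                "p_unadjusted",
                "n_control",
                "n_group",
            ]
        )
    return pd.concat(rows, ignore_index=True)
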