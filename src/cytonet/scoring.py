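"""Combined 75th-percentile quantile scores and Spearman severity associations.

A combined score dichotomizes each mediator in a named set at the cohort
75th percentile of its levels (value >= cut point scores 1, below scores 0)
and sums the indicators, so a 4-mediator set yields an integer in 0..4.
Standard sets: A = (IL-1b, IL-6, IL-8, IL-10, MCP-1, PAI-1),
B = (IL-6, IL-8, IL-10, MCP-1, PAI-1), C = (IL-6, IL-8, IL-10, MCP-1),
D = (IL-6, IL-8, MCP-1).

Associations of markers and scores with the SOFA / JAAM DIC / ISTH DIC
scores are tie-corrected Spearman rank correlations, classified by |rho|:
strong (>0.8), moderate (0.5-0.8), weak (0.3-0.5), very weak (0.1-0.3),
negligible otherwise; band boundaries fall to the lower band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from cytonet.errors import InsufficientData
from cytonet.io import DayMatrix
from cytonet.markers import SCORE_SETS, SEVERITY_SCORES

#: Quantile rule for the cut points: linear interpolation between order
#: statistics (numpy's default), recorded in output metadata because the
#: boundary ">=" indicator rule makes the choice consequential.
QUANTILE_RULE = "linear"


@dataclass
class CombinedScoreDefinition:
    """A named mediator set with frozen per-mediator 75th-percentile cuts."""

    name: str
    mediators: tuple[str, ...]
    cutpoints: dict[str, float]
    day: int | None = None
    n_subjects: int | None = None
    quantile_rule: str = QUANTILE_RULE

    @property
    def max_score(self) -> int:
        return len(self.mediators)


@dataclass
class SeverityAssociation:
    day: int | None
    variable: str
    target: str
    rho: float
    p: float
    n: int
    strength: str
    sign: int


def percentile75(values) -> float:
    """75th percentile under linear interpolation of order statistics.

    Requires at least 4 non-missing values.
    """
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    if len(arr) < 4:
        raise InsufficientData(
            f"75th percentile needs >= 4 values, got {len(arr)}"
        )
    return float(np.quantile(arr, 0.75, method=QUANTILE_RULE))


def make_definition(
    name: str,
    day_matrix: DayMatrix,
    mediators: tuple[str, ...] | None = None,
    scale: str = "log10",
) -> CombinedScoreDefinition:
    """Compute cut points for a score among the subjects measured that day.

    ``scale`` selects which view the cuts are computed on; indicators are
    invariant to any monotone transform, so log10 and raw give identical
    scores -- log10 is used for consistency with the rest of the analysis.
    """
    if mediators is None:
        mediators = SCORE_SETS[name]
    data = getattr(day_matrix, scale)
    cuts = {m: percentile75(data[m]) for m in mediators}
    return CombinedScoreDefinition(
        name=name,
        mediators=tuple(mediators),
        cutpoints=cuts,
        day=day_matrix.day,
        n_subjects=len(data),
    )


def combined_score(values, definition: CombinedScoreDefinition) -> int:
    """Sum of per-mediator indicators 1{value >= cut point}.

    ``values`` maps mediator name to the subject's level on the same scale
    the cut points were computed on. Every mediator in the definition must be
    present and non-missing, otherwise the score is unavailable.
    """
    total = 0
    for m in definition.mediators:
        v = values.get(m) if hasattr(values, "get") else values[m]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise InsufficientData(f"mediator {m} missing; combined score unavailable")
        total += int(v >= definition.cutpoints[m])
    return total


def score_table(
    day_matrix: DayMatrix, definitions: list[CombinedScoreDefinition]
) -> pd.DataFrame:
    """Per-subject combined scores (NaN where a required mediator is missing)."""
    out = pd.DataFrame(index=day_matrix.log10.index)
    for d in definitions:
        col = []
        for _, row in day_matrix.log10.iterrows():
            try:
                col.append(combined_score(row, d))
            except InsufficientData:
                col.append(np.nan)
        out[f"score_{d.name}"] = col
    return out


def strength_class(rho: float) -> str:
    """Band for |rho|: boundaries (0.8, 0.5, 0.3, 0.1) go to the lower band."""
    a = abs(rho)
    if a > 0.8:
        return "strong"
    if a > 0.5:
        return "moderate"
    if a > 0.3:
        return "weak"
    if a > 0.1:
        return "very weak"
    return "negligible"


def spearman_assoc(
    variable,
    severity,
    day: int | None = None,
    variable_name: str = "variable",
    target: str = "severity",
) -> SeverityAssociation:
    """Tie-corrected Spearman correlation with two-sided p and strength band."""
    x = pd.Series(variable).astype(float)
    y = pd.Series(severity).astype(float)
    ok = x.notna() & y.notna()
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise InsufficientData(f"Spearman needs >= 3 paired observations, got {len(x)}")
    if x.nunique() < 2 or y.nunique() < 2:
        raise InsufficientData("constant series: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return SeverityAssociation(
        day=day,
        variable=variable_name,
        target=target,
        rho=float(rho),
        p=float(p),
        n=int(len(x)),
        strength=strength_class(float(rho)),
        sign=int(np.sign(rho)),
    )


def severity_association_table(
    day_matrix: DayMatrix,
    definitions: list[CombinedScoreDefinition] | None = None,
) -> pd.DataFrame:
    """Tidy per-day associations: every marker and score vs every severity score.

    The machine twin of the per-day association grids: columns
    day, variable, target, rho, p, n, strength.
    """
    frames = day_matrix.log10.copy()
    if definitions:
        frames = frames.join(score_table(day_matrix, definitions))
    rows = []
    for var in frames.columns:
        for target in SEVERITY_SCORES:
            try:
                assoc = spearman_assoc(
                    frames[var],
                    day_matrix.severity[target],
                    day=day_matrix.day,
                    variable_name=var,
                    target=target,
                )
            except InsufficientData:
                continue
            rows.append(
                {
                    "day": assoc.day,
                    "variable": assoc.variable,
                    "target": assoc.target,
                    "rho": assoc.rho,
                    "p": assoc.p,
                    "n": assoc.n,
                    "strength": assoc.strength,
                }
            )
    return pd.DataFrame(rows)
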