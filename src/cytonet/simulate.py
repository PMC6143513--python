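"""Synthetic longitudinal sepsis cohorts with a planted cytokine network.

The generator emulates the structure the downstream analysis assumes: a
sepsis arm sampled on days 1, 2, 4, 6, 8, 11 and 15 (at most 7 samples per
patient) and a once-sampled healthy-control arm; 12 mediators that are
log-normally distributed with a planted correlated cluster
{IL-6, IL-8, MCP-1, IL-10, PAI-1}; assay detection-limit censoring; integer
SOFA/JAAM/ISTH severity scores and a 28-day survival outcome, both driven by
a shared latent severity; and attrition by death or ICU discharge.

Latent structure
----------------
One scalar latent severity per patient-day follows a stationary AR(1)
process (coefficient ``ar_coefficient``, standard-normal marginals). For a
cluster mediator the standardised log10 concentration is
``sqrt(rho) * s + sqrt(1 - rho) * noise`` so that (a) any two cluster
members correlate at exactly ``rho`` on the log10 scale and (b) the cluster
co-moves with severity and hence with the hazard. Non-members are
independent noise. Severity scores are clipped rounded affine functions of
the latent severity; the death hazard is exponential, proportional to
``exp(log_hazard_per_severity_unit * s_day1)``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from cytonet.errors import ConfigError, DomainError
from cytonet.io import Cohort
from cytonet.markers import (
    CYTOKINE_DETECTION_HIGH,
    CYTOKINE_DETECTION_LOW,
    MEDIATORS,
    NETWORK_CLUSTER,
    PAI1,
    PAI1_DETECTION_LOW,
    SEVERITY_MAX,
    UNITS,
)

# Per-mediator location parameters on the log10 scale (concentrations in
# native assay units: pg/mL for cytokines, ng/mL for PAI-1). These are stated
# defaults chosen to be clinically plausible -- they are not fitted to any
# cohort. The planted cluster members are strongly elevated in sepsis
# (log2 fold change well above the 1.5 network-inclusion threshold), IL-1b
# moderately so, and the remaining mediators only marginally.
DEFAULT_CONTROL_LOG10_MEANS: dict[str, float] = {
    "IL-1b": 0.5,
    "IL-6": 0.7,
    "IL-8": 1.0,
    "IL-10": 0.6,
    "MCP-1": 1.5,
    "TNF-a": 1.0,
    "IFN-a": 0.6,
    "IFN-g": 0.7,
    "IL-4": 0.5,
    "IL-17A": 0.8,
    "IL-12/IL-23p40": 1.3,
    "PAI-1": 1.0,
}
DEFAULT_SEPSIS_LOG10_MEANS: dict[str, float] = {
    "IL-1b": 1.05,
    "IL-6": 2.3,
    "IL-8": 2.2,
    "IL-10": 1.9,
    "MCP-1": 2.7,
    "TNF-a": 1.2,
    "IFN-a": 0.75,
    "IFN-g": 0.9,
    "IL-4": 0.65,
    "IL-17A": 0.95,
    "IL-12/IL-23p40": 1.5,
    "PAI-1": 1.9,
}
DEFAULT_LOG10_SD: dict[str, float] = {m: 0.45 for m in MEDIATORS}

# Baseline offsets and integer-noise SDs for the severity-score mappings
# (score = clip(round(offset + loading * latent + noise), 0, max)).
_SEVERITY_OFFSET = {"sofa": 9.0, "jaam": 3.0, "isth": 2.0}
_SEVERITY_NOISE_SD = {"sofa": 1.0, "jaam": 0.7, "isth": 0.7}

# Named RNG stream identifiers: each purpose draws from its own child stream
# of the single user seed, so e.g. adding mediators never perturbs the
# survival draws.
_STREAM_LATENT = 1
_STREAM_SEVERITY = 2
_STREAM_SURVIVAL = 3
_STREAM_DISCHARGE = 4
_STREAM_MEDIATOR = 5
_STREAM_CONTROL = 6


def _name_key(name: str) -> int:
    digest = hashlib.sha256(name.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(key)))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the study conditions: 31 septic patients, 13 healthy
    controls, sampling days (1, 2, 4, 6, 8, 11, 15), cytokine detection range
    9.77-3000 pg/mL, PAI-1 lower limit 0.014 ng/mL, 28-day follow-up.
    """

    n_patients: int = 31
    n_controls: int = 13
    sampling_days: tuple[int, ...] = (1, 2, 4, 6, 8, 11, 15)
    mediator_names: tuple[str, ...] = MEDIATORS
    cluster_members: tuple[str, ...] = NETWORK_CLUSTER
    cluster_correlation: float = 0.7
    control_log10_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_LOG10_MEANS)
    )
    sepsis_log10_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEPSIS_LOG10_MEANS)
    )
    log10_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOG10_SD))
    detection_low_pg_ml: float = CYTOKINE_DETECTION_LOW
    detection_high_pg_ml: float = CYTOKINE_DETECTION_HIGH
    pai1_detection_low_ng_ml: float = PAI1_DETECTION_LOW
    ar_coefficient: float = 0.8
    severity_loading: dict[str, float] = field(
        default_factory=lambda: {"sofa": 3.5, "jaam": 1.5, "isth": 1.5}
    )
    baseline_hazard: float = 0.01
    log_hazard_per_severity_unit: float = 0.8
    followup_days: int = 28
    discharge_probability_per_visit: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0 or self.n_controls <= 0:
            raise ConfigError("n_patients and n_controls must be positive")
        days = self.sampling_days
        if not days or days[0] != 1 or any(b <= a for a, b in zip(days, days[1:])):
            raise ConfigError(
                "sampling_days must be strictly increasing and start at day 1"
            )
        missing = set(self.cluster_members) - set(self.mediator_names)
        if missing:
            raise ConfigError(f"cluster_members not in mediator_names: {sorted(missing)}")
        k = len(self.cluster_members)
        rho = self.cluster_correlation
        block = np.full((k, k), rho)
        np.fill_diagonal(block, 1.0)
        if np.linalg.eigvalsh(block).min() <= 0:
            raise ConfigError(
                f"cluster block {self.cluster_members} with correlation {rho} "
                "is not positive definite"
            )
        if not 0 <= rho < 1:
            raise ConfigError("cluster_correlation must lie in [0, 1)")
        if self.detection_low_pg_ml >= self.detection_high_pg_ml:
            raise ConfigError("detection_low must be below detection_high")
        if not 0 <= self.discharge_probability_per_visit <= 1:
            raise ConfigError("discharge_probability_per_visit must lie in [0, 1]")
        for m in self.mediator_names:
            for table, label in (
                (self.control_log10_means, "control_log10_means"),
                (self.sepsis_log10_means, "sepsis_log10_means"),
                (self.log10_sd, "log10_sd"),
            ):
                if m not in table:
                    raise ConfigError(f"{label} missing entry for {m}")


@dataclass
class SyntheticCohort(Cohort):
    """A simulated cohort; adds the hidden per-patient-day latent severity.

    ``latent`` is retained for parameter-recovery tests only and is never
    written by the cohort writer.
    """

    latent: pd.DataFrame = field(default_factory=pd.DataFrame)


def apply_detection_limits(
    raw: float, low: float, high: float | None = None
) -> tuple[float, bool, bool]:
    """Clip a raw concentration to the assay's detectable range.

    Returns ``(stored value, below_limit, above_limit)``: values under ``low``
    are stored at ``low`` and flagged below-limit; values over ``high`` (when
    an upper limit exists) are stored at ``high`` and flagged above-limit.
    """
    if raw < 0:
        raise DomainError(f"negative concentration {raw!r}")
    if high is not None and low >= high:
        raise DomainError(f"detection limits must satisfy low < high; got {low}, {high}")
    if raw < low:
        return low, True, False
    if high is not None and raw > high:
        return high, False, True
    return float(raw), False, False


def _limits_for(config: SimulationConfig, marker: str) -> tuple[float, float | None]:
    if marker == PAI1:
        return config.pai1_detection_low_ng_ml, None
    return config.detection_low_pg_ml, config.detection_high_pg_ml


def _simulate_latent(config: SimulationConfig) -> np.ndarray:
    """Stationary AR(1) latent severity, shape (n_patients, n_days)."""
    rng = _stream(config.seed, _STREAM_LATENT)
    n, t = config.n_patients, len(config.sampling_days)
    phi = config.ar_coefficient
    s = np.empty((n, t))
    s[:, 0] = rng.standard_normal(n)
    innov_sd = np.sqrt(1.0 - phi**2)
    for j in range(1, t):
        s[:, j] = phi * s[:, j - 1] + innov_sd * rng.standard_normal(n)
    return s


def make_cohort(config: SimulationConfig | None = None, **overrides) -> SyntheticCohort:
    """Generate a synthetic cohort; deterministic for a fixed config seed.

    Keyword overrides are applied to the (default) config, e.g.
    ``make_cohort(n_patients=200, seed=3)``.
    """
    if config is None:
        config = SimulationConfig()
    if overrides:
        config = replace(config, **overrides)
    config.validate()

    days = config.sampling_days
    n, t = config.n_patients, len(days)
    latent = _simulate_latent(config)

    # Survival: exponential with patient hazard scaled by day-1 latent severity.
    surv_rng = _stream(config.seed, _STREAM_SURVIVAL)
    hazard = config.baseline_hazard * np.exp(
        config.log_hazard_per_severity_unit * latent[:, 0]
    )
    u = surv_rng.random(n)
    with np.errstate(divide="ignore"):
        death_time = np.where(
            hazard > 0, -np.log1p(-u) / np.where(hazard > 0, hazard, 1.0), np.inf
        )
    event = death_time <= config.followup_days
    event_day = np.where(event, np.maximum(1, np.ceil(death_time)), config.followup_days)

    # Discharge: after each completed visit (from the second on), an
    # independent chance of leaving the ICU; later visits are dropped but the
    # 28-day outcome remains known.
    dis_rng = _stream(config.seed, _STREAM_DISCHARGE)
    p_dis = config.discharge_probability_per_visit
    discharge_after = np.full(n, np.inf)  # day after which no more visits
    if p_dis > 0:
        draws = dis_rng.random((n, t))
        for i in range(n):
            for j in range(1, t):
                if draws[i, j] < p_dis:
                    discharge_after[i] = days[j - 1]
                    break
    else:
        dis_rng.random((n, t))  # keep the stream advanced identically

    # Visit schedule: day 1 always (sampled within 24 h of diagnosis); later
    # sampling days only while the patient is alive and not discharged.
    visit = np.zeros((n, t), dtype=bool)
    visit[:, 0] = True
    for j in range(1, t):
        visit[:, j] = (days[j] < death_time) & (days[j] <= discharge_after)

    subject_ids = [f"P{i + 1:03d}" for i in range(n)]
    control_ids = [f"C{i + 1:03d}" for i in range(config.n_controls)]

    # Mediator draws: one named noise stream per mediator so the panel can be
    # extended without perturbing other draws.
    rho = config.cluster_correlation
    cluster = set(config.cluster_members)
    rows: list[tuple] = []
    for m in config.mediator_names:
        rng_m = _stream(config.seed, _STREAM_MEDIATOR, _name_key(m))
        eps = rng_m.standard_normal((n, t))
        if m in cluster:
            z = np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * eps
        else:
            z = eps
        log10_conc = config.sepsis_log10_means[m] + config.log10_sd[m] * z
        conc = 10.0**log10_conc
        low, high = _limits_for(config, m)
        for i in range(n):
            for j in range(t):
                if not visit[i, j]:
                    continue
                value, below, above = apply_detection_limits(conc[i, j], low, high)
                rows.append(
                    (subject_ids[i], "sepsis", days[j], m, value, UNITS[m], below, above)
                )

    for m in config.mediator_names:
        rng_c = _stream(config.seed, _STREAM_CONTROL, _name_key(m))
        conc = 10.0 ** (
            config.control_log10_means[m]
            + config.log10_sd[m] * rng_c.standard_normal(config.n_controls)
        )
        low, high = _limits_for(config, m)
        for i in range(config.n_controls):
            value, below, above = apply_detection_limits(conc[i], low, high)
            rows.append((control_ids[i], "control", pd.NA, m, value, UNITS[m], below, above))

    measurements = pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "group",
            "day",
            "marker",
            "value",
            "unit",
            "below_limit",
            "above_limit",
        ],
    )
    measurements["day"] = measurements["day"].astype("Int64")
    order = {m: k for k, m in enumerate(config.mediator_names)}
    measurements = measurements.sort_values(
        by=["group", "subject_id", "day", "marker"],
        key=lambda col: col.map(order) if col.name == "marker" else col,
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)

    # Severity scores on visit days: clipped rounded affine maps of latent
    # severity plus integer noise.
    sev_rng = _stream(config.seed, _STREAM_SEVERITY)
    sev_rows = []
    lat_rows = []
    for i in range(n):
        for j in range(t):
            noise = {k: sev_rng.standard_normal() for k in ("sofa", "jaam", "isth")}
            if not visit[i, j]:
                continue
            scores = {}
            for k in ("sofa", "jaam", "isth"):
                raw = (
                    _SEVERITY_OFFSET[k]
                    + config.severity_loading[k] * latent[i, j]
                    + _SEVERITY_NOISE_SD[k] * noise[k]
                )
                scores[k] = int(np.clip(round(raw), 0, SEVERITY_MAX[k]))
            sev_rows.append(
                (subject_ids[i], days[j], scores["sofa"], scores["jaam"], scores["isth"])
            )
            lat_rows.append((subject_ids[i], days[j], latent[i, j]))
    severity = pd.DataFrame(
        sev_rows, columns=["subject_id", "day", "sofa", "jaam", "isth"]
    )
    latent_df = pd.DataFrame(lat_rows, columns=["subject_id", "day", "severity"])

    outcomes = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "event": event.astype(int),
            "event_day": event_day.astype(int),
        }
    )

    return SyntheticCohort(
        measurements=measurements,
        severity=severity,
        outcomes=outcomes,
        sampling_days=days,
        latent=latent_df,
    )
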