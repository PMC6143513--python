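"""Registry of the measured mediators, their assay limits and score sets.

The panel is 11 serum cytokines (cytometric bead array, detectable range
9.77-3000 pg/mL) plus plasma PAI-1 (ELISA, minimum detectable level
0.014 ng/mL, no upper limit).
"""

from __future__ import annotations

# Panel order is fixed; it is the tie-break order for clustering.
CYTOKINES: tuple[str, ...] = (
    "IL-1b",
    "IL-6",
    "IL-8",
    "IL-10",
    "MCP-1",
    "TNF-a",
    "IFN-a",
    "IFN-g",
    "IL-4",
    "IL-17A",
    "IL-12/IL-23p40",
)

PAI1 = "PAI-1"

MEDIATORS: tuple[str, ...] = CYTOKINES + (PAI1,)

#: Mediators that co-elevate as one inflammatory/endothelial-injury axis in
#: the acute phase; the simulator plants this as a correlated block.
NETWORK_CLUSTER: tuple[str, ...] = ("IL-6", "IL-8", "MCP-1", "IL-10", "PAI-1")

CYTOKINE_DETECTION_LOW = 9.77  # pg/mL
CYTOKINE_DETECTION_HIGH = 3000.0  # pg/mL
PAI1_DETECTION_LOW = 0.014  # ng/mL

UNITS: dict[str, str] = {m: "pg/mL" for m in CYTOKINES}
UNITS[PAI1] = "ng/mL"

#: Combined quantile score definitions A-D (mediator sets summed as
#: 75th-percentile indicators).
SCORE_SETS: dict[str, tuple[str, ...]] = {
    "A": ("IL-1b", "IL-6", "IL-8", "IL-10", "MCP-1", "PAI-1"),
    "B": ("IL-6", "IL-8", "IL-10", "MCP-1", "PAI-1"),
    "C": ("IL-6", "IL-8", "IL-10", "MCP-1"),
    "D": ("IL-6", "IL-8", "MCP-1"),
}

SEVERITY_SCORES: tuple[str, ...] = ("sofa", "jaam", "isth")

#: Integer score ceilings: SOFA 0-24, JAAM DIC 0-8, ISTH overt DIC 0-8.
SEVERITY_MAX: dict[str, int] = {"sofa": 24, "jaam": 8, "isth": 8}


def detection_limits(marker: str) -> tuple[float, float | None]:
    """Return (lower, upper) assay limits for a marker; upper may be None."""
    if marker == PAI1:
        return PAI1_DETECTION_LOW, None
    return CYTOKINE_DETECTION_LOW, CYTOKINE_DETECTION_HIGH
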