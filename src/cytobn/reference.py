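"""Published per-analyte concentration moments used to calibrate synthetic panels.

Mean +/- SEM (pg/ml) of 24-plex cytokine measurements in seminal fluid and
serum for rat and mouse. These printed summary statistics parameterise the
synthetic generator; they are inputs, not quantities the package recomputes.

A mean of 0.00 denotes an analyte below the assay detection limit in that
compartment (encoded downstream as an always-undetectable column).
"""
from __future__ import annotations

__all__ = [
    "RAT_SEMINAL_FLUID",
    "RAT_SERUM",
    "MOUSE_SEMINAL_FLUID",
    "MOUSE_SERUM",
    "RAT_ANALYTES",
    "MOUSE_ANALYTES",
    "SHARED_ANALYTES",
    "RAT_ABRIDGE_EXCLUSIONS",
    "MOUSE_ABRIDGE_EXCLUSIONS",
    "moments",
]

# analyte -> (mean pg/ml, SEM pg/ml)
RAT_SEMINAL_FLUID: dict[str, tuple[float, float]] = {
    "IL-1alpha": (3.09, 1.01),
    "IL-1beta": (20.14, 0.84),
    "IL-2": (27.74, 3.29),
    "IL-4": (19.63, 1.04),
    "IL-5": (9.03, 0.82),
    "IL-6": (147.01, 7.73),
    "IL-9": (53.36, 4.35),
    "IL-10": (111.39, 6.68),
    "IL-12 (p70)": (52.98, 3.94),
    "IL-13": (7.70, 1.28),
    "IL-17": (14.99, 0.80),
    "IL-18": (6.17, 0.79),
    "Eotaxin": (34.04, 1.35),
    "G-CSF": (1.47, 0.06),
    "GM-CSF": (39.69, 2.04),
    "IFN-gamma": (2.80, 0.39),
    "KC": (229.24, 24.48),
    "MCP-1": (60.73, 2.16),
    "MIP-1alpha": (0.12, 0.02),
    "RANTES": (285.05, 22.53),
    "TNF-alpha": (2.21, 0.16),
    "Leptin": (41.96, 2.07),
    "IP-10": (4.03, 0.28),
    "VEGF": (0.00, 0.00),
}

RAT_SERUM: dict[str, tuple[float, float]] = {
    "IL-1alpha": (18.92, 6.74),
    "IL-1beta": (6.84, 2.47),
    "IL-2": (234.45, 90.66),
    "IL-4": (20.00, 2.54),
    "IL-5": (0.25, 0.17),
    "IL-6": (0.00, 0.00),
    "IL-9": (387.39, 23.88),
    "IL-10": (0.00, 0.00),
    "IL-12 (p70)": (108.24, 10.18),
    "IL-13": (308.64, 21.63),
    "IL-17": (1.25, 0.64),
    "IL-18": (113.73, 26.31),
    "Eotaxin": (47.50, 3.37),
    "G-CSF": (0.09, 0.09),
    "GM-CSF": (0.00, 0.00),
    "IFN-gamma": (46.91, 5.82),
    "KC": (643.20, 25.04),
    "MCP-1": (380.75, 20.32),
    "MIP-1alpha": (14.97, 1.13),
    "RANTES": (4398.42, 1831.59),
    "TNF-alpha": (11.94, 0.93),
    "Leptin": (9498.56, 791.89),
    "IP-10": (27.31, 2.54),
    "VEGF": (2.04, 1.36),
}

MOUSE_SEMINAL_FLUID: dict[str, tuple[float, float]] = {
    "IL-1alpha": (8.19, 1.96),
    "IL-1beta": (87.48, 9.04),
    "IL-2": (3.03, 0.49),
    "IL-3": (0.35, 0.04),
    "IL-4": (0.11, 0.01),
    "IL-5": (0.56, 0.07),
    "IL-6": (3.63, 0.44),
    "IL-9": (135.14, 33.47),
    "IL-10": (19.95, 3.36),
    "IL-12 (p40)": (5.25, 0.53),
    "IL-12 (p70)": (10.91, 1.08),
    "IL-13": (20.64, 1.86),
    "IL-17": (5.10, 0.90),
    "Eotaxin": (857.22, 73.85),
    "G-CSF": (45.03, 3.33),
    "GM-CSF": (4.16, 0.39),
    "IFN-gamma": (46.38, 3.95),
    "KC": (37.17, 3.56),
    "MCP-1": (30.23, 2.65),
    "MIP-1alpha": (114.32, 8.31),
    "MIP-1beta": (6.68, 1.36),
    "RANTES": (618.62, 84.17),
    "TNF-alpha": (102.27, 9.11),
}

MOUSE_SERUM: dict[str, tuple[float, float]] = {
    "IL-1alpha": (62.24, 0.76),
    "IL-1beta": (113.76, 4.25),
    "IL-2": (9.41, 1.47),
    "IL-3": (0.00, 0.00),
    "IL-4": (0.10, 0.03),
    "IL-5": (4.82, 0.62),
    "IL-6": (10.15, 2.76),
    "IL-9": (285.95, 27.44),
    "IL-10": (16.03, 4.02),
    "IL-12 (p40)": (309.65, 30.19),
    "IL-12 (p70)": (76.91, 10.84),
    "IL-13": (171.69, 16.50),
    "IL-17": (161.31, 26.88),
    "Eotaxin": (401.33, 38.07),
    "G-CSF": (30.32, 3.25),
    "GM-CSF": (30.79, 2.39),
    "IFN-gamma": (388.72, 29.30),
    "KC": (26.70, 1.27),
    "MCP-1": (305.54, 25.43),
    "MIP-1alpha": (108.21, 11.94),
    "MIP-1beta": (14.44, 3.23),
    "RANTES": (0.58, 0.58),
    "TNF-alpha": (224.84, 27.02),
}

RAT_ANALYTES: tuple[str, ...] = tuple(RAT_SEMINAL_FLUID)
MOUSE_ANALYTES: tuple[str, ...] = tuple(MOUSE_SEMINAL_FLUID)
SHARED_ANALYTES: tuple[str, ...] = tuple(
    a for a in RAT_ANALYTES if a in MOUSE_SEMINAL_FLUID
)

# Cross-species comparison presets: analytes NOT measured in the other species
# are dropped before relearning, so both abridged networks share a node set.
RAT_ABRIDGE_EXCLUSIONS: tuple[str, ...] = ("IL-18", "IP-10", "Leptin", "VEGF")
MOUSE_ABRIDGE_EXCLUSIONS: tuple[str, ...] = ("IL-3", "IL-12 (p40)", "MIP-1beta")

_TABLES = {
    ("rat", "seminal_fluid"): RAT_SEMINAL_FLUID,
    ("rat", "serum"): RAT_SERUM,
    ("mouse", "seminal_fluid"): MOUSE_SEMINAL_FLUID,
    ("mouse", "serum"): MOUSE_SERUM,
}


def moments(species: str, compartment: str) -> dict[str, tuple[float, float]]:
    """Return the (mean, SEM) table for a species/compartment pair."""
    try:
        return dict(_TABLES[(species, compartment)])
    except KeyError:
        raise ValueError(
            f"unknown panel {species!r}/{compartment!r}; "
            "species in {rat, mouse}, compartment in {seminal_fluid, serum}"
        ) from None
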