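"""Shared fixtures: default parameters, toxicity constants, and concentration
summaries rebuilt from the study's printed per-metal statistics."""

import pytest

from hmrisk.datamodel import (
    ConcentrationSummary,
    ExposureParameters,
    MetalSummary,
)
from hmrisk.io import exposure_from_config, load_default_config, toxicity_from_config

# Printed site-well water summary (mg/L): metal -> (min, max, mean, sd)
WATER_SITE_STATS = {
    "Mg": (0.71, 1.50, 1.09, 0.35),
    "Mn": (0.06, 0.08, 0.07, 0.01),
    "Fe": (1.30, 2.50, 1.75, 0.46),
    "Zn": (1.50, 3.00, 2.15, 0.63),
    "Cd": (0.18, 0.25, 0.22, 0.03),
    "As": (0.58, 2.22, 1.66, 0.67),
    "Cr": (1.40, 2.70, 2.05, 0.54),
    "Pb": (1.20, 2.00, 1.67, 0.30),
    "Cu": (1.10, 2.18, 1.38, 0.46),
}

# Printed site topsoil summary (mg/kg): metal -> (min, max, mean, sd)
SOIL_SITE_STATS = {
    "Mg": (42.0, 64.0, 53.70, 8.97),
    "Mn": (58.0, 72.0, 66.70, 5.10),
    "Ag": (2.0, 5.0, 3.50, 1.60),
    "Zn": (105.0, 210.0, 154.70, 35.00),
    "Cd": (8.20, 12.0, 10.05, 1.17),
    "Pb": (25.0, 37.0, 28.79, 3.05),
    "Cu": (18.0, 28.0, 22.60, 3.29),
    "Fe": (340.0, 410.0, 378.00, 22.28),
    "As": (35.0, 50.0, 42.48, 3.84),
    "Cr": (90.0, 122.0, 108.00, 8.30),
}

# Printed control topsoil means (mg/kg)
SOIL_CONTROL_MEANS = {
    "Mg": 4.30, "Mn": 3.60, "Ag": 0.80, "Zn": 8.10, "Cd": 3.80,
    "Pb": 1.94, "Cu": 1.14, "Fe": 22.46, "As": 3.34, "Cr": 5.80,
}


def summary_from_stats(stats: dict, medium: str, group: str, n: int) -> ConcentrationSummary:
    per = {}
    for metal, (mn, mx, mean, sd) in stats.items():
        cv = 100.0 * sd / mean if mean else None
        per[metal] = MetalSummary(metal, n, 0, mn, mx, mean, sd, cv)
    return ConcentrationSummary(medium, group, per)


@pytest.fixture(scope="session")
def default_config():
    return load_default_config()


@pytest.fixture(scope="session")
def params(default_config) -> ExposureParameters:
    return exposure_from_config(default_config)


@pytest.fixture(scope="session")
def toxicity(default_config):
    return toxicity_from_config(default_config)


@pytest.fixture(scope="session")
def water_site_summary() -> ConcentrationSummary:
    return summary_from_stats(WATER_SITE_STATS, "water", "site", n=5)


@pytest.fixture(scope="session")
def soil_site_summary() -> ConcentrationSummary:
    return summary_from_stats(SOIL_SITE_STATS, "soil", "site", n=26)
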