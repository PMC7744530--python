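"""Non-carcinogenic (THQ/HI) and carcinogenic (ILCR) risk characterisation.

THQ = ADI/RfD per pathway; HI sums the hazard quotients that could be
assessed. ILCR = ADI * SF for the known human carcinogens (Pb, Cr, Cd, As);
the reported ILCR is the ingestion-pathway value by default, since ingestion
dominates the dose. ILCR magnitudes are banded into the seven Delphi levels
and flagged against the 1e-6..1e-4 acceptable range.

Missing toxicity constants always yield an explicit not-assessed state (None),
never a silent zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .datamodel import (
    ConcentrationSummary,
    ExposureParameters,
    ToxicityTable,
    ValidationError,
)
from .exposure import PATHWAYS_SOIL, PATHWAYS_WATER, adi_all_pathways

#: Default set of metals assessed for carcinogenic risk.
CARCINOGENS = ("Pb", "Cr", "Cd", "As")

#: Delphi classification: (upper edge, level, acceptability phrase); bands are
#: half-open [lower, upper).
DELPHI_LEVELS = (
    (1e-6, "Level I", "completely acceptable (extremely low risk)"),
    (1e-5, "Level II", "not eager to care about the probable risk (low risk)"),
    (5e-5, "Level III", "not to be mindful about the risk (low-medium risk)"),
    (1e-4, "Level IV", "worry about the probable risk (medium risk)"),
    (5e-4, "Level V", "care about the risk and willing to invest (medium-high risk)"),
    (1e-3, "Level VI", "pay attention and take action to solve it (high risk)"),
    (math.inf, "Level VII", "must solve it (extremely high risk)"),
)


def thq(adi: float, rfd: float) -> float:
    """Target hazard quotient, ADI/RfD (dimensionless)."""
    if rfd <= 0:
        raise ValidationError(f"RfD must be positive (got {rfd})")
    if adi < 0:
        raise ValidationError(f"ADI must be non-negative (got {adi})")
    return adi / rfd


def hazard_index(thqs: Iterable[float | None]) -> float:
    """Hazard index: arithmetic sum of the hazard quotients.

    ``None`` entries (not-assessed pathways) are excluded from the sum; an
    input with no assessable values at all is an error."""
    vals = [t for t in thqs if t is not None]
    if not vals:
        raise ValidationError("hazard_index needs at least one assessed THQ")
    return math.fsum(vals)  # exact, order-independent summation


def ilcr(adi: float, sf: float) -> float:
    """Incremental lifetime cancer risk, ADI * SF (probability)."""
    if sf <= 0:
        raise ValidationError(f"slope factor must be positive (got {sf})")
    if adi < 0:
        raise ValidationError(f"ADI must be non-negative (got {adi})")
    return adi * sf


def classify_delphi(ilcr_value: float) -> tuple[str, str]:
    """Delphi level and acceptability phrase for a cancer-risk value."""
    if ilcr_value < 0 or not math.isfinite(ilcr_value):
        raise ValidationError(f"ILCR must be finite and non-negative (got {ilcr_value})")
    for upper, level, phrase in DELPHI_LEVELS:
        if ilcr_value < upper:
            return level, phrase
    raise AssertionError("unreachable: Delphi bands end at +inf")


def acceptable_range_flag(ilcr_value: float) -> str:
    """Position of a cancer risk relative to the 1e-6..1e-4 acceptable range:
    below_range (< 1e-6), within_range ([1e-6, 1e-4]), above_range (> 1e-4)."""
    if ilcr_value < 0:
        raise ValidationError(f"ILCR must be non-negative (got {ilcr_value})")
    if ilcr_value < 1e-6:
        return "below_range"
    if ilcr_value <= 1e-4:
        return "within_range"
    return "above_range"


@dataclass
class RiskResult:
    """Per-metal risk characterisation for one medium.

    ``None`` in any field means the quantity could not be assessed (missing
    RfD/SF/KP), as distinct from a computed zero."""

    metal: str
    medium: str
    adi_by_pathway: dict[str, float | None] = field(default_factory=dict)
    thq_by_pathway: dict[str, float | None] = field(default_factory=dict)
    hi: float | None = None
    ilcr_by_pathway: dict[str, float | None] = field(default_factory=dict)
    ilcr: float | None = None
    delphi_level: str | None = None
    acceptability: str | None = None
    range_flag: str | None = None
    hi_flag: str | None = None  # safe (<1) | concern (>=1)


def assess_medium(
    conc_summary: ConcentrationSummary,
    toxicity: ToxicityTable,
    exposure_params: ExposureParameters,
    medium: str,
    carcinogens: Iterable[str] = CARCINOGENS,
    ilcr_mode: str = "ingestion",
    concentrations: Mapping[str, float] | None = None,
) -> list[RiskResult]:
    """Full deterministic risk characterisation for one medium.

    Uses each metal's mean concentration from ``conc_summary`` (override per
    metal via ``concentrations``). Soil pathways: ingestion, inhalation,
    dermal; water: ingestion, dermal (KP-dependent). ILCR is computed per
    pathway for the carcinogen set where slope factors exist; the reported
    ILCR is the ingestion-pathway value (``ilcr_mode="ingestion"``) or the sum
    over assessed pathways (``"sum"``).
    """
    if ilcr_mode not in ("ingestion", "sum"):
        raise ValidationError(f"ilcr_mode must be 'ingestion' or 'sum', got {ilcr_mode!r}")
    carcinogens = set(carcinogens)
    pathways = PATHWAYS_SOIL if medium == "soil" else PATHWAYS_WATER
    results: list[RiskResult] = []
    for metal, ms in conc_summary.per_metal.items():
        conc = (concentrations or {}).get(metal, ms.mean)
        res = RiskResult(metal=metal, medium=medium)
        if conc is None:  # all non-detect: nothing to assess
            res.adi_by_pathway = {pw: None for pw in pathways}
            res.thq_by_pathway = {pw: None for pw in pathways}
            results.append(res)
            continue
        tox = toxicity.get(metal)
        adis = {a.pathway: a.adi for a in adi_all_pathways(metal, conc, medium, exposure_params, kp=tox.kp)}
        res.adi_by_pathway = adis
        for pw in pathways:
            adi, rfd = adis.get(pw), tox.rfd(pw)
            res.thq_by_pathway[pw] = thq(adi, rfd) if (adi is not None and rfd is not None) else None
        assessed = [t for t in res.thq_by_pathway.values() if t is not None]
        if assessed:
            res.hi = hazard_index(assessed)
            res.hi_flag = "concern" if res.hi >= 1.0 else "safe"
        if metal in carcinogens:
            for pw in pathways:
                adi, sf = adis.get(pw), tox.sf(pw)
                res.ilcr_by_pathway[pw] = ilcr(adi, sf) if (adi is not None and sf is not None) else None
            if ilcr_mode == "ingestion":
                res.ilcr = res.ilcr_by_pathway.get("ingestion")
            else:
                vals = [v for v in res.ilcr_by_pathway.values() if v is not None]
                res.ilcr = float(sum(vals)) if vals else None
            if res.ilcr is not None:
                res.delphi_level, res.acceptability = classify_delphi(res.ilcr)
                res.range_flag = acceptable_range_flag(res.ilcr)
        results.append(res)
    return results


def risk_frame(results: list[RiskResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"metal": r.metal, "medium": r.medium}
        for pw, v in r.thq_by_pathway.items():
            row[f"thq_{pw}"] = v
        row.update(
            hi=r.hi,
            hi_flag=r.hi_flag,
            ilcr=r.ilcr,
            delphi_level=r.delphi_level,
            acceptability=r.acceptability,
            range_flag=r.range_flag,
        )
        rows.append(row)
    return pd.DataFrame(rows)
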