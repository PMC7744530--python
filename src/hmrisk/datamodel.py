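"""Core domain types for heavy-metal concentration data and exposure/toxicity parameters.

Concentrations are long-format records, one row per (sample, metal). Soil values
are mg/kg (= ppm for solids); water values are mg/L (= ppm for dilute aqueous
solutions). Non-detects are carried as records with ``detected=False`` and are
excluded, never imputed, downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping

import numpy as np

#: The ten metals analysed in the study system (automobile recycling soils/well water).
STUDY_METALS: tuple[str, ...] = ("Mg", "Mn", "Ag", "Zn", "Cd", "Pb", "Cu", "Fe", "As", "Cr")

_METAL_NAMES = {
    "magnesium": "Mg",
    "manganese": "Mn",
    "silver": "Ag",
    "zinc": "Zn",
    "cadmium": "Cd",
    "lead": "Pb",
    "copper": "Cu",
    "iron": "Fe",
    "arsenic": "As",
    "chromium": "Cr",
}
_SYMBOL_LOOKUP = {s.lower(): s for s in STUDY_METALS}

#: Tokens in a value cell that mark a measurement below the detection limit.
ND_TOKENS = frozenset({"nd", "na", ""})

MEDIA = ("soil", "water")
GROUPS = ("site", "control")


class ValidationError(ValueError):
    """Raised when input data violates a structural or physical constraint."""


def canonical_metal(name: str) -> str:
    """Map a metal name or symbol (any case) to its element symbol.

    Only the ten study metals are accepted; anything else raises
    :class:`ValidationError`.
    """
    key = name.strip().lower()
    if key in _SYMBOL_LOOKUP:
        return _SYMBOL_LOOKUP[key]
    if key in _METAL_NAMES:
        return _METAL_NAMES[key]
    raise ValidationError(f"unknown metal {name!r}; expected one of {', '.join(STUDY_METALS)}")


@dataclass(frozen=True)
class ConcentrationRecord:
    sample_id: str
    metal: str
    value: float
    detected: bool = True


@dataclass
class ConcentrationTable:
    """Per-sample metal concentrations for one medium and one sampling group.

    Invariants enforced on construction: detected values are finite and
    non-negative; (sample_id, metal) pairs are unique; medium/group are fixed
    for the whole table.
    """

    medium: str
    group: str
    records: list[ConcentrationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.medium not in MEDIA:
            raise ValidationError(f"medium must be one of {MEDIA}, got {self.medium!r}")
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.sample_id, rec.metal)
            if key in seen:
                raise ValidationError(f"duplicate record for sample {rec.sample_id!r}, metal {rec.metal}")
            seen.add(key)
            if rec.detected:
                if not math.isfinite(rec.value):
                    raise ValidationError(f"non-finite value for sample {rec.sample_id!r}, metal {rec.metal}")
                if rec.value < 0:
                    raise ValidationError(
                        f"negative concentration {rec.value} for sample {rec.sample_id!r}, metal {rec.metal}"
                    )

    @property
    def units(self) -> str:
        return "mg/kg" if self.medium == "soil" else "mg/L"

    @property
    def metals(self) -> tuple[str, ...]:
        ordered = [m for m in STUDY_METALS if any(r.metal == m for r in self.records)]
        extra = sorted({r.metal for r in self.records} - set(ordered))
        return tuple(ordered + extra)

    def detected_values(self, metal: str) -> np.ndarray:
        """All detected concentrations for one metal, in record order."""
        return np.array([r.value for r in self.records if r.metal == metal and r.detected], dtype=float)

    def nondetect_count(self, metal: str) -> int:
        return sum(1 for r in self.records if r.metal == metal and not r.detected)


@dataclass(frozen=True)
class MetalSummary:
    """Summary statistics for one metal within one table (non-detects excluded)."""

    metal: str
    n: int
    n_nondetect: int
    minimum: float | None
    maximum: float | None
    mean: float | None
    sd: float | None
    cv_percent: float | None

    @property
    def not_detectable(self) -> bool:
        return self.n == 0


@dataclass
class ConcentrationSummary:
    medium: str
    group: str
    per_metal: dict[str, MetalSummary]

    def __getitem__(self, metal: str) -> MetalSummary:
        return self.per_metal[metal]


def summarize(table: ConcentrationTable) -> ConcentrationSummary:
    """Per-metal n/min/max/mean/sd/CV over detected records.

    The SD uses the sample (n-1) denominator; CV is 100*sd/mean. A metal whose
    records are all non-detect gets a summary flagged ``not_detectable`` with
    no numbers fabricated; sd/cv are None when n < 2 or the mean is zero.
    """
    if not table.records:
        raise ValidationError("cannot summarize an empty concentration table")
    out: dict[str, MetalSummary] = {}
    for metal in table.metals:
        vals = table.detected_values(metal)
        n_nd = table.nondetect_count(metal)
        if vals.size == 0:
            out[metal] = MetalSummary(metal, 0, n_nd, None, None, None, None, None)
            continue
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else None
        cv = 100.0 * sd / mean if (sd is not None and mean != 0.0) else None
        out[metal] = MetalSummary(
            metal, int(vals.size), n_nd, float(np.min(vals)), float(np.max(vals)), mean, sd, cv
        )
    return ConcentrationSummary(table.medium, table.group, out)


@dataclass
class ExposureParameters:
    """Receptor and scenario parameters for the dose equations (adult receptor).

    Units: ingr_soil mg/day; ingr_water L/day; inhr m3/day; ef day/year;
    ed year; bw kg; at day (defaults to ed*365); pef m3/kg; sa cm2;
    af mg/(cm2*day); abs dimensionless; et h/event.
    """

    ingr_soil: float = 100.0
    ingr_water: float = 2.0
    inhr: float = 20.0
    ef: float = 365.0
    ed: float = 55.0
    bw: float = 70.0
    at: float | None = None
    pef: float = 1.36e9
    sa: float = 5700.0
    af: float = 0.07
    abs: float = 0.001
    et: float = 0.58

    def __post_init__(self) -> None:
        if self.at is None:
            self.at = self.ed * 365.0
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValidationError(f"exposure parameter {f.name} must be strictly positive, got {v!r}")

    def with_overrides(self, **kwargs: float) -> "ExposureParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class MetalToxicity:
    """Toxicity/permeability constants for one metal; absent entries mean the
    corresponding computation is skipped (never defaulted to zero)."""

    metal: str
    rfd_ing: float | None = None  # mg/kg/day
    rfd_inh: float | None = None
    rfd_derm: float | None = None
    sf_ing: float | None = None  # (mg/kg/day)^-1
    sf_inh: float | None = None
    sf_derm: float | None = None
    kp: float | None = None  # cm/h
    guidelines: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("rfd_ing", "rfd_inh", "rfd_derm", "sf_ing", "sf_inh", "sf_derm", "kp"):
            v = getattr(self, name)
            if v is not None and not (math.isfinite(v) and v > 0):
                raise ValidationError(f"{name} for {self.metal} must be positive if present, got {v!r}")
        for auth, lim in self.guidelines.items():
            if not (math.isfinite(lim) and lim > 0):
                raise ValidationError(f"guideline {auth} for {self.metal} must be positive, got {lim!r}")

    def rfd(self, pathway: str) -> float | None:
        return getattr(self, f"rfd_{_PATHWAY_ABBREV[pathway]}")

    def sf(self, pathway: str) -> float | None:
        return getattr(self, f"sf_{_PATHWAY_ABBREV[pathway]}")


_PATHWAY_ABBREV = {"ingestion": "ing", "inhalation": "inh", "dermal": "derm"}


@dataclass
class ToxicityTable:
    per_metal: dict[str, MetalToxicity] = field(default_factory=dict)

    def get(self, metal: str) -> MetalToxicity:
        return self.per_metal.get(metal, MetalToxicity(metal=metal))

    def __contains__(self, metal: str) -> bool:
        return metal in self.per_metal

    @classmethod
    def from_dict(cls, d: Mapping[str, Mapping[str, object]]) -> "ToxicityTable":
        per = {}
        for metal, entry in d.items():
            sym = canonical_metal(metal)
            kwargs = {k: v for k, v in entry.items() if k != "guidelines"}
            guidelines = dict(entry.get("guidelines", {}) or {})
            per[sym] = MetalToxicity(metal=sym, guidelines=guidelines, **kwargs)  # type: ignore[arg-type]
        return cls(per)


@dataclass(frozen=True)
class GuidelineStatus:
    metal: str
    authority: str
    mean: float | None
    limit: float | None
    status: str  # below | exceeds | no-guideline
    ratio: float | None


def compare_to_guidelines(
    summary: ConcentrationSummary, toxicity: ToxicityTable, authorities: Iterable[str] | None = None
) -> list[GuidelineStatus]:
    """Screen per-metal mean concentrations against guideline limits.

    For each metal in the summary and each authority, report ``exceeds`` when
    mean > limit, ``below`` otherwise, with the mean/limit ratio; an absent
    guideline (or a non-detectable metal) yields ``no-guideline`` with no
    fabricated numbers.
    """
    out: list[GuidelineStatus] = []
    for metal, ms in summary.per_metal.items():
        limits = toxicity.get(metal).guidelines
        names = list(authorities) if authorities is not None else list(limits)
        if not names:
            out.append(GuidelineStatus(metal, "-", ms.mean, None, "no-guideline", None))
            continue
        for auth in names:
            limit = limits.get(auth)
            if limit is None or ms.mean is None:
                out.append(GuidelineStatus(metal, auth, ms.mean, limit, "no-guideline", None))
            else:
                ratio = ms.mean / limit
                status = "exceeds" if ms.mean > limit else "below"
                out.append(GuidelineStatus(metal, auth, ms.mean, limit, status, ratio))
    return out
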