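"""Average daily intake (ADI) by exposure pathway, in mg/kg/day.

Five standard USEPA-style chronic dose equations for an adult receptor:
soil ingestion, water ingestion, soil-dust inhalation (via the particle
emission factor PEF), soil dermal contact, and water dermal contact (via the
metal-specific skin permeability KP). Soil-mass pathways carry a 1e-6 kg/mg
conversion so that mg/kg soil times mg/day intake yields mg/day of metal.

Every equation is exactly linear in concentration and inversely proportional
to body weight; with the default parameters (EF=365 d/y, AT=ED*365 d) the
EF*ED/AT factor is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

from .datamodel import ExposureParameters, ValidationError

KG_PER_MG = 1e-6
L_PER_CM3 = 1e-3

PATHWAYS_SOIL = ("ingestion", "inhalation", "dermal")
PATHWAYS_WATER = ("ingestion", "dermal")


def _check_conc(c: float) -> None:
    if c < 0:
        raise ValidationError(f"concentration must be non-negative (got {c})")


def adi_ingestion_soil(cs: float, p: ExposureParameters) -> float:
    """Dose from incidental soil ingestion: Cs*IngRs*1e-6*EF*ED/(BW*AT)."""
    _check_conc(cs)
    return cs * p.ingr_soil * KG_PER_MG * p.ef * p.ed / (p.bw * p.at)


def adi_ingestion_water(cw: float, p: ExposureParameters) -> float:
    """Dose from drinking-water ingestion: Cw*IngRw*EF*ED/(BW*AT).

    No mass conversion: L/day times mg/L is already mg/day."""
    _check_conc(cw)
    return cw * p.ingr_water * p.ef * p.ed / (p.bw * p.at)


def adi_inhalation_soil(cs: float, p: ExposureParameters) -> float:
    """Dose from inhaling resuspended soil dust: Cs*InhR*EF*ED/(PEF*BW*AT)."""
    _check_conc(cs)
    return cs * p.inhr * p.ef * p.ed / (p.pef * p.bw * p.at)


def adi_dermal_soil(c: float, p: ExposureParameters) -> float:
    """Dose from dermal contact with soil: C*SA*AF*ABS*1e-6*EF*ED/(BW*AT)."""
    _check_conc(c)
    return c * p.sa * p.af * p.abs * KG_PER_MG * p.ef * p.ed / (p.bw * p.at)


def adi_dermal_water(
    c: float, kp: float | None, p: ExposureParameters, conventional: bool = False
) -> float:
    """Dose from dermal contact with water.

    Default form: C*1e-3*SA*KP*AF*ABS*ET*EF*ED/(BW*AT). SA (cm2) * KP (cm/h)
    * ET (h) is a water volume in cm3; the 1e-3 L/cm3 factor converts it so
    that mg/L times litres gives mg of metal. ``conventional=True`` switches
    to the usual USEPA water-dermal expression, which drops the AF and ABS
    factors. ``kp`` is metal-specific; if a metal has no KP the pathway is
    not assessable and the caller should skip it — passing None raises.
    """
    _check_conc(c)
    if kp is None:
        raise ValidationError("KP is required for the water dermal pathway")
    base = c * L_PER_CM3 * p.sa * kp * p.et * p.ef * p.ed / (p.bw * p.at)
    return base if conventional else base * p.af * p.abs


@dataclass(frozen=True)
class AdiResult:
    metal: str
    medium: str
    pathway: str  # ingestion | inhalation | dermal
    adi: float | None  # None => pathway not assessable (e.g. no KP)
    concentration: float | None = None

    @property
    def assessed(self) -> bool:
        return self.adi is not None


def adi_all_pathways(
    metal: str,
    concentration: float,
    medium: str,
    p: ExposureParameters,
    kp: float | None = None,
) -> list[AdiResult]:
    """ADI for every pathway relevant to the medium.

    Soil: ingestion, inhalation, dermal. Water: ingestion, dermal (dermal only
    when the metal has a permeability constant; otherwise an unassessed result
    is returned rather than a silent zero)."""
    out: list[AdiResult] = []
    if medium == "soil":
        out.append(AdiResult(metal, medium, "ingestion", adi_ingestion_soil(concentration, p), concentration))
        out.append(AdiResult(metal, medium, "inhalation", adi_inhalation_soil(concentration, p), concentration))
        out.append(AdiResult(metal, medium, "dermal", adi_dermal_soil(concentration, p), concentration))
    elif medium == "water":
        out.append(AdiResult(metal, medium, "ingestion", adi_ingestion_water(concentration, p), concentration))
        if kp is None:
            out.append(AdiResult(metal, medium, "dermal", None, concentration))
        else:
            out.append(AdiResult(metal, medium, "dermal", adi_dermal_water(concentration, kp, p), concentration))
    else:
        raise ValidationError(f"unknown medium {medium!r}")
    return out
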