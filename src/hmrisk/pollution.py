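"""Enrichment/pollution indices and depth-attenuation summaries.

Three indices separate anthropogenic from geogenic metal input by contrasting
a polluted site against an unpolluted control sharing its geology:

* MEF — modified enrichment factor, the site/control concentration ratio.
  By default the plain per-element ratio is used; the classical double-ratio
  normalisation against a conservative reference element is available via
  ``reference_element``.
* MPI — modified pollution index, the root-mean-square of the mean- and
  maximum-based enrichment factors.
* AM — anthropogenic metal fraction, the percentage excess of the site
  concentration over the control (lithogenic) baseline; algebraically
  AM = 100*(MEF - 1) for the same concentration pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import ConcentrationSummary, ValidationError

ENRICHMENT_BANDS = (
    (2.0, "minimal enrichment"),
    (5.0, "moderate enrichment"),
    (20.0, "significant enrichment"),
    (40.0, "very high enrichment"),
    (math.inf, "extremely high enrichment"),
)

MPI_BANDS = (
    (1.0, "unpolluted"),
    (2.0, "slightly polluted"),
    (3.0, "moderately polluted"),
    (5.0, "significantly polluted"),
    (10.0, "severely polluted"),
    (math.inf, "extremely polluted"),
)


def mef(site_conc: float, control_conc: float) -> float:
    """Enrichment factor: site/control concentration ratio (dimensionless).

    ``control_conc`` must be positive; a zero control raises rather than
    returning infinity."""
    if control_conc <= 0:
        raise ZeroDivisionError(f"control concentration must be > 0 for MEF (got {control_conc})")
    if site_conc < 0:
        raise ValidationError(f"site concentration must be >= 0 (got {site_conc})")
    return site_conc / control_conc


def mef_double_ratio(
    site_conc: float, control_conc: float, site_ref: float, control_ref: float
) -> float:
    """Classical enrichment factor normalised by a reference element:
    (Ci/Cref)_site / (Ci/Cref)_control."""
    if site_ref <= 0 or control_ref <= 0:
        raise ZeroDivisionError("reference-element concentrations must be > 0")
    return mef(site_conc, control_conc) * (control_ref / site_ref)


def _classify(value: float, bands, kind: str) -> str:
    if value < 0 or not math.isfinite(value):
        raise ValidationError(f"{kind} must be a finite non-negative number (got {value})")
    for upper, label in bands:
        if value < upper:
            return label
    raise AssertionError("unreachable: bands end at +inf")


def classify_enrichment(mef_value: float) -> str:
    """Band an enrichment factor: minimal [0,2), moderate [2,5), significant
    [5,20), very high [20,40), extremely high [40,inf). Bands are half-open at
    the upper edge."""
    return _classify(mef_value, ENRICHMENT_BANDS, "MEF")


def mpi(mef_mean: float, mef_max: float) -> float:
    """Root-mean-square of the mean- and max-based enrichment factors."""
    if mef_mean < 0 or mef_max < 0:
        raise ValidationError("MEF components must be non-negative")
    return math.sqrt((mef_mean**2 + mef_max**2) / 2.0)


def classify_mpi(mpi_value: float) -> str:
    """Band a pollution index: unpolluted [0,1), slight [1,2), moderate [2,3),
    significant [3,5), severe [5,10), extreme [10,inf)."""
    return _classify(mpi_value, MPI_BANDS, "MPI")


def am(site_conc: float, control_conc: float) -> float:
    """Anthropogenic metal percentage, 100*(site - control)/control.

    Negative when the site sits below the control baseline."""
    if control_conc <= 0:
        raise ZeroDivisionError(f"control concentration must be > 0 for AM (got {control_conc})")
    return 100.0 * (site_conc - control_conc) / control_conc


@dataclass(frozen=True)
class MetalPollution:
    metal: str
    mef_mean: float
    mef_max: float
    mpi: float
    am_percent: float
    enrichment_class: str
    mpi_class: str


def evaluate_pollution(
    site: ConcentrationSummary,
    control: ConcentrationSummary,
    reference_element: str | None = None,
) -> list[MetalPollution]:
    """Per-metal pollution evaluation from site and control summaries.

    MEF_mean uses the site mean, MEF_max the site maximum; both divide by the
    control mean. Metals lacking a detected mean in either summary are
    skipped. With ``reference_element`` the double-ratio normalisation is
    applied to both MEF components.
    """
    results: list[MetalPollution] = []
    ref_pair = None
    if reference_element is not None:
        rs, rc = site.per_metal.get(reference_element), control.per_metal.get(reference_element)
        if rs is None or rc is None or rs.mean is None or rc.mean is None or rs.mean <= 0:
            raise ValidationError(f"reference element {reference_element} lacks detected means")
        ref_pair = (rs.mean, rc.mean)
    for metal, ms in site.per_metal.items():
        mc = control.per_metal.get(metal)
        if ms.mean is None or mc is None or mc.mean is None or mc.mean <= 0:
            continue
        scale = 1.0 if ref_pair is None else ref_pair[1] / ref_pair[0]
        m_mean = mef(ms.mean, mc.mean) * scale
        m_max = mef(ms.maximum, mc.mean) * scale
        results.append(
            MetalPollution(
                metal=metal,
                mef_mean=m_mean,
                mef_max=m_max,
                mpi=mpi(m_mean, m_max),
                am_percent=am(ms.mean, mc.mean),
                enrichment_class=classify_enrichment(m_mean),
                mpi_class=classify_mpi(mpi(m_mean, m_max)),
            )
        )
    return results


def pollution_frame(results: list[MetalPollution]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metal": r.metal,
                "mef_mean": r.mef_mean,
                "mef_max": r.mef_max,
                "mpi": r.mpi,
                "am_percent": r.am_percent,
                "enrichment_class": r.enrichment_class,
                "mpi_class": r.mpi_class,
            }
            for r in results
        ]
    )


@dataclass(frozen=True)
class DepthSummary:
    """Depth behaviour of one metal: relative surface-to-plateau decrease,
    scatter below the plateau depth, and monotone-decline check above it."""

    metal: str
    relative_decrease_percent: float | None
    plateau_cv_percent: float | None
    monotone_decline: bool | None
    incomplete: bool = False


def depth_attenuation(
    profile: Mapping[float, Mapping[str, float]] | pd.DataFrame,
    decline_to_cm: float = 50.0,
) -> dict[str, DepthSummary]:
    """Summarise concentration-vs-depth profiles.

    ``profile`` maps depth (cm) to per-metal concentration (or a DataFrame
    indexed by depth with metals as columns). Per metal the summary carries:
    the relative decrease 100*(c(0) - c(d*))/c(0) between the surface and the
    depth nearest ``decline_to_cm``; the CV of concentrations strictly below
    that depth (the plateau); and whether the profile is non-strictly
    decreasing from the surface down to it. A profile without a 0 cm level is
    marked incomplete.
    """
    if isinstance(profile, pd.DataFrame):
        df = profile.astype(float)
    else:
        df = pd.DataFrame({d: dict(m) for d, m in profile.items()}).T.astype(float)
    df = df.sort_index()
    if len(df.index) < 2:
        raise ValidationError("depth profile needs at least 2 depth levels")
    depths = np.asarray(df.index, dtype=float)
    out: dict[str, DepthSummary] = {}
    has_surface = np.isclose(depths, 0.0).any()
    target = depths[np.argmin(np.abs(depths - decline_to_cm))]
    for metal in df.columns:
        col = df[metal].dropna()
        if not has_surface or 0.0 not in col.index:
            out[metal] = DepthSummary(metal, None, None, None, incomplete=True)
            continue
        c0 = col.loc[0.0]
        cd = col.loc[target]
        decrease = 100.0 * (c0 - cd) / c0 if c0 > 0 else None
        upper = col[(col.index >= 0.0) & (col.index <= target)].sort_index()
        monotone = bool(np.all(np.diff(upper.to_numpy()) <= 0))
        plateau = col[col.index > target].to_numpy()
        if plateau.size >= 2 and plateau.mean() != 0:
            cv = 100.0 * float(np.std(plateau, ddof=1)) / float(plateau.mean())
        else:
            cv = None
        out[metal] = DepthSummary(metal, decrease, cv, monotone)
    return out
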