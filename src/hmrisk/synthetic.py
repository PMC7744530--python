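"""Synthetic concentration tables and depth profiles.

The generator emulates the statistical structure of the study system so the
whole pipeline is testable without field data: per-metal lognormal
concentrations moment-matched to target (mean, SD) with a strong site-over-
control contrast, Ag non-detect in water, and soil depth profiles that decay
geometrically from a surface value to a plateau at 50 cm and stay flat below
(multiplicative lognormal noise, default 5% CV).

Defaults ship in ``data/defaults.yaml``; a few control-group SDs there are
plausible placeholders (marked ``synthetic: true``) where the source summary
printed a garbled or zero SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import ConcentrationRecord, ConcentrationTable
from .io import load_default_config


class ConfigError(ValueError):
    """Raised for inconsistent synthetic-generator settings."""


@dataclass(frozen=True)
class MetalTarget:
    mean: float | None
    sd: float | None
    nondetect: bool = False


@dataclass
class SyntheticConfig:
    """Targets for the generator: per (medium, group, metal) mean/SD, group
    sizes, and the depth-profile shape (surface, plateau value, plateau depth)."""

    concentrations: dict[tuple[str, str], dict[str, MetalTarget]]
    n_samples: dict[str, int]
    depth_grid_cm: list[float]
    plateau_cm: float
    depth_noise_cv: float
    depth_metals: dict[str, tuple[float, float]]  # metal -> (surface, plateau value)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plateau_cm not in self.depth_grid_cm:
            raise ConfigError(f"plateau depth {self.plateau_cm} cm must be on the depth grid")
        if self.depth_noise_cv < 0:
            raise ConfigError("depth noise CV must be >= 0")
        for metal, (surface, plateau) in self.depth_metals.items():
            if surface < plateau:
                raise ConfigError(f"{metal}: surface {surface} below plateau {plateau}")

    @classmethod
    def from_config(cls, cfg: Mapping, seed: int = 0) -> "SyntheticConfig":
        syn = cfg["synthetic"]
        conc: dict[tuple[str, str], dict[str, MetalTarget]] = {}
        for medium, groups in syn["concentrations"].items():
            for group, metals in groups.items():
                conc[(medium, group)] = {
                    m: MetalTarget(
                        mean=entry.get("mean"),
                        sd=entry.get("sd"),
                        nondetect=bool(entry.get("nondetect", False)),
                    )
                    for m, entry in metals.items()
                }
        dp = syn["depth_profile"]
        return cls(
            concentrations=conc,
            n_samples=dict(syn["n_samples"]),
            depth_grid_cm=[float(d) for d in dp["grid_cm"]],
            plateau_cm=float(dp["plateau_cm"]),
            depth_noise_cv=float(dp["noise_cv"]),
            depth_metals={m: (float(e["surface"]), float(e["plateau"])) for m, e in dp["metals"].items()},
            seed=seed,
        )

    @classmethod
    def default(cls, seed: int = 0) -> "SyntheticConfig":
        return cls.from_config(load_default_config(), seed=seed)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def generate_concentrations(
    config: SyntheticConfig,
    medium: str,
    group: str,
    n: int | None = None,
    seed: int | None = None,
) -> ConcentrationTable:
    """Draw a synthetic :class:`ConcentrationTable` for one medium and group.

    Per metal, ``n`` lognormal values moment-matched to the configured
    (mean, SD); metals flagged non-detect yield ``detected=False`` records.
    Deterministic given (config, seed).
    """
    key = (medium, group)
    if key not in config.concentrations:
        raise ConfigError(f"no synthetic targets for medium={medium!r}, group={group!r}")
    if n is None:
        n = config.n_samples[f"{medium}_{group}"]
    if n < 1:
        raise ConfigError(f"n must be >= 1 (got {n})")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records: list[ConcentrationRecord] = []
    for metal, target in config.concentrations[key].items():
        if target.nondetect:
            for i in range(n):
                records.append(ConcentrationRecord(f"{medium[0]}{group[0]}{i + 1:03d}", metal, 0.0, detected=False))
            continue
        if target.mean is None or target.mean <= 0:
            raise ConfigError(f"{metal} {medium}/{group}: positive target mean required")
        if target.sd is None or target.sd <= 0:
            if n > 1:
                raise ConfigError(f"{metal} {medium}/{group}: positive sd required for n > 1")
            values = np.array([target.mean])
        else:
            mu, sigma = _lognormal_params(target.mean, target.sd)
            values = rng.lognormal(mu, sigma, size=n)
        for i, v in enumerate(values):
            records.append(ConcentrationRecord(f"{medium[0]}{group[0]}{i + 1:03d}", metal, float(v)))
    return ConcentrationTable(medium=medium, group=group, records=records)


def generate_depth_profile(
    config: SyntheticConfig, seed: int | None = None, noise_cv: float | None = None
) -> pd.DataFrame:
    """Synthetic depth-vs-concentration table (depth cm index, metal columns).

    The noise-free profile interpolates geometrically from the surface value
    at 0 cm to the plateau value at the plateau depth — strictly decreasing in
    between whenever plateau < surface — and is constant below. Multiplicative
    lognormal noise with the configured CV (mean 1) is applied on top; CV 0
    reproduces the deterministic shape exactly.
    """
    cv = config.depth_noise_cv if noise_cv is None else noise_cv
    if cv < 0:
        raise ConfigError("noise CV must be >= 0")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    depths = np.asarray(sorted(config.depth_grid_cm), dtype=float)
    d_plateau = config.plateau_cm
    cols: dict[str, np.ndarray] = {}
    for metal, (surface, plateau) in config.depth_metals.items():
        with np.errstate(divide="ignore"):
            frac = np.clip(depths / d_plateau, 0.0, 1.0)
            if plateau == surface:
                base = np.full_like(depths, surface)
            else:
                # geometric interpolation: c(0)=surface, c(D)=plateau, flat below D
                base = surface * (plateau / surface) ** frac
        if cv > 0:
            sigma2 = math.log1p(cv**2)
            noise = rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2), size=depths.size)
            base = base * noise
        cols[metal] = base
    return pd.DataFrame(cols, index=pd.Index(depths, name="depth_cm"))
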