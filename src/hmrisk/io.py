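"""CSV and config readers/writers.

Concentration tables travel as long-format UTF-8 CSV with columns
``sample_id,metal,value`` ("." decimal separator). The value cell is a number
or a non-detect token ({ND, NA, empty}, case-insensitive). Writers emit a
leading ``#`` comment line naming the units.
"""

from __future__ import annotations

import io as _io
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .datamodel import (
    ND_TOKENS,
    ConcentrationRecord,
    ConcentrationSummary,
    ConcentrationTable,
    ExposureParameters,
    GuidelineStatus,
    ToxicityTable,
    ValidationError,
    canonical_metal,
)

REQUIRED_COLUMNS = ("sample_id", "metal", "value")


class SchemaError(ValueError):
    """Raised when a CSV file does not carry the expected columns."""


def read_concentration_table(path: str | Path, medium: str, group: str) -> ConcentrationTable:
    """Read a long-format concentration CSV into a validated table.

    Non-detect cells become records with ``detected=False`` (value 0.0,
    excluded from all downstream statistics); metal names are canonicalized to
    element symbols. Negative or non-numeric values raise
    :class:`~hmrisk.datamodel.ValidationError` naming the offending row.
    """
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; header must declare {REQUIRED_COLUMNS}")
    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # line 1 is the header
        metal = canonical_metal(str(row.metal))
        raw = str(row.value).strip()
        if raw.lower() in ND_TOKENS:
            records.append(ConcentrationRecord(str(row.sample_id), metal, 0.0, detected=False))
            continue
        try:
            value = float(raw.replace("−", "-"))  # tolerate unicode minus
        except ValueError as exc:
            raise ValidationError(f"{path} line {idx}: value {raw!r} is not a number or ND token") from exc
        if value < 0:
            raise ValidationError(f"{path} line {idx}: negative concentration {value} for {metal}")
        records.append(ConcentrationRecord(str(row.sample_id), metal, value))
    return ConcentrationTable(medium=medium, group=group, records=records)


def write_concentration_table(table: ConcentrationTable, path: str | Path) -> None:
    """Write a table as long-format CSV with a units header comment.

    Values round-trip bit-identically through :func:`read_concentration_table`
    for decimal inputs (repr-based formatting)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# medium={table.medium} group={table.group} units={table.units}\n")
        fh.write("sample_id,metal,value\n")
        for rec in table.records:
            cell = repr(rec.value) if rec.detected else "ND"
            fh.write(f"{rec.sample_id},{rec.metal},{cell}\n")


def summary_frame(summary: ConcentrationSummary) -> pd.DataFrame:
    rows = []
    for metal, ms in summary.per_metal.items():
        rows.append(
            {
                "metal": metal,
                "n": ms.n,
                "n_nondetect": ms.n_nondetect,
                "min": ms.minimum,
                "max": ms.maximum,
                "mean": ms.mean,
                "sd": ms.sd,
                "cv_percent": ms.cv_percent,
                "not_detectable": ms.not_detectable,
            }
        )
    return pd.DataFrame(rows)


def exceedance_frame(statuses: list[GuidelineStatus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metal": s.metal,
                "authority": s.authority,
                "mean": s.mean,
                "limit": s.limit,
                "status": s.status,
                "ratio": s.ratio,
            }
            for s in statuses
        ]
    )


def _default_config_text() -> str:
    return resources.files("hmrisk.data").joinpath("defaults.yaml").read_text(encoding="utf-8")


def load_default_config() -> dict:
    """The bundled study configuration (exposure parameters, toxicity table,
    guideline limits, synthetic-generator targets)."""
    return yaml.safe_load(_io.StringIO(_default_config_text()))


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config file, falling back to the bundled defaults.

    A user file only needs the keys it overrides; missing top-level blocks are
    taken from the defaults."""
    cfg = load_default_config()
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, Mapping) and isinstance(cfg.get(key), Mapping):
                merged = dict(cfg[key])
                merged.update(val)
                cfg[key] = merged
            else:
                cfg[key] = val
    return cfg


def exposure_from_config(cfg: Mapping) -> ExposureParameters:
    return ExposureParameters(**cfg.get("exposure", {}))


def toxicity_from_config(cfg: Mapping) -> ToxicityTable:
    entries = {}
    for metal, entry in (cfg.get("toxicity") or {}).items():
        entry = dict(entry or {})
        entry.pop("synthetic", None)
        entries[metal] = entry
    return ToxicityTable.from_dict(entries)
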