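"""Pipeline orchestration and human-readable reporting.

``run_pipeline`` drives the full analysis — summaries, guideline screening,
pollution indices, deterministic risk for both media, and the optional Monte
Carlo stage — writing one CSV per stage plus a markdown report. Every number
in the report is an operation output; the report layer does no arithmetic of
its own. A stage failure removes any partially written outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import exposure as exp
from .datamodel import (
    ConcentrationSummary,
    ConcentrationTable,
    ExposureParameters,
    ToxicityTable,
    compare_to_guidelines,
    summarize,
)
from .io import (
    exceedance_frame,
    exposure_from_config,
    load_config,
    read_concentration_table,
    summary_frame,
    toxicity_from_config,
    write_concentration_table,
)
from .montecarlo import DistributionSpec, default_param_dists, simulate_ilcr
from .pollution import evaluate_pollution, pollution_frame
from .risk import CARCINOGENS, assess_medium, risk_frame

log = logging.getLogger("hmrisk")


def format_scientific(x: float, sig: int = 3) -> str:
    """Format in the tabular style ``d.ddE-n`` at ``sig`` significant figures,
    rounding half away from zero; values with |base-10 exponent| <= 2 print in
    fixed notation instead (e.g. 2.9126 -> "2.91", 164.47 -> "164")."""
    if sig < 1:
        raise ValueError(f"sig must be >= 1 (got {sig})")
    if x == 0:
        mant = "0" if sig == 1 else "0." + "0" * (sig - 1)
        return f"{mant}E0"
    d = Decimal(repr(float(x)))
    exponent = d.adjusted()
    mant = d.scaleb(-exponent).quantize(Decimal(1).scaleb(-(sig - 1)), rounding=ROUND_HALF_UP)
    if abs(mant) >= 10:  # e.g. 9.996 at 3 s.f.
        mant = (mant / 10).quantize(Decimal(1).scaleb(-(sig - 1)), rounding=ROUND_HALF_UP)
        exponent += 1
    if -2 <= exponent <= 2:
        fixed = mant.scaleb(exponent)
        decimals = max(0, sig - 1 - exponent)
        return str(fixed.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))
    return f"{mant}E{exponent}"


def round_sig(x: float, sig: int = 3) -> float:
    """Round half-away-from-zero at ``sig`` significant figures."""
    if x == 0:
        return 0.0
    d = Decimal(repr(float(x)))
    q = d.scaleb(-d.adjusted()).quantize(Decimal(1).scaleb(-(sig - 1)), rounding=ROUND_HALF_UP)
    return float(q.scaleb(d.adjusted()))


@dataclass
class RunConfig:
    """Settings for one end-to-end run.

    Exactly one of {explicit input paths, synthetic mode} should be active per
    medium; a seed is mandatory whenever the Monte Carlo stage is enabled."""

    outdir: Path
    synth: bool = True
    seed: int | None = None
    inputs: dict[tuple[str, str], Path] = field(default_factory=dict)  # (medium, group) -> CSV
    config_path: Path | None = None
    mc_enabled: bool = True
    mc_trials: int = 10_000
    ilcr_mode: str = "ingestion"

    def validate(self) -> None:
        media_from_paths = {m for (m, _g) in self.inputs}
        if self.synth and media_from_paths:
            raise ValueError("choose either synthetic mode or explicit input paths, not both")
        if not self.synth and not self.inputs:
            raise ValueError("no inputs: give CSV paths or enable synthetic mode")
        if self.mc_enabled and self.seed is None:
            raise ValueError("a seed is required when the Monte Carlo stage is enabled")
        if self.synth and self.seed is None:
            raise ValueError("a seed is required in synthetic mode")


def _sub_seed(seed: int, *key: int) -> int:
    """Deterministic child seed below 2**31 from a base seed and an index key."""
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0] % (2**31))


def _load_tables(cfg: RunConfig) -> dict[tuple[str, str], ConcentrationTable]:
    tables: dict[tuple[str, str], ConcentrationTable] = {}
    if cfg.synth:
        from .synthetic import SyntheticConfig, generate_concentrations

        syn = SyntheticConfig.from_config(load_config(cfg.config_path), seed=cfg.seed)
        for i, (medium, group) in enumerate([("soil", "site"), ("soil", "control"), ("water", "site"), ("water", "control")]):
            tables[(medium, group)] = generate_concentrations(syn, medium, group, seed=_sub_seed(cfg.seed, 100 + i))
    else:
        for (medium, group), path in cfg.inputs.items():
            tables[(medium, group)] = read_concentration_table(path, medium, group)
    for (medium, group), tab in tables.items():
        if not tab.records:
            raise ValueError(f"empty concentration table for {medium}/{group}")
    return tables


def _adi_frame(summary: ConcentrationSummary, tox: ToxicityTable, p: ExposureParameters) -> pd.DataFrame:
    rows = []
    for metal, ms in summary.per_metal.items():
        kp = tox.get(metal).kp
        for stat, conc in (("min", ms.minimum), ("mean", ms.mean), ("max", ms.maximum)):
            if conc is None:
                continue
            for a in exp.adi_all_pathways(metal, conc, summary.medium, p, kp=kp):
                rows.append(
                    {
                        "metal": metal,
                        "statistic": stat,
                        "concentration": conc,
                        "pathway": a.pathway,
                        "adi": a.adi,
                        "adi_formatted": format_scientific(a.adi) if a.adi is not None else "not assessed",
                    }
                )
    return pd.DataFrame(rows)


def _md_table(df: pd.DataFrame, float_cols: tuple[str, ...] = ()) -> str:
    show = df.copy()
    for c in float_cols:
        if c in show.columns:
            show[c] = show[c].map(lambda v: format_scientific(v) if isinstance(v, float) and pd.notna(v) else ("" if v is None or (isinstance(v, float) and pd.isna(v)) else v))
    cols = list(show.columns)
    lines = ["| " + " | ".join(cols) + " |", "|" + "|".join("---" for _ in cols) + "|"]
    for _, row in show.iterrows():
        lines.append("| " + " | ".join("" if pd.isna(row[c]) else str(row[c]) for c in cols) + " |")
    return "\n".join(lines)


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run the full analysis and write the report bundle into ``cfg.outdir``.

    Returns a mapping of artifact name to file path. On any stage error the
    partially written files are removed and the exception re-raised."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _write_csv(name: str, df: pd.DataFrame) -> None:
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        written[name] = path

    try:
        config = load_config(cfg.config_path)
        params = exposure_from_config(config)
        tox = toxicity_from_config(config)
        carcinogens = tuple(config.get("carcinogens", CARCINOGENS))

        log.info("stage: load/generate concentration tables")
        tables = _load_tables(cfg)
        summaries = {key: summarize(tab) for key, tab in tables.items()}
        for (medium, group), summ in summaries.items():
            _write_csv(f"summary_{medium}_{group}", summary_frame(summ))
        if cfg.synth:
            for (medium, group), tab in tables.items():
                path = outdir / f"synthetic_{medium}_{group}.csv"
                write_concentration_table(tab, path)
                written[f"synthetic_{medium}_{group}"] = path

        log.info("stage: guideline screening (water)")
        water_exc = compare_to_guidelines(summaries[("water", "site")], tox, authorities=("WHO", "USEPA", "ECE")) if ("water", "site") in summaries else []
        if water_exc:
            _write_csv("guideline_exceedance_water", exceedance_frame(water_exc))

        pollution_results = []
        if ("soil", "site") in summaries and ("soil", "control") in summaries:
            log.info("stage: pollution indices")
            pollution_results = evaluate_pollution(summaries[("soil", "site")], summaries[("soil", "control")])
            _write_csv("pollution_indices", pollution_frame(pollution_results))

        risk_results: dict[str, list] = {}
        for medium in ("soil", "water"):
            key = (medium, "site")
            if key not in summaries:
                continue
            log.info("stage: ADI + risk (%s)", medium)
            _write_csv(f"adi_{medium}", _adi_frame(summaries[key], tox, params))
            res = assess_medium(summaries[key], tox, params, medium, carcinogens=carcinogens, ilcr_mode=cfg.ilcr_mode)
            risk_results[medium] = res
            _write_csv(f"risk_{medium}", risk_frame(res))

        mc_rows = []
        if cfg.mc_enabled and ("water", "site") in summaries:
            log.info("stage: Monte Carlo (%d trials)", cfg.mc_trials)
            wsum = summaries[("water", "site")]
            for j, metal in enumerate(carcinogens):
                ms = wsum.per_metal.get(metal)
                if ms is None or ms.mean is None or ms.sd is None or tox.get(metal).sf_ing is None:
                    continue
                mc = simulate_ilcr(
                    metal,
                    DistributionSpec.lognormal(ms.mean, ms.sd),
                    default_param_dists(params),
                    tox,
                    n_trials=cfg.mc_trials,
                    seed=_sub_seed(cfg.seed, 200 + j),
                    exposure=params,
                )
                mc_rows.append({"metal": metal, "mean": mc.mean, "p5": mc.p5, "p95": mc.p95})
            if mc_rows:
                _write_csv("mc_summary", pd.DataFrame(mc_rows))

        log.info("stage: report")
        report_path = outdir / "report.md"
        report_path.write_text(
            _render_report(summaries, water_exc, pollution_results, risk_results, mc_rows, cfg),
            encoding="utf-8",
        )
        written["report"] = report_path
        return written
    except Exception:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise


def _render_report(summaries, water_exc, pollution_results, risk_results, mc_rows, cfg: RunConfig) -> str:
    parts = ["# Heavy-metal exposure and health-risk report", ""]
    parts.append(f"Mode: {'synthetic data' if cfg.synth else 'measured input files'}; seed: {cfg.seed}.")
    parts.append("")
    for (medium, group), summ in summaries.items():
        parts.append(f"## Concentrations: {medium} / {group} ({'mg/kg' if medium == 'soil' else 'mg/L'})")
        parts.append(_md_table(summary_frame(summ), float_cols=("min", "max", "mean", "sd", "cv_percent")))
        parts.append("")
    if water_exc:
        parts.append("## Drinking-water guideline screening (site wells)")
        exceeding = sorted({s.metal for s in water_exc if s.status == "exceeds"})
        parts.append(_md_table(exceedance_frame(water_exc), float_cols=("mean", "limit", "ratio")))
        if exceeding:
            parts.append("")
            parts.append("Metals whose mean exceeds at least one guideline: " + ", ".join(exceeding) + ".")
        parts.append("")
    if pollution_results:
        parts.append("## Pollution indices (site vs control topsoil)")
        parts.append(_md_table(pollution_frame(pollution_results), float_cols=("mef_mean", "mef_max", "mpi", "am_percent")))
        parts.append("")
    for medium, res in risk_results.items():
        parts.append(f"## Risk characterisation: {medium}")
        parts.append(_md_table(risk_frame(res), float_cols=("thq_ingestion", "thq_inhalation", "thq_dermal", "hi", "ilcr")))
        concern = [r.metal for r in res if r.hi_flag == "concern"]
        above = [r.metal for r in res if r.range_flag == "above_range"]
        parts.append("")
        parts.append(
            f"Hazard index >= 1 (non-carcinogenic concern): {', '.join(concern) if concern else 'none'}. "
            f"Cancer risk above the 1E-6..1E-4 acceptable range: {', '.join(above) if above else 'none'}."
        )
        parts.append("")
    if mc_rows:
        parts.append(f"## Monte Carlo ILCR, water ingestion ({cfg.mc_trials} trials)")
        parts.append(_md_table(pd.DataFrame(mc_rows), float_cols=("mean", "p5", "p95")))
        parts.append("")
    return "\n".join(parts)
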