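"""End-to-end pipeline: one configuration in, the full set of
financial-protection tables out.

Outputs mirror the shape of a standard financial-protection report: an
incidence trend (year x CHE definition), a stratified incidence table with
confidence intervals, impoverishment and poverty-gap tables by region and
expenditure quintile, and the pooled odds-ratio table with diagnostics.
Runs are deterministic for a fixed configuration and seed; empty strata
are rendered with an en-dash.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catastrophic import CheConfig, assign_quintiles, che_incidence, che_table
from .datamodel import SurveyDataset, read_survey, write_table
from .determinants import CheDeterminants
from .impoverish import PovertyLine, impoverishment
from .synth import SURVEY_YEARS, default_params, generate_survey

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "render_tables", "load_config"]

log = logging.getLogger("finprotect")

MISSING_MARK = "–"  # en-dash for empty strata

DEFAULT_CHE_CONFIGS = (
    CheConfig(method="budget_share", threshold=0.10),
    CheConfig(method="budget_share", threshold=0.25),
    CheConfig(method="capacity_to_pay", threshold=0.40),
)


@dataclass
class PipelineConfig:
    """One config drives the whole analysis.

    ``inputs`` maps survey-year label to a CSV path; when empty, synthetic
    surveys are generated for ``years`` with ``n_households`` each.
    """

    years: tuple[str, ...] = SURVEY_YEARS
    inputs: dict = field(default_factory=dict)
    synthetic: bool = True
    n_households: int = 6720
    seed: int = 0
    che_configs: tuple[CheConfig, ...] = DEFAULT_CHE_CONFIGS
    line_usd: float = 3.1
    exchange_rate: float = 35.8  # Rs/US$ implied by the Rs 13,310 four-person monthly line
    days_per_month: float = 30.0
    determinants_thresholds: tuple = ((("budget_share", 0.10)), ("budget_share", 0.25), ("capacity_to_pay", 0.40))
    hl_groups: int = 10
    ci_level: float = 0.95
    generator_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.years) == 0:
            raise ValueError("pipeline needs at least one survey year")
        seen = set()
        for cfg in self.che_configs:
            key = (cfg.method, cfg.threshold)
            if key in seen:
                raise ValueError(f"duplicate CHE definition {key}")
            seen.add(key)


@dataclass
class ReportBundle:
    """All pipeline outputs plus run metadata."""

    incidence_trend: pd.DataFrame
    stratified_table: pd.DataFrame
    impoverishment_table: pd.DataFrame
    poverty_gap_table: pd.DataFrame
    or_tables: dict
    diagnostics: dict
    metadata: dict


def load_config(path) -> PipelineConfig:
    """Read a YAML pipeline configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    che = raw.pop("che_configs", None)
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in PipelineConfig.__dataclass_fields__})
    if raw.get("years"):
        cfg.years = tuple(raw["years"])
    if che:
        cfg.che_configs = tuple(CheConfig(method=c["method"], threshold=float(c["threshold"])) for c in che)
    return cfg


def _load_surveys(cfg: PipelineConfig) -> dict[str, SurveyDataset]:
    surveys: dict[str, SurveyDataset] = {}
    for i, year in enumerate(cfg.years):
        if cfg.inputs:
            surveys[year] = read_survey(cfg.inputs[year])
        else:
            # per-year seeds derived from the master seed, kept below 2^31
            params = default_params(year, n_households=cfg.n_households, seed=(cfg.seed * 131 + i) % (2**31 - 1))
            if cfg.generator_overrides:
                params = replace(params, **cfg.generator_overrides)
            surveys[year] = generate_survey(params)
        log.info("survey %s: %d households", year, len(surveys[year]))
    return surveys


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Run the full analysis deterministically from one configuration."""
    surveys = _load_surveys(cfg)
    pl = PovertyLine(cfg.line_usd, cfg.exchange_rate, cfg.days_per_month)

    trend_rows, strat_frames, imp_rows, gap_rows = [], [], [], []
    for year, ds in surveys.items():
        for che_cfg in cfg.che_configs:
            est = che_incidence(ds, che_cfg, ci_level=cfg.ci_level)
            trend_rows.append(
                dict(
                    survey_year=year,
                    method=che_cfg.method,
                    threshold=che_cfg.threshold,
                    proportion=est.proportion,
                    ci_low=est.ci_low,
                    ci_high=est.ci_high,
                    n=est.n,
                )
            )
        strat = che_table(ds, cfg.che_configs, ci_level=cfg.ci_level)
        strat.insert(0, "survey_year", year)
        strat_frames.append(strat)

        df = ds.frame.copy()
        df["quintile"] = assign_quintiles(df)
        for by in (None, "region", "quintile"):
            results = impoverishment(df, pl, by=by)
            results = results if isinstance(results, list) else [results]
            for r in results:
                if by is not None and r.stratum == "total":
                    continue  # overall row emitted once via by=None
                imp_rows.append(
                    dict(
                        survey_year=year,
                        stratum=r.stratum,
                        level=r.level,
                        headcount_pre=r.headcount_pre,
                        headcount_post=r.headcount_post,
                        impoverished_share=r.impoverished_share,
                        n=r.n,
                    )
                )
                gap_rows.append(
                    dict(
                        survey_year=year,
                        stratum=r.stratum,
                        level=r.level,
                        gap_pre=r.gap_pre,
                        gap_post=r.gap_post,
                        gap_due_to_oop=r.gap_due_to_oop,
                    )
                )
        log.info("year %s done", year)

    or_tables, diagnostics = {}, {}
    pooled = pd.concat([s.frame for s in surveys.values()], ignore_index=True)
    for method, threshold in cfg.determinants_thresholds:
        label = f"{method}@{threshold:g}"
        try:
            model = CheDeterminants(
                method=method, threshold=threshold, hl_groups=cfg.hl_groups, ci_level=cfg.ci_level
            ).fit(pooled)
        except Exception as exc:
            raise RuntimeError(f"stage determinants[{label}] failed: {exc}") from exc
        or_tables[label] = model.or_table_.reset_index(names="covariate")
        diagnostics[label] = {
            "hl_statistic": model.hl_.statistic,
            "hl_df": model.hl_.df,
            "hl_p_value": model.hl_.p_value,
            "max_vif": float(model.vif_["vif"].replace(np.inf, np.nan).max()),
            "converged": model.result_.converged,
            "log_likelihood": model.result_.log_likelihood,
            "design_warnings": model.design_warnings_,
        }
        log.info("determinants %s fitted (HL p=%s)", label, diagnostics[label]["hl_p_value"])

    metadata = {
        "package_version": __version__,
        "seed": cfg.seed,
        "years": list(cfg.years),
        "n_per_year": {y: len(s) for y, s in surveys.items()},
        "che_configs": [dict(method=c.method, threshold=c.threshold) for c in cfg.che_configs],
        "poverty_line": dict(usd=cfg.line_usd, exchange_rate=cfg.exchange_rate, days=cfg.days_per_month),
        "quintile_variable": "per-capita total expenditure (pre-OOP), weighted, ties low",
    }
    return ReportBundle(
        incidence_trend=pd.DataFrame(trend_rows),
        stratified_table=pd.concat(strat_frames, ignore_index=True),
        impoverishment_table=pd.DataFrame(imp_rows),
        poverty_gap_table=pd.DataFrame(gap_rows),
        or_tables=or_tables,
        diagnostics=diagnostics,
        metadata=metadata,
    )


def _human_readable(df: pd.DataFrame, percent_cols: tuple[str, ...]) -> pd.DataFrame:
    out = df.copy()
    for c in percent_cols:
        if c in out.columns:
            out[c] = out[c].map(lambda v: MISSING_MARK if pd.isna(v) else f"{100 * v:.2f}")
    return out


def render_tables(bundle: ReportBundle, outdir, fmt: str = "csv") -> list[str]:
    """Write every table of the bundle; returns the files written.

    ``csv`` always writes full-precision CSVs; ``text`` additionally
    writes human-readable tables with percentages at 2 decimals and empty
    strata marked with an en-dash.
    """
    if fmt not in ("csv", "text"):
        raise ValueError(f"unknown render format {fmt!r}")
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    tables = {
        "incidence_trend": bundle.incidence_trend,
        "stratified_che": bundle.stratified_table,
        "impoverishment": bundle.impoverishment_table,
        "poverty_gap": bundle.poverty_gap_table,
    }
    for label, t in bundle.or_tables.items():
        tables[f"odds_ratios_{label.replace('@', '_').replace('.', '')}"] = t

    for name, table in tables.items():
        path = outdir / f"{name}.csv"
        write_table(table, path)
        written.append(str(path))
        if fmt == "text":
            pretty = _human_readable(table, ("proportion", "ci_low", "ci_high"))
            txt = outdir / f"{name}.txt"
            txt.write_text(pretty.to_string(index=False, na_rep=MISSING_MARK) + "\n")
            written.append(str(txt))

    meta_path = outdir / "run_metadata.json"
    meta_path.write_text(
        json.dumps({"metadata": bundle.metadata, "diagnostics": bundle.diagnostics}, indent=2, default=str)
    )
    written.append(str(meta_path))
    return written
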