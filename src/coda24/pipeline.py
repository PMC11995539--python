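"""End-to-end study orchestration.

From a cohort table (per-participant daily minutes of MVPA, LPA, ST and
sleep, a 0-63 symptom score, an urban/rural stratum label and covariates)
this module runs the complete analysis: complete-case filtering,
descriptives with compositional means, bootstrap log-ratio group
contrasts, stratified and pooled ilr regressions with per-behaviour
effects, pairwise reallocation grids, a sensitivity rerun restricted to
participants sleeping 7-9 h (420-540 min, bounds inclusive), and the
two-lines U-shape check for sleep.  Every table is written as delimited
text and the run is byte-reproducible given the seed.

The pooled ("all") model does not adjust for residency, matching its role
as the unstratified analysis; the per-stratum models are fit on the
stratum subsets with the same covariate adjustment.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coda import (PARTS, MINUTES_PER_DAY, bootstrap_contrast, compositional_mean,
                   contrast_seed)
from .reallocate import GridSpec, grid_frame, reallocation_grid
from .regression import (DEFAULT_COVARIATES, OUTCOME_COLUMN, CovariateSpec,
                         composition_matrix, effects_table, fit_ilr_model)
from .shape import TwoLinesResult, two_lines_test

SLEEP_COLUMN = "sleep_min"
STRATA = ("urban", "rural")

_FLOAT_FMT = "%.10g"


@dataclass
class AnalysisConfig:
    input_path: str | None = None
    output_dir: str = "results"
    parts_order: tuple[str, ...] = PARTS
    covariates: CovariateSpec = field(default_factory=lambda: DEFAULT_COVARIATES)
    bootstrap_replicates: int = 1000
    level: float = 0.95
    grid: GridSpec = field(default_factory=GridSpec)
    sleep_low_min: float = 420.0
    sleep_high_min: float = 540.0
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sleep_low_min < self.sleep_high_min:
            raise ValueError("sleep sensitivity bounds must be ordered")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def load_config(path) -> AnalysisConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "parts_order" in raw:
        raw["parts_order"] = tuple(raw["parts_order"])
    if "grid" in raw:
        g = raw["grid"]
        raw["grid"] = GridSpec(minutes=tuple(g.get("minutes", GridSpec().minutes)),
                               mvpa_cap=g.get("mvpa_cap", GridSpec().mvpa_cap))
    if "covariates" in raw:
        c = raw["covariates"]
        raw["covariates"] = CovariateSpec(
            categorical={k: tuple(v) for k, v in c.get("categorical", {}).items()},
            continuous=tuple(c.get("continuous", ())),
        )
    return AnalysisConfig(**raw)


def config_echo(cfg: AnalysisConfig) -> str:
    d = dataclasses.asdict(cfg)
    d["grid"] = dataclasses.asdict(cfg.grid)
    d["covariates"] = {"categorical": {k: list(v) for k, v in
                                       cfg.covariates.categorical.items()},
                       "continuous": list(cfg.covariates.continuous)}
    d["parts_order"] = list(cfg.parts_order)
    return yaml.safe_dump(d, sort_keys=True)


def complete_cases(records: pd.DataFrame, cfg: AnalysisConfig) -> pd.DataFrame:
    """Rows with no missing exposure, outcome or covariate values."""
    part_cols = [c for c in ("mvpa_min", "lpa_min", "st_min", "sleep_min")]
    needed = part_cols + [OUTCOME_COLUMN, "stratum"] + list(cfg.covariates.columns)
    return records.dropna(subset=[c for c in needed if c in records]).copy()


def sensitivity_subset(records: pd.DataFrame, low: float = 420.0,
                       high: float = 540.0) -> pd.DataFrame:
    """Participants sleeping between ``low`` and ``high`` minutes, inclusive."""
    s = records[SLEEP_COLUMN]
    return records[(s >= low) & (s <= high)].copy()


def run_descriptives(records: pd.DataFrame, cfg: AnalysisConfig) -> dict[str, pd.DataFrame]:
    """Characteristics table and compositional means, per stratum and overall."""
    if records.empty:
        raise ValueError("no records to describe")
    groups = {"all": records, **{s: records[records["stratum"] == s] for s in STRATA}}

    rows = []
    for gname, g in groups.items():
        rows.append({"group": gname, "variable": "n", "level": "",
                     "value": float(len(g)), "stat": "count"})
        for name in cfg.covariates.columns:
            if name not in g:
                continue
            col = g[name]
            if name in cfg.covariates.categorical:
                for level in cfg.covariates.categorical[name]:
                    k = int((col == level).sum())
                    rows.append({"group": gname, "variable": name, "level": level,
                                 "value": k, "stat": "count"})
                    rows.append({"group": gname, "variable": name, "level": level,
                                 "value": 100.0 * k / max(len(g), 1), "stat": "pct"})
            else:
                rows.append({"group": gname, "variable": name, "level": "",
                             "value": float(col.mean()), "stat": "mean"})
                rows.append({"group": gname, "variable": name, "level": "",
                             "value": float(col.std()), "stat": "sd"})
            rows.append({"group": gname, "variable": name, "level": "",
                         "value": int(col.isna().sum()), "stat": "missing"})
        rows.append({"group": gname, "variable": OUTCOME_COLUMN, "level": "",
                     "value": float(g[OUTCOME_COLUMN].mean()), "stat": "mean"})
        rows.append({"group": gname, "variable": OUTCOME_COLUMN, "level": "",
                     "value": float(g[OUTCOME_COLUMN].std()), "stat": "sd"})
    characteristics = pd.DataFrame(rows)

    comp_rows = []
    for gname, g in groups.items():
        cm = compositional_mean(composition_matrix(g, cfg.parts_order),
                                MINUTES_PER_DAY, cfg.parts_order)
        for b, v in cm.as_dict().items():
            comp_rows.append({"group": gname, "behaviour": b,
                              "minutes": v, "pct_of_day": 100.0 * v / MINUTES_PER_DAY})
    return {"characteristics": characteristics,
            "compositional_means": pd.DataFrame(comp_rows)}


def run_group_contrasts(records: pd.DataFrame, cfg: AnalysisConfig) -> pd.DataFrame:
    """Urban-vs-rural bootstrap log-ratio contrasts for all four behaviours.

    Urban is the numerator: positive values mean urban residents spend
    relatively more of the day in that behaviour.
    """
    urban = composition_matrix(records[records["stratum"] == "urban"], cfg.parts_order)
    rural = composition_matrix(records[records["stratum"] == "rural"], cfg.parts_order)
    rows = []
    for b in cfg.parts_order:
        c = bootstrap_contrast(
            urban, rural, b, n_replicates=cfg.bootstrap_replicates,
            level=cfg.level, seed=contrast_seed(cfg.seed, b), names=cfg.parts_order)
        rows.append({"behaviour": b, "estimate": c.estimate, "ci_low": c.ci_low,
                     "ci_high": c.ci_high, "n_replicates": c.n_replicates,
                     "significant": not (c.ci_low <= 0.0 <= c.ci_high)})
    return pd.DataFrame(rows)


def _stratum_frames(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    return {"all": records,
            **{s: records[records["stratum"] == s] for s in STRATA}}


def run_regressions(records: pd.DataFrame, cfg: AnalysisConfig) -> pd.DataFrame:
    tables = []
    for gname, g in _stratum_frames(records).items():
        tables.append(effects_table(g, cfg.covariates, cfg.parts_order)
                      .assign(stratum=gname))
    out = pd.concat(tables, ignore_index=True)
    return out[["stratum", "behaviour", "beta", "ci_low", "ci_high", "p",
                "model_r2", "model_p", "n"]]


def run_reallocations(records: pd.DataFrame, cfg: AnalysisConfig) -> pd.DataFrame:
    """Reallocation grid per stratum, evaluated at the stratum compositional
    mean with the baseline outcome predicted there (covariates at their
    sample means, which for OLS equals the observed mean outcome)."""
    frames = []
    for gname, g in _stratum_frames(records).items():
        fit = fit_ilr_model(g, cfg.parts_order, cfg.covariates)
        m = compositional_mean(composition_matrix(g, cfg.parts_order),
                               MINUTES_PER_DAY, cfg.parts_order)
        baseline = float(g[OUTCOME_COLUMN].mean())
        grid = reallocation_grid(fit, m, baseline, cfg.grid, stratum=gname,
                                 level=cfg.level)
        frames.append(grid_frame(grid))
    return pd.concat(frames, ignore_index=True)


def run_shape_test(records: pd.DataFrame) -> TwoLinesResult:
    return two_lines_test(records[SLEEP_COLUMN].to_numpy(),
                          records[OUTCOME_COLUMN].to_numpy())


@dataclass
class AnalysisResults:
    descriptives: dict[str, pd.DataFrame]
    contrasts: pd.DataFrame
    regressions: pd.DataFrame
    reallocations: pd.DataFrame
    sensitivity_regressions: pd.DataFrame
    sensitivity_reallocations: pd.DataFrame
    two_lines: TwoLinesResult
    n_by_stratum: dict[str, int]
    config_text: str


def run_full_analysis(cfg: AnalysisConfig,
                      records: pd.DataFrame | None = None) -> AnalysisResults:
    """Run the whole study on a cohort table (loaded from cfg.input_path if
    not passed) and return the results bundle."""
    if records is None:
        if cfg.input_path is None:
            raise ValueError("no input: pass records or set input_path")
        records = pd.read_csv(cfg.input_path)
    cc = complete_cases(records, cfg)
    sens = sensitivity_subset(cc, cfg.sleep_low_min, cfg.sleep_high_min)
    return AnalysisResults(
        descriptives=run_descriptives(cc, cfg),
        contrasts=run_group_contrasts(cc, cfg),
        regressions=run_regressions(cc, cfg),
        reallocations=run_reallocations(cc, cfg),
        sensitivity_regressions=run_regressions(sens, cfg),
        sensitivity_reallocations=run_reallocations(sens, cfg),
        two_lines=run_shape_test(cc),
        n_by_stratum={"all": len(cc),
                      **{s: int((cc["stratum"] == s).sum()) for s in STRATA}},
        config_text=config_echo(cfg),
    )


def write_results(res: AnalysisResults, outdir) -> list[Path]:
    """Write the bundle as delimited text + JSON; deterministic byte-for-byte
    given identical inputs (fixed float formatting, no timestamps)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def csv(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False, float_format=_FLOAT_FMT)
        written.append(p)

    csv(res.descriptives["characteristics"], "characteristics.csv")
    csv(res.descriptives["compositional_means"], "compositional_means.csv")
    csv(res.contrasts, "group_contrasts.csv")
    csv(res.regressions, "regression_effects.csv")
    csv(res.reallocations, "reallocation_grid.csv")
    csv(res.sensitivity_regressions, "sensitivity_regression_effects.csv")
    csv(res.sensitivity_reallocations, "sensitivity_reallocation_grid.csv")

    p = out / "two_lines.json"
    p.write_text(json.dumps(res.two_lines.as_dict(), indent=2, sort_keys=True) + "\n")
    written.append(p)

    p = out / "config.yaml"
    p.write_text(res.config_text)
    written.append(p)

    log = out / "run_log.txt"
    cfg_hash = hashlib.sha256(res.config_text.encode()).hexdigest()[:16]
    log.write_text(
        f"coda24 version: {__version__}\n"
        f"config sha256: {cfg_hash}\n"
        f"n (complete cases): {res.n_by_stratum}\n"
    )
    written.append(log)
    return written
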