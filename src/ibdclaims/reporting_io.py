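"""Publication-shaped outputs and the end-to-end pipeline.

Assembles the incident-case count table (counts with column percentages by
sex, age group and disease), the annual ASR table, the trend table, and tidy
figure data series; provides CSV readers for the pipeline inputs; and
orchestrates ascertainment -> rates -> trends into an output directory with
a reproducibility manifest.

Rendered tables round half-up to one decimal (matching the conventional
presentation); machine-readable CSVs keep full precision.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .age_groups import AgeGrouping
from .case_ascertainment import ascertain_cases, write_cases
from .config import PipelineConfig
from .errors import ConfigurationError, CoverageError, IbdClaimsError
from .incidence_estimation import (
    build_rate_tables,
    cd_uc_ratio_by_age,
    regroup_population,
    tabulate_cases,
)
from .standards import canada_2006_weights, load_standard_csv
from .trend_model import run_trend_suite, trend_summary

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- rounding

def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero at ``ndigits`` decimals (0.25 -> 0.3)."""
    if not np.isfinite(x):
        return float(x)
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def share_percent(count: float, total: float, ndigits: int = 1) -> float:
    """Column percentage ``100 * count / total`` rounded half-up."""
    if total == 0:
        return float("nan")
    return round_half_up(100.0 * count / total, ndigits)


# ---------------------------------------------------------------- readers

def _require(path: Path, what: str) -> Path:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"{what} file not found: {path}")
    return path


def read_registry(path) -> pd.DataFrame:
    df = pd.read_csv(_require(path, "registry"), parse_dates=["birth_date", "cover_start", "cover_end"])
    missing = {"person_id", "sex", "birth_date", "cover_start", "cover_end"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"registry {path} missing columns {sorted(missing)}")
    return df


def read_encounters(path) -> pd.DataFrame:
    """Read the encounter stream.

    One row is one dated contact carrying one diagnosis code; multi-code
    discharge abstracts must be exploded into one row per code upstream.
    """
    df = pd.read_csv(_require(path, "encounters"), parse_dates=["date"])
    missing = {"person_id", "date", "source", "icd_version", "code"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"encounters {path} missing columns {sorted(missing)}")
    return df


def read_population(path) -> pd.DataFrame:
    df = pd.read_csv(_require(path, "population"))
    missing = {"year", "age_group", "sex", "count"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"population {path} missing columns {sorted(missing)}")
    return df


def read_cases(path) -> pd.DataFrame:
    return pd.read_csv(_require(path, "cases"), parse_dates=["diagnosis_date"])


# ---------------------------------------------------------------- tables

def build_table2(cases: pd.DataFrame, registry: pd.DataFrame, grouping: AgeGrouping) -> pd.DataFrame:
    """Incident-case counts and column percentages by sex, age group, disease.

    Long format: sex, age_group (bins plus an ``All`` row), disease, n,
    percent.  Percentages are per (sex, disease) column and sum to 100
    within rounding.
    """
    years = sorted(cases["diagnosis_year"].unique()) if len(cases) else []
    cube = tabulate_cases(cases, registry, grouping, years=years)
    counts = cube.groupby(["sex", "age_group", "disease"], as_index=False)["count"].sum()
    rows = []
    for (sex, disease), g in counts.groupby(["sex", "disease"]):
        g = g.set_index("age_group")["count"].reindex(list(grouping.labels), fill_value=0)
        total = int(g.sum())
        for age_group, n in g.items():
            rows.append(
                {
                    "sex": sex,
                    "age_group": age_group,
                    "disease": disease,
                    "n": int(n),
                    "percent": share_percent(n, total),
                }
            )
        rows.append({"sex": sex, "age_group": "All", "disease": disease, "n": total,
                     "percent": 100.0 if total else float("nan")})
    return pd.DataFrame(rows)


def build_table3(rate_table: pd.DataFrame) -> pd.DataFrame:
    """Annual ASRs, one row per year, columns (sex, disease), one decimal.

    Rows ascend by year; a missing (year, sex, disease) ASR cell is a
    coverage error.
    """
    asr = rate_table[(rate_table["age_group"] == "ALL") & rate_table["disease"].isin(["CD", "UC", "IBDU"])]
    wide = asr.pivot(index="year", columns=["sex", "disease"], values="rate")
    years = sorted(wide.index)
    gaps = sorted(set(range(years[0], years[-1] + 1)) - set(years)) if years else []
    if gaps:
        raise CoverageError(f"build_table3: missing years {gaps}")
    cols = pd.MultiIndex.from_product([["female", "male", "both"], ["CD", "UC", "IBDU"]])
    missing = [c for c in cols if c not in wide.columns]
    if missing or wide.isna().any().any():
        raise CoverageError(f"build_table3: missing ASR cells {missing or 'NaN entries'}")
    wide = wide.reindex(columns=cols).sort_index()
    return wide.map(round_half_up)


def build_figure_series(
    rate_table: pd.DataFrame, ratio_table: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Tidy data series behind the three standard figures.

    ``asr_by_year``: sexes-combined ASR per year for CD/UC/IBDU/IBD (the IBD
    series standardizes summed counts; with shared weights this equals the
    sum of the component ASRs).  ``age_specific_rates``: sexes-combined
    crude rates per year and age bin per disease.  ``cd_uc_ratio``: CD:UC
    case ratio per age bin and sex.
    """
    fig1 = rate_table[(rate_table["age_group"] == "ALL") & (rate_table["sex"] == "both")][
        ["year", "disease", "rate"]
    ].reset_index(drop=True)
    fig2 = rate_table[(rate_table["age_group"] != "ALL") & (rate_table["sex"] == "both")][
        ["year", "age_group", "disease", "cases", "denominator", "rate"]
    ].reset_index(drop=True)
    return {"asr_by_year": fig1, "age_specific_rates": fig2, "cd_uc_ratio": ratio_table}


# ---------------------------------------------------------------- pipeline

def _config_digest(config: PipelineConfig) -> str:
    blob = json.dumps({k: str(v) for k, v in asdict(config).items()}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def _file_digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """End-to-end run: ascertain, tabulate, standardize, fit trends, write outputs.

    Writes cases.csv, rates.csv, table2.csv, table3.csv, trend.csv,
    figure_data/*.csv, run.log and run_manifest.json to ``config.out_dir``.
    Deterministic given identical inputs; a ``.partial`` marker is present
    while the run is incomplete and removed on success.  Stage errors are
    re-raised annotated with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "figure_data").mkdir(exist_ok=True)
    marker = out / ".partial"
    marker.touch()

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("ibdclaims")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))

    stage = "read inputs"
    try:
        registry = read_registry(config.registry)
        encounters = read_encounters(config.encounters)
        population = read_population(config.population)
        if config.standard is None:
            std = canada_2006_weights(config.table_grouping)
        else:
            std = load_standard_csv(config.standard, config.table_grouping)

        study_years = list(range(config.study_span[0], config.study_span[1] + 1))
        reference_year = config.reference_year or config.study_span[0]
        final_year = config.final_year or config.study_span[1]

        stage = "case ascertainment"
        cases = ascertain_cases(
            registry,
            encounters,
            gate=config.gate,
            weights=config.weights,
            washout_span=config.washout_span,
            study_span=config.study_span,
            classification_window_days=config.classification_window_days,
        )
        logger.info("ascertained %d incident cases", len(cases))
        write_cases(out / "cases.csv", cases)

        stage = "incidence estimation"
        pop_study = population[population["year"].isin(study_years)]
        cube = tabulate_cases(cases, registry, config.table_grouping, years=study_years)
        rate_table = build_rate_tables(cube, pop_study, std, config.table_grouping)
        rate_table.to_csv(out / "rates.csv", index=False)

        stage = "report tables"
        table2 = build_table2(cases, registry, config.table_grouping)
        table2.to_csv(out / "table2.csv", index=False)
        table3 = build_table3(rate_table)
        table3.to_csv(out / "table3.csv")

        stage = "trend model"
        trend_cube = tabulate_cases(cases, registry, config.trend_grouping, years=study_years)
        trend_pop = regroup_population(pop_study, config.table_grouping, config.trend_grouping)
        trend = run_trend_suite(trend_cube, trend_pop, reference_year)
        trend.to_csv(out / "trend_by_year.csv", index=False)
        summary = trend_summary(trend, final_year)
        summary["label"] = [
            f"{round_half_up(p)} ({round_half_up(lo)}, {round_half_up(hi)})" if e else "n/e"
            for p, lo, hi, e in zip(
                summary["percent_change"], summary["ci_low"], summary["ci_high"], summary["estimable"]
            )
        ]
        summary.to_csv(out / "trend.csv", index=False)

        stage = "figure data"
        ratio = cd_uc_ratio_by_age(cases, registry, config.table_grouping)
        for name, df in build_figure_series(rate_table, ratio).items():
            df.to_csv(out / "figure_data" / f"{name}.csv", index=False)

        stage = "manifest"
        manifest = {
            "package": "ibdclaims",
            "version": __version__,
            "config_sha256": _config_digest(config),
            "inputs": {
                name: _file_digest(getattr(config, name))
                for name in ("registry", "encounters", "population")
            },
            "study_span": list(config.study_span),
            "washout_span": list(config.washout_span),
            "reference_year": reference_year,
            "final_year": final_year,
            "n_cases": int(len(cases)),
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except IbdClaimsError as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()

    marker.unlink()
    return out
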