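"""Crude and directly age-standardized incidence rates per 100,000.

Case records and annual population denominators are cross-tabulated into a
complete (year x age-group x sex x disease) cube; age-specific crude rates
are ``100000 * cases / population`` and the direct age-standardized rate
(ASR) is the weighted average of age-specific rates under a fixed standard
population's age weights.  Sexes-combined ASRs standardize pooled-sex
age-specific rates with the same weights.  Age at diagnosis is calendar-year
age (diagnosis year minus birth year), consistent with annual denominators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .age_groups import AgeGrouping, regroup_map
from .errors import CoverageError, DataError, UndefinedRateError

CATEGORIES = ("CD", "UC", "IBDU")
SEX_LEVELS = ("female", "male", "both")


def tabulate_cases(
    cases: pd.DataFrame,
    registry: pd.DataFrame,
    grouping: AgeGrouping,
    years: list[int] | None = None,
) -> pd.DataFrame:
    """Complete zero-filled counts cube by (year, age_group, sex, disease).

    ``years`` defaults to the span of diagnosis years present; passing it
    explicitly guarantees a complete study-span cube even when some years
    have no cases.
    """
    missing = set(cases["person_id"]) - set(registry["person_id"])
    if missing:
        raise DataError(f"tabulate_cases: case persons missing from registry (e.g. {sorted(missing)[:3]})")
    if years is None:
        years = sorted(cases["diagnosis_year"].unique()) if len(cases) else []

    merged = cases.merge(registry[["person_id", "sex", "birth_date"]], on="person_id", validate="one_to_one")
    if len(merged):
        age = merged["diagnosis_year"].to_numpy() - pd.to_datetime(merged["birth_date"]).dt.year.to_numpy()
        merged["age_group"] = grouping.label_of(np.clip(age, 0, None))

    index = pd.MultiIndex.from_product(
        [years, list(grouping.labels), ["female", "male"], list(CATEGORIES)],
        names=["year", "age_group", "sex", "disease"],
    )
    if len(merged):
        counts = (
            merged.groupby(["diagnosis_year", "age_group", "sex", "category"], observed=True)
            .size()
            .rename_axis(["year", "age_group", "sex", "disease"])
        )
        cube = counts.reindex(index, fill_value=0)
    else:
        cube = pd.Series(0, index=index, dtype="int64")
    return cube.rename("count").reset_index()


def add_ibd_total(cube: pd.DataFrame) -> pd.DataFrame:
    """Append rows with disease ``IBD`` = CD + UC + IBDU per cell."""
    keys = [c for c in cube.columns if c not in ("disease", "count")]
    total = cube.groupby(keys, as_index=False)["count"].sum()
    total["disease"] = "IBD"
    return pd.concat([cube, total[cube.columns]], ignore_index=True)


def crude_rate(cases: float, population: float) -> float:
    """Cases per 100,000 population; 0/0 is 0, cases against zero denominator is an error."""
    if population <= 0:
        if cases > 0:
            raise UndefinedRateError(f"{cases} cases against population {population}")
        return 0.0
    return 1e5 * cases / population


def age_standardize(age_specific_rates: pd.Series, std_weights: pd.Series) -> float:
    """Directly standardized rate: dot product of rates with standard age weights.

    Every age group carrying positive weight must have a rate (an explicit
    zero counts); otherwise a :class:`CoverageError` is raised.
    """
    positive = std_weights[std_weights > 0]
    missing = set(positive.index) - set(age_specific_rates.dropna().index)
    if missing:
        raise CoverageError(f"age_standardize: no rate for weighted age groups {sorted(missing)}")
    rates = age_specific_rates.reindex(positive.index)
    return float((rates * positive).sum())


def _pool_sex(df: pd.DataFrame) -> pd.DataFrame:
    keys = [c for c in df.columns if c not in ("sex", "count")]
    pooled = df.groupby(keys, as_index=False)["count"].sum()
    pooled["sex"] = "both"
    return pd.concat([df, pooled[df.columns]], ignore_index=True)


def build_rate_tables(
    cube: pd.DataFrame,
    population: pd.DataFrame,
    std_weights: pd.Series,
    grouping: AgeGrouping,
) -> pd.DataFrame:
    """Long-format rate table: age-specific crude rates plus per-year ASRs.

    Output columns: year, age_group (bin label or ``ALL`` for the ASR rows),
    sex (female/male/both), disease (CD/UC/IBDU/IBD), cases, denominator,
    rate (per 100,000), undefined (True where an empty denominator met zero
    cases and the rate was set to 0).

    The ASR for a (year, sex, disease) stratum standardizes that stratum's
    age-specific rates by ``std_weights``; the IBD rows use summed CD+UC+IBDU
    counts, which under shared weights equals the sum of the component ASRs.
    """
    cube = add_ibd_total(_pool_sex(cube))
    pop = _pool_sex(population).rename(columns={"count": "denominator"})

    merged = cube.merge(pop, on=["year", "age_group", "sex"], how="left", validate="many_to_one")
    if merged["denominator"].isna().any():
        bad = merged[merged["denominator"].isna()][["year", "age_group", "sex"]].iloc[0].tolist()
        raise CoverageError(f"build_rate_tables: population cell missing for {bad}")
    merged["undefined"] = merged["denominator"] <= 0
    if ((merged["undefined"]) & (merged["count"] > 0)).any():
        bad = merged[(merged["undefined"]) & (merged["count"] > 0)].iloc[0]
        raise UndefinedRateError(
            f"cases with zero population in cell {(bad['year'], bad['age_group'], bad['sex'], bad['disease'])}"
        )
    merged["rate"] = np.where(merged["undefined"], 0.0, 1e5 * merged["count"] / merged["denominator"].where(merged["denominator"] > 0))

    age_specific = merged.rename(columns={"count": "cases"})[
        ["year", "age_group", "sex", "disease", "cases", "denominator", "rate", "undefined"]
    ]

    asr_rows = []
    for (year, sex, disease), g in age_specific.groupby(["year", "sex", "disease"]):
        rates = g.set_index("age_group")["rate"]
        asr = age_standardize(rates.reindex(list(grouping.labels)), std_weights)
        asr_rows.append(
            {
                "year": year,
                "age_group": "ALL",
                "sex": sex,
                "disease": disease,
                "cases": int(g["cases"].sum()),
                "denominator": float(g["denominator"].sum()),
                "rate": asr,
                "undefined": bool(g["undefined"].any()),
            }
        )
    out = pd.concat([age_specific, pd.DataFrame(asr_rows)], ignore_index=True)
    return out.sort_values(["disease", "sex", "year", "age_group"], kind="mergesort").reset_index(drop=True)


def regroup_population(population: pd.DataFrame, fine: AgeGrouping, coarse: AgeGrouping) -> pd.DataFrame:
    """Aggregate a population table from fine bins to coarse bins (must nest)."""
    mapping = regroup_map(fine, coarse)
    out = population.copy()
    out["age_group"] = out["age_group"].map(mapping)
    if out["age_group"].isna().any():
        raise CoverageError("regroup_population: population has age groups outside the fine grouping")
    return out.groupby(["year", "age_group", "sex"], as_index=False)["count"].sum()


def cd_uc_ratio_by_age(
    cases: pd.DataFrame, registry: pd.DataFrame, grouping: AgeGrouping
) -> pd.DataFrame:
    """Ratio of CD to UC incident counts per (age_group, sex incl. pooled).

    Within a cell the population denominator cancels, so the count ratio is
    the rate ratio.  Cells with zero UC cases get a NaN ratio and an
    ``undefined`` flag rather than an error.
    """
    years = sorted(cases["diagnosis_year"].unique()) if len(cases) else []
    cube = _pool_sex(tabulate_cases(cases, registry, grouping, years=years))
    wide = (
        cube[cube["disease"].isin(["CD", "UC"])]
        .groupby(["age_group", "sex", "disease"], as_index=False)["count"]
        .sum()
        .pivot(index=["age_group", "sex"], columns="disease", values="count")
        .reindex(columns=["CD", "UC"], fill_value=0)
        .reindex(
            pd.MultiIndex.from_product([list(grouping.labels), list(SEX_LEVELS)], names=["age_group", "sex"]),
            fill_value=0,
        )
        .reset_index()
    )
    wide["undefined"] = wide["UC"] == 0
    wide["ratio"] = np.where(wide["undefined"], np.nan, wide["CD"] / wide["UC"].replace(0, np.nan))
    return wide.rename(columns={"CD": "cd_cases", "UC": "uc_cases"})[
        ["age_group", "sex", "cd_cases", "uc_cases", "ratio", "undefined"]
    ]
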