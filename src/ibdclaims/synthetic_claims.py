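"""Synthetic administrative-claims cohort with known ground truth.

Emulates a single-payer provincial claims environment: a person registry with
universal coverage, annual population denominators, and two ICD-coded event
streams (outpatient physician claims and hospital discharge abstracts).
Disease onsets follow configurable age/sex-specific incidence with a
multiplicative calendar-year trend; post-onset care contact is a Poisson
claims process plus Bernoulli hospitalizations per calendar year, with
optional diagnostic-code noise that produces mixed CD/UC coding (the raw
material for undifferentiated IBD labels downstream).

Everything is deterministic given ``SimulationConfig.seed``; the three stages
draw from independent child streams of that seed so each stage is
individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from numbers import Real
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .age_groups import AgeGrouping
from .config import DISEASES, SimulationConfig
from .errors import ConfigurationError, DataError

SEXES = ("female", "male")
_OPEN_TOP_SPAN = 15  # ages in the open-ended top bin are drawn uniformly over this many years

_CODE_VARIANTS: dict[tuple[str, int], tuple[str, ...]] = {
    ("CD", 9): ("555.0", "555.1", "555.2", "555.9"),
    ("UC", 9): ("556.0", "556.5", "556.6", "556.9"),
    ("CD", 10): ("K50.0", "K50.1", "K50.9"),
    ("UC", 10): ("K51.0", "K51.5", "K51.9"),
}
_BACKGROUND_CODES: dict[int, tuple[str, ...]] = {
    9: ("250.0", "401.9", "493.9", "780.9"),
    10: ("E11.9", "I10", "J45.9", "R53"),
}


def _jan1(years) -> np.ndarray:
    y = np.asarray(years, dtype="int64")
    return (y - 1970).astype("M8[Y]").astype("M8[D]")


def _dec31(years) -> np.ndarray:
    return _jan1(np.asarray(years, dtype="int64") + 1) - np.timedelta64(1, "D")


def _uniform_dates(rng: np.random.Generator, start: np.ndarray, end: np.ndarray) -> np.ndarray:
    """Uniform dates in the inclusive interval [start, end], elementwise."""
    span = (end - start).astype("timedelta64[D]").astype("int64") + 1
    offs = np.floor(rng.random(len(span)) * span).astype("int64")
    return start + offs.astype("timedelta64[D]")


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


def _resolve_surface(value, grouping: AgeGrouping, what: str) -> np.ndarray:
    """Expand a rate spec to a (sex, age-bin) array, rows ordered (female, male)."""
    out = np.zeros((2, grouping.n_bins))
    if isinstance(value, Real):
        out[:] = float(value)
    elif isinstance(value, Mapping) and set(value) <= set(SEXES):
        if set(value) != set(SEXES):
            raise ConfigurationError(f"{what}: sex-specific rates must cover both sexes")
        for i, sex in enumerate(SEXES):
            out[i] = _resolve_surface(value[sex], grouping, f"{what}[{sex}]")[i]
    elif isinstance(value, Mapping):
        unknown = set(value) - set(grouping.labels)
        missing = set(grouping.labels) - set(value)
        if unknown or missing:
            raise ConfigurationError(
                f"{what}: age-group keys must match {list(grouping.labels)}; "
                f"unknown {sorted(unknown)}, missing {sorted(missing)}"
            )
        out[:] = np.array([float(value[lab]) for lab in grouping.labels])
    else:
        raise ConfigurationError(f"{what}: expected number or mapping, got {type(value).__name__}")
    if (out < 0).any():
        raise ConfigurationError(f"{what}: rates must be non-negative")
    return out


@dataclass(frozen=True)
class SimulatedCohort:
    persons: pd.DataFrame
    truths: pd.DataFrame
    encounters: pd.DataFrame
    population: pd.DataFrame


def simulate_registry(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the person registry and its annual population denominators.

    The baseline cohort of ``n_persons`` is aged according to
    ``age_distribution`` at the first calendar year; if ``replenish_births``
    is set, newborn cohorts enter in every later year at the rate implied by
    the density of the youngest bin, so no age group empties as the cohort
    ages.  Everyone is covered from max(birth, span start) to the span end.
    """
    grouping = config.age_grouping()
    rng = _rng(config, 0)
    first, last = config.calendar_span

    weights = np.array([config.age_distribution[lab] for lab in grouping.labels], dtype=float)
    lowers = np.array(grouping.lowers)
    uppers = np.append(lowers[1:], lowers[-1] + _OPEN_TOP_SPAN)

    n0 = int(config.n_persons)
    if n0 > 0:
        bins = rng.choice(grouping.n_bins, size=n0, p=weights)
        ages = lowers[bins] + np.floor(rng.random(n0) * (uppers - lowers)[bins]).astype("int64")
        birth_year = first - ages
    else:
        birth_year = np.empty(0, dtype="int64")

    if config.replenish_births and n0 > 0 and last > first:
        density0 = weights[0] / (uppers[0] - lowers[0])
        newborn_counts = rng.poisson(n0 * density0, size=last - first)
        newborn_years = np.repeat(np.arange(first + 1, last + 1), newborn_counts)
        birth_year = np.concatenate([birth_year, newborn_years])

    n = len(birth_year)
    sex = np.where(rng.random(n) < config.sex_ratio, "female", "male")
    birth_date = _uniform_dates(rng, _jan1(birth_year), _dec31(birth_year))
    cover_start = np.maximum(birth_date, _jan1([first])[0])
    cover_end = np.full(n, _dec31([last])[0])

    persons = pd.DataFrame(
        {
            "person_id": np.arange(n, dtype="int64"),
            "sex": sex,
            "birth_date": birth_date,
            "cover_start": cover_start,
            "cover_end": cover_end,
        }
    )
    population = population_from_registry(persons, grouping, range(first, last + 1))
    return persons, population


def population_from_registry(
    persons: pd.DataFrame, grouping: AgeGrouping, years: Iterable[int]
) -> pd.DataFrame:
    """Annual person counts by (year, age_group, sex), zero-filled and complete.

    Each person counts in every year their coverage interval touches, at their
    calendar-year age (year minus birth year).
    """
    years = list(years)
    birth_year = pd.to_datetime(persons["birth_date"]).dt.year.to_numpy() if len(persons) else np.empty(0, "int64")
    start_year = pd.to_datetime(persons["cover_start"]).dt.year.to_numpy() if len(persons) else np.empty(0, "int64")
    end_year = pd.to_datetime(persons["cover_end"]).dt.year.to_numpy() if len(persons) else np.empty(0, "int64")
    sex_idx = (persons["sex"].to_numpy() == "male").astype("int64") if len(persons) else np.empty(0, "int64")

    blocks = []
    for y in years:
        counts = np.zeros((grouping.n_bins, 2), dtype="int64")
        alive = (start_year <= y) & (y <= end_year) & (birth_year <= y)
        if alive.any():
            gi = grouping.index_of(y - birth_year[alive])
            np.add.at(counts, (gi, sex_idx[alive]), 1)
        blocks.append(
            pd.DataFrame(
                {
                    "year": y,
                    "age_group": np.repeat(list(grouping.labels), 2),
                    "sex": list(SEXES) * grouping.n_bins,
                    "count": counts.ravel(),
                }
            )
        )
    return pd.concat(blocks, ignore_index=True)


def simulate_disease_onsets(persons: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Assign at most one disease per person with a per-year incidence hazard.

    In calendar year ``y`` a disease-free person of age ``a`` and sex ``s``
    acquires disease ``d`` with probability
    ``baseline_incidence[d][s, a]/100000 * annual_trend[d]**(y - first_year)``.
    The onset date is uniform within the onset year (clamped to birth).
    """
    grouping = config.age_grouping()
    rng = _rng(config, 1)
    first, last = config.calendar_span
    surfaces = {
        d: _resolve_surface(config.baseline_incidence[d], grouping, f"baseline_incidence[{d}]")
        for d in DISEASES
    }

    n = len(persons)
    birth_date = pd.to_datetime(persons["birth_date"]).to_numpy().astype("M8[D]")
    birth_year = birth_date.astype("M8[Y]").astype("int64") + 1970
    sex_idx = (persons["sex"].to_numpy() == "male").astype("int64")

    disease = np.full(n, "none", dtype=object)
    onset_year = np.full(n, -1, dtype="int64")
    free = np.ones(n, dtype=bool)
    for y in range(first, last + 1):
        ages = y - birth_year
        at_risk = free & (ages >= 0)
        gi = grouping.index_of(np.clip(ages, 0, None))
        t = y - first
        p_cd = surfaces["CD"][sex_idx, gi] / 1e5 * config.annual_trend["CD"] ** t
        p_uc = surfaces["UC"][sex_idx, gi] / 1e5 * config.annual_trend["UC"] ** t
        u = rng.random(n)
        hit_cd = at_risk & (u < p_cd)
        hit_uc = at_risk & ~hit_cd & (u < np.minimum(p_cd + p_uc, 1.0))
        disease[hit_cd] = "CD"
        disease[hit_uc] = "UC"
        hit = hit_cd | hit_uc
        onset_year[hit] = y
        free &= ~hit

    sick = onset_year >= 0
    onset_date = np.full(n, np.datetime64("NaT", "D"))
    if sick.any():
        starts = np.maximum(_jan1(onset_year[sick]), birth_date[sick])
        onset_date[sick] = _uniform_dates(rng, starts, _dec31(onset_year[sick]))

    return pd.DataFrame(
        {
            "person_id": persons["person_id"].to_numpy(),
            "true_disease": disease,
            "true_onset_date": onset_date,
        }
    )


def _expand_person_years(pids, start_years, last_year):
    """Person-year grid from each start year through ``last_year``."""
    lengths = last_year - start_years + 1
    total = int(lengths.sum())
    pid_py = np.repeat(pids, lengths)
    base = np.repeat(np.cumsum(lengths) - lengths, lengths)
    year_py = np.arange(total) - base + np.repeat(start_years, lengths)
    return pid_py, year_py, lengths


def _emit_codes(rng, disease, dates, transition_year):
    years = dates.astype("M8[Y]").astype("int64") + 1970
    version = np.where(years >= transition_year, 10, 9)
    codes = np.empty(len(dates), dtype=object)
    for d in DISEASES:
        for v in (9, 10):
            mask = (disease == d) & (version == v)
            if mask.any():
                opts = np.array(_CODE_VARIANTS[(d, v)], dtype=object)
                codes[mask] = opts[rng.integers(0, len(opts), mask.sum())]
    return version, codes


def simulate_encounters(
    persons: pd.DataFrame, truths: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """ICD-coded physician claims and hospital discharges for the cohort.

    Post-onset persons emit Poisson(``claims_per_year_post_onset``) claims and
    a Bernoulli(``hospitalization_prob_per_year``) discharge in each calendar
    year from onset through the end of coverage, dated uniformly in the
    post-onset part of the year and coded for their true disease — flipped to
    the other disease's code with probability ``code_noise_prob``.  All
    persons additionally emit Poisson(``background_encounter_rate``) non-IBD
    claims per covered year.  ICD-9 codes are used for encounter dates before
    ``icd10_transition_year``, ICD-10 from that year on.
    """
    if not set(truths["person_id"]) <= set(persons["person_id"]):
        raise DataError("simulate_encounters: truths refer to persons absent from the registry")
    rng = _rng(config, 2)
    first, last = config.calendar_span
    frames: list[pd.DataFrame] = []

    sick = truths[truths["true_disease"].isin(DISEASES)].merge(
        persons[["person_id", "birth_date"]], on="person_id", validate="one_to_one"
    )
    if len(sick):
        pids = sick["person_id"].to_numpy()
        onset_date = pd.to_datetime(sick["true_onset_date"]).to_numpy().astype("M8[D]")
        onset_year = onset_date.astype("M8[Y]").astype("int64") + 1970
        true_dis = sick["true_disease"].to_numpy(dtype=object)

        pid_py, year_py, lengths = _expand_person_years(pids, onset_year, last)
        dis_py = np.repeat(true_dis, lengths)
        win_start = np.maximum(_jan1(year_py), np.repeat(onset_date, lengths))
        win_end = _dec31(year_py)

        n_claims = rng.poisson(config.claims_per_year_post_onset, len(pid_py))
        has_disch = rng.random(len(pid_py)) < config.hospitalization_prob_per_year

        for source, reps in (("claim", n_claims), ("discharge", has_disch.astype("int64"))):
            m = int(reps.sum())
            if m == 0:
                continue
            dates = _uniform_dates(rng, np.repeat(win_start, reps), np.repeat(win_end, reps))
            dis = np.repeat(dis_py, reps)
            flip = rng.random(m) < config.code_noise_prob
            emitted = np.where(flip, np.where(dis == "CD", "UC", "CD"), dis)
            version, codes = _emit_codes(rng, emitted, dates, config.icd10_transition_year)
            frames.append(
                pd.DataFrame(
                    {
                        "person_id": np.repeat(pid_py, reps),
                        "date": dates,
                        "source": source,
                        "icd_version": version,
                        "code": codes,
                    }
                )
            )

    if config.background_encounter_rate > 0 and len(persons):
        all_pids = persons["person_id"].to_numpy()
        bdate = pd.to_datetime(persons["birth_date"]).to_numpy().astype("M8[D]")
        byear = bdate.astype("M8[Y]").astype("int64") + 1970
        for y in range(first, last + 1):
            alive = byear <= y
            if not alive.any():
                continue
            counts = rng.poisson(config.background_encounter_rate, int(alive.sum()))
            m = int(counts.sum())
            if m == 0:
                continue
            starts = np.repeat(np.maximum(bdate[alive], _jan1([y])[0]), counts)
            dates = _uniform_dates(rng, starts, np.repeat(_dec31([y])[0], m))
            version = np.where(y >= config.icd10_transition_year, 10, 9)
            opts = np.array(_BACKGROUND_CODES[10 if y >= config.icd10_transition_year else 9], dtype=object)
            frames.append(
                pd.DataFrame(
                    {
                        "person_id": np.repeat(all_pids[alive], counts),
                        "date": dates,
                        "source": "claim",
                        "icd_version": np.broadcast_to(version, m).copy(),
                        "code": opts[rng.integers(0, len(opts), m)],
                    }
                )
            )

    if not frames:
        return pd.DataFrame(
            {
                "person_id": pd.Series(dtype="int64"),
                "date": pd.Series(dtype="datetime64[s]"),
                "source": pd.Series(dtype=object),
                "icd_version": pd.Series(dtype="int64"),
                "code": pd.Series(dtype=object),
            }
        )
    out = pd.concat(frames, ignore_index=True)
    out["icd_version"] = out["icd_version"].astype("int64")
    out = out.sort_values(
        ["person_id", "date", "source", "code"], kind="mergesort"
    ).reset_index(drop=True)
    return out


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Run all three stages: registry, onsets, encounters."""
    persons, population = simulate_registry(config)
    truths = simulate_disease_onsets(persons, config)
    encounters = simulate_encounters(persons, truths, config)
    return SimulatedCohort(persons, truths, encounters, population)


def write_cohort(out_dir: str | Path, cohort: SimulatedCohort) -> dict[str, Path]:
    """Write registry.csv, truth.csv, encounters.csv, population.csv (ISO dates)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    persons = cohort.persons.copy()
    for col in ("birth_date", "cover_start", "cover_end"):
        persons[col] = pd.to_datetime(persons[col]).dt.strftime("%Y-%m-%d")
    paths["registry"] = out / "registry.csv"
    persons.to_csv(paths["registry"], index=False)

    truths = cohort.truths.copy()
    truths["true_onset_date"] = pd.to_datetime(truths["true_onset_date"]).dt.strftime("%Y-%m-%d")
    paths["truth"] = out / "truth.csv"
    truths.to_csv(paths["truth"], index=False)

    enc = cohort.encounters.copy()
    enc["date"] = pd.to_datetime(enc["date"]).dt.strftime("%Y-%m-%d")
    paths["encounters"] = out / "encounters.csv"
    enc.to_csv(paths["encounters"], index=False)

    paths["population"] = out / "population.csv"
    cohort.population.to_csv(paths["population"], index=False)
    return paths
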