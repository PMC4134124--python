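"""Configuration objects: scoring weights, gate rule, simulation and pipeline configs.

All configs validate eagerly and raise :class:`ConfigurationError` naming the
offending field.  YAML and JSON files are both accepted (JSON is a subset of
YAML, so one loader suffices).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .age_groups import DECADE_BINS, TREND_BINS, AgeGrouping
from .errors import ConfigurationError

DISEASES = ("CD", "UC")

# Age structure loosely shaped like an eastern-Canadian province in the 1990s.
DEFAULT_AGE_DISTRIBUTION: dict[str, float] = {
    "<10": 0.120,
    "10-19": 0.135,
    "20-29": 0.140,
    "30-39": 0.160,
    "40-49": 0.150,
    "50-59": 0.120,
    "60-69": 0.095,
    "70-79": 0.055,
    "80+": 0.025,
}

# Incidence per 100,000 person-years by age group, peaked in young adulthood
# for CD and slightly older for UC; calibrated so the cohort-wide rates sit
# near the high-incidence baseline the study population is known for
# (CD ~ 27/100,000, UC ~ 21/100,000 at the start of follow-up).
DEFAULT_BASELINE_INCIDENCE: dict[str, dict[str, float]] = {
    "CD": {
        "<10": 3.0, "10-19": 28.0, "20-29": 48.0, "30-39": 42.0, "40-49": 30.0,
        "50-59": 24.0, "60-69": 17.0, "70-79": 11.0, "80+": 6.0,
    },
    "UC": {
        "<10": 2.0, "10-19": 14.0, "20-29": 28.0, "30-39": 32.0, "40-49": 30.0,
        "50-59": 26.0, "60-69": 22.0, "70-79": 15.0, "80+": 9.0,
    },
}


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass(frozen=True)
class ScoreWeights:
    """Per-encounter scores and the classification thresholds.

    Outpatient claims contribute +/-1 (UC/CD), hospital discharges +/-2; a
    cumulative score above ``uc_threshold`` labels UC, below ``cd_threshold``
    labels CD, anything in between (inclusive) is undifferentiated IBD.
    """

    claim_uc: int = 1
    claim_cd: int = -1
    discharge_uc: int = 2
    discharge_cd: int = -2
    uc_threshold: int = 2
    cd_threshold: int = -2

    def __post_init__(self) -> None:
        _check(self.cd_threshold < self.uc_threshold, "ScoreWeights: cd_threshold must be < uc_threshold")
        _check(self.claim_uc > 0 and self.discharge_uc > 0, "ScoreWeights: UC weights must be positive")
        _check(self.claim_cd < 0 and self.discharge_cd < 0, "ScoreWeights: CD weights must be negative")


@dataclass(frozen=True)
class GateRule:
    """Entry criterion: >=1 hospitalization, or >=4 claims within two years."""

    min_hospitalizations: int = 1
    min_claims: int = 4
    window_days: int = 730

    def __post_init__(self) -> None:
        for f in ("min_hospitalizations", "min_claims", "window_days"):
            _check(int(getattr(self, f)) > 0, f"GateRule: {f} must be a positive integer")


@dataclass(frozen=True)
class SimulationConfig:
    """Data-generating assumptions for the synthetic claims cohort.

    ``calendar_span`` is the full record span over which onsets and encounters
    are simulated (the washout years are part of it, so prevalent-style cases
    arise naturally).  ``baseline_incidence`` entries may be a single number
    (flat over age and sex), a mapping age-group label -> rate, or a mapping
    sex -> {age-group -> rate}; rates are per 100,000 person-years and decay
    (or grow) by ``annual_trend[disease]`` per calendar year from the start of
    the span.
    """

    seed: int = 0
    n_persons: int = 50_000
    calendar_span: tuple[int, int] = (1991, 2010)
    washout_span: tuple[int, int] = (1991, 1995)
    age_distribution: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_DISTRIBUTION)
    )
    sex_ratio: float = 0.51
    baseline_incidence: Mapping[str, Any] = field(
        default_factory=lambda: {d: dict(v) for d, v in DEFAULT_BASELINE_INCIDENCE.items()}
    )
    annual_trend: Mapping[str, float] = field(default_factory=lambda: {"CD": 0.97, "UC": 0.978})
    claims_per_year_post_onset: float = 4.0
    hospitalization_prob_per_year: float = 0.15
    code_noise_prob: float = 0.10
    icd10_transition_year: int = 2001
    background_encounter_rate: float = 2.0
    replenish_births: bool = True

    def __post_init__(self) -> None:
        _check(int(self.n_persons) >= 0, "SimulationConfig: n_persons must be >= 0")
        first, last = self.calendar_span
        _check(first <= last, "SimulationConfig: calendar_span must satisfy first_year <= last_year")
        w0, w1 = self.washout_span
        _check(w0 <= w1, "SimulationConfig: washout_span must satisfy first_year <= last_year")
        _check(w0 <= first + (last - first), "SimulationConfig: washout_span malformed")
        _check(
            w1 < last, "SimulationConfig: washout_span must precede the end of calendar_span"
        )
        _check(0.0 <= self.sex_ratio <= 1.0, "SimulationConfig: sex_ratio must be in [0,1]")
        for p in ("hospitalization_prob_per_year", "code_noise_prob"):
            _check(0.0 <= getattr(self, p) <= 1.0, f"SimulationConfig: {p} must be in [0,1]")
        for r in ("claims_per_year_post_onset", "background_encounter_rate"):
            _check(getattr(self, r) >= 0.0, f"SimulationConfig: {r} must be non-negative")
        total = sum(self.age_distribution.values())
        _check(abs(total - 1.0) <= 1e-9, "SimulationConfig: age_distribution weights must sum to 1")
        _check(all(w >= 0 for w in self.age_distribution.values()),
               "SimulationConfig: age_distribution weights must be non-negative")
        # labels must parse as a contiguous grouping
        self.age_grouping()
        for d in DISEASES:
            _check(d in self.baseline_incidence, f"SimulationConfig: baseline_incidence missing {d}")
            _check(d in self.annual_trend, f"SimulationConfig: annual_trend missing {d}")
            _check(self.annual_trend[d] > 0, f"SimulationConfig: annual_trend[{d}] must be positive")

    def age_grouping(self) -> AgeGrouping:
        return AgeGrouping.from_labels(tuple(self.age_distribution))

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class PipelineConfig:
    """Paths, spans and rule objects for an end-to-end run."""

    registry: Path
    encounters: Path
    population: Path
    out_dir: Path
    standard: Path | None = None  # None -> bundled 2006 Canadian census weights
    study_span: tuple[int, int] = (1996, 2009)
    washout_span: tuple[int, int] = (1991, 1995)
    gate: GateRule = field(default_factory=GateRule)
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    table_grouping: AgeGrouping = DECADE_BINS
    trend_grouping: AgeGrouping = TREND_BINS
    classification_window_days: int | None = 730
    reference_year: int | None = None  # None -> study_span[0]
    final_year: int | None = None  # None -> study_span[1]
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        _check(self.study_span[0] <= self.study_span[1], "PipelineConfig: study_span malformed")
        _check(self.washout_span[0] <= self.washout_span[1], "PipelineConfig: washout_span malformed")
        _check(self.washout_span[1] < self.study_span[0],
               "PipelineConfig: washout_span must precede study_span")
        if self.classification_window_days is not None:
            _check(self.classification_window_days > 0,
                   "PipelineConfig: classification_window_days must be positive or None")


def _sub(mapping: Mapping[str, Any], key: str) -> dict[str, Any]:
    value = mapping.get(key, {})
    if value is None:
        return {}
    if not isinstance(value, Mapping):
        raise ConfigurationError(f"config section {key!r} must be a mapping")
    return dict(value)


def simulation_config_from_mapping(raw: Mapping[str, Any]) -> SimulationConfig:
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"SimulationConfig: unknown fields {sorted(unknown)}")
    kwargs = dict(raw)
    for span in ("calendar_span", "washout_span"):
        if span in kwargs:
            kwargs[span] = tuple(int(v) for v in kwargs[span])
    return SimulationConfig(**kwargs)


def pipeline_config_from_mapping(raw: Mapping[str, Any], base_dir: Path | None = None) -> PipelineConfig:
    base = Path(base_dir) if base_dir else Path(".")
    kwargs: dict[str, Any] = {}
    for key in ("registry", "encounters", "population", "standard", "out_dir"):
        if raw.get(key) is not None:
            p = Path(raw[key])
            kwargs[key] = p if p.is_absolute() else base / p
    for key in ("study_span", "washout_span"):
        if key in raw:
            kwargs[key] = tuple(int(v) for v in raw[key])
    if "gate" in raw:
        kwargs["gate"] = GateRule(**_sub(raw, "gate"))
    if "weights" in raw:
        kwargs["weights"] = ScoreWeights(**_sub(raw, "weights"))
    if "table_grouping" in raw:
        kwargs["table_grouping"] = AgeGrouping.from_labels(tuple(raw["table_grouping"]))
    if "trend_grouping" in raw:
        kwargs["trend_grouping"] = AgeGrouping.from_labels(tuple(raw["trend_grouping"]))
    for key in ("classification_window_days", "reference_year", "final_year", "log_level"):
        if key in raw:
            kwargs[key] = raw[key]
    missing = {"registry", "encounters", "population", "out_dir"} - set(kwargs)
    if missing:
        raise ConfigurationError(f"PipelineConfig: missing required fields {sorted(missing)}")
    return PipelineConfig(**kwargs)


def load_config_file(path: str | Path) -> dict[str, Any]:
    """Load a YAML/JSON config file into a plain dict."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        return {}
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"config file {path} must contain a mapping at top level")
    return dict(raw)
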