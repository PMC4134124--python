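"""Log-linear Poisson trend regression with calendar year as a categorical factor.

The model for a stratum (disease x sex-level x age-level) is

    log E[count_cell] = log population_cell + intercept + beta_year
                        (+ gamma_agegroup when adjusting for age)

with the first study year (1996 in the default profile) as the reference
year level.  Fitting is by iteratively reweighted least squares (Fisher
scoring, which for the canonical log link equals Newton-Raphson) to a score
inf-norm below 1e-8, with the observed-information covariance.  The percent
change for a year level is ``100 * (exp(beta) - 1)`` with Wald 95% CIs on the
log scale, and the single summary per stratum is the final-year-vs-reference
contrast.

Year (or adjustment) levels whose total observed count is zero have no finite
MLE; their cells are excluded from the likelihood and the level is reported
as non-estimable rather than crashing the stratum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import TrendFitError

logger = logging.getLogger(__name__)

_MAX_ITER = 100
_GRAD_TOL = 1e-8


@dataclass
class PoissonFit:
    """MLE of a log-linear Poisson model with offset."""

    params: pd.Series
    cov: pd.DataFrame
    deviance_path: list[float]
    n_iter: int
    converged: bool
    non_estimable: dict[str, list] = field(default_factory=dict)

    @property
    def deviance(self) -> float:
        return self.deviance_path[-1]

    def se(self, name: str) -> float:
        return float(np.sqrt(self.cov.loc[name, name]))


def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def _irls(X: np.ndarray, y: np.ndarray, offset: np.ndarray, names: list[str]):
    beta = np.zeros(X.shape[1])
    total = y.sum()
    if total > 0:
        beta[0] = np.log(total / np.exp(offset).sum())
    path = []
    grad_norm = np.inf
    for it in range(1, _MAX_ITER + 1):
        mu = np.exp(offset + X @ beta)
        path.append(_deviance(y, mu))
        score = X.T @ (y - mu)
        grad_norm = float(np.abs(score).max())
        if grad_norm < _GRAD_TOL:
            info = X.T @ (X * mu[:, None])
            cov = np.linalg.inv(info)
            return beta, cov, path, it, True
        info = X.T @ (X * mu[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise TrendFitError(f"singular information matrix (columns {names})") from exc
        beta = beta + step
    raise TrendFitError(f"IRLS did not converge in {_MAX_ITER} iterations; last score inf-norm {grad_norm:.3g}")


def fit_poisson(
    data: pd.DataFrame,
    reference_year: int,
    adjust_age: bool = False,
    count_col: str = "count",
    population_col: str = "denominator",
) -> PoissonFit:
    """Fit the categorical-year Poisson model to per-cell counts.

    ``data`` needs columns ``year``, ``count_col``, ``population_col`` and
    ``age_group`` when ``adjust_age``.  Cells with zero population are
    excluded from the likelihood (logged); factor levels with zero total
    count are excluded and reported under ``non_estimable``.
    """
    df = data.copy()
    n_zero_pop = int((df[population_col] <= 0).sum())
    if n_zero_pop:
        logger.warning("fit_poisson: excluding %d cells with zero population", n_zero_pop)
        df = df[df[population_col] > 0]
    if df.empty:
        raise TrendFitError("fit_poisson: no cells with positive population")
    if (df[count_col] < 0).any():
        raise TrendFitError("fit_poisson: negative counts")
    if reference_year not in set(df["year"]):
        raise TrendFitError(f"fit_poisson: reference year {reference_year} absent from data")

    non_estimable: dict[str, list] = {}
    year_totals = df.groupby("year")[count_col].sum()
    dead_years = sorted(year_totals.index[year_totals == 0])
    if reference_year in dead_years:
        raise TrendFitError(f"fit_poisson: reference year {reference_year} has zero total count")
    if dead_years:
        non_estimable["year"] = dead_years
        df = df[~df["year"].isin(dead_years)]
    if adjust_age:
        age_totals = df.groupby("age_group")[count_col].sum()
        dead_ages = sorted(age_totals.index[age_totals == 0])
        if dead_ages:
            non_estimable["age_group"] = dead_ages
            df = df[~df["age_group"].isin(dead_ages)]

    years = sorted(df["year"].unique())
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["intercept"]
    for y in years:
        if y == reference_year:
            continue
        cols.append((df["year"] == y).to_numpy(dtype=float))
        names.append(f"year:{y}")
    if adjust_age:
        levels = sorted(df["age_group"].unique())
        for lev in levels[1:]:
            cols.append((df["age_group"] == lev).to_numpy(dtype=float))
            names.append(f"age:{lev}")

    X = np.column_stack(cols)
    y = df[count_col].to_numpy(dtype=float)
    offset = np.log(df[population_col].to_numpy(dtype=float))
    beta, cov, path, n_iter, ok = _irls(X, y, offset, names)
    return PoissonFit(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        deviance_path=path,
        n_iter=n_iter,
        converged=ok,
        non_estimable=non_estimable,
    )


def percent_change(coefficient: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """Percent change and Wald CI for a log-rate-ratio: 100*(exp(b +/- z*se) - 1)."""
    if se < 0:
        raise ValueError("percent_change: negative standard error")
    z = stats.norm.ppf(0.5 + level / 2.0)
    point = 100.0 * (np.exp(coefficient) - 1.0)
    lo = 100.0 * (np.exp(coefficient - z * se) - 1.0)
    hi = 100.0 * (np.exp(coefficient + z * se) - 1.0)
    return float(point), float(lo), float(hi)


def run_trend_suite(
    cube: pd.DataFrame,
    population: pd.DataFrame,
    reference_year: int,
    diseases: tuple[str, ...] = ("CD", "UC", "IBDU", "IBD"),
    level: float = 0.95,
) -> pd.DataFrame:
    """Fit every stratum's trend model and return tidy per-year contrasts.

    Strata are disease x sex-level (female/male/both) x age-level (each bin
    as a year-only model, plus an all-ages model with the age-group factor —
    the "adjusted for age" rows).  ``cube`` is a counts cube on the trend
    age grouping; ``population`` the matching denominators.  Output has one
    row per stratum and non-reference year with the coefficient, its SE, the
    percent change and the Wald CI; non-estimable year levels appear with
    NaN estimates and ``estimable=False``.
    """
    from .incidence_estimation import _pool_sex, add_ibd_total  # local to avoid cycle

    cube = add_ibd_total(_pool_sex(cube))
    pop = _pool_sex(population).rename(columns={"count": "denominator"})
    merged = cube.merge(pop, on=["year", "age_group", "sex"], how="left", validate="many_to_one")
    if merged["denominator"].isna().any():
        raise TrendFitError("run_trend_suite: population cell missing for some cube cells")

    all_years = sorted(merged["year"].unique())
    age_levels = list(dict.fromkeys(merged["age_group"])) + ["all (age-adjusted)"]
    rows = []
    for disease in diseases:
        d = merged[merged["disease"] == disease]
        for sex in ("female", "male", "both"):
            ds = d[d["sex"] == sex]
            for age_level in age_levels:
                adjust = age_level == "all (age-adjusted)"
                sub = ds if adjust else ds[ds["age_group"] == age_level]
                try:
                    fit = fit_poisson(sub, reference_year, adjust_age=adjust)
                except TrendFitError as exc:
                    logger.warning("stratum (%s, %s, %s) not estimable: %s", disease, sex, age_level, exc)
                    fit = None
                for year in all_years:
                    if year == reference_year:
                        continue
                    name = f"year:{year}"
                    if fit is not None and name in fit.params.index:
                        beta = float(fit.params[name])
                        se = fit.se(name)
                        point, lo, hi = percent_change(beta, se, level)
                        estimable = True
                    else:
                        beta = se = point = lo = hi = np.nan
                        estimable = False
                    rows.append(
                        {
                            "disease": disease,
                            "sex": sex,
                            "age_level": age_level,
                            "target_year": year,
                            "coefficient": beta,
                            "se": se,
                            "percent_change": point,
                            "ci_low": lo,
                            "ci_high": hi,
                            "estimable": estimable,
                        }
                    )
    return pd.DataFrame(rows)


def trend_summary(trend: pd.DataFrame, final_year: int) -> pd.DataFrame:
    """One row per stratum: the final-year-vs-reference contrast."""
    out = trend[trend["target_year"] == final_year].copy()
    if out.empty:
        raise TrendFitError(f"trend_summary: no estimates for final year {final_year}")
    return out.reset_index(drop=True)
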