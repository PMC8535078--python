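"""Weather-window covariates and trait-environment correlations.

Daily site weather is aggregated into per-environment covariates over
calendar windows anchored to the harvest year (e.g. "cumulative
rainfall, December to April" or "mean July temperature"), and those
covariates are correlated with per-environment trait means using
Pearson's product-moment coefficient with pairwise deletion and the
conventional significance stars (* p<0.05, ** p<0.01, *** p<0.001).

Window anchoring follows the autumn-sown crop calendar: a window month
from September onwards belongs to the calendar year *before* harvest,
months up to August to the harvest year itself.  So for a 2013 harvest
"Dec to April" spans 2012-12-01 .. 2013-04-30.
"""

from __future__ import annotations

import calendar
import logging
import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, IntegrityError
from .met_core import EnvironmentRecord

__all__ = [
    "DailyWeather",
    "WindowSpec",
    "WeatherCovariate",
    "CorrelationResult",
    "significance_stars",
    "aggregate_weather",
    "pearson",
    "correlation_table",
]

logger = logging.getLogger(__name__)

#: Fraction of window days that may be absent before the aggregate is
#: declared missing.
MAX_MISSING_FRACTION = 0.10

#: First month considered part of the pre-harvest calendar year.
_AUTUMN_ANCHOR_MONTH = 9


class DailyWeather:
    """Daily weather series for one site.

    Columns: ``date`` plus any of ``rain`` (mm/day), ``tmin``/``tmax``
    (degC), ``rh`` (%), ``radiation`` (MJ/m2/day).  Dates must be
    unique; rain and radiation non-negative; tmin <= tmax; rh within
    [0, 100].
    """

    REQUIRED = ("date",)
    KNOWN = ("rain", "tmin", "tmax", "rh", "radiation")

    def __init__(self, frame: pd.DataFrame):
        df = frame.copy()
        if "date" not in df.columns:
            raise IntegrityError("daily weather needs a 'date' column")
        df["date"] = pd.to_datetime(df["date"]).dt.date
        if df["date"].duplicated().any():
            dup = df.loc[df["date"].duplicated(), "date"].iloc[0]
            raise IntegrityError(f"duplicate weather date {dup}")
        if "rain" in df and (df["rain"].dropna() < 0).any():
            raise IntegrityError("rainfall must be non-negative")
        if "radiation" in df and (df["radiation"].dropna() < 0).any():
            raise IntegrityError("radiation must be non-negative")
        if {"tmin", "tmax"} <= set(df.columns):
            both = df[["tmin", "tmax"]].dropna()
            if (both["tmin"] > both["tmax"]).any():
                raise IntegrityError("tmin exceeds tmax on at least one day")
        if "rh" in df:
            rh = df["rh"].dropna()
            if ((rh < 0) | (rh > 100)).any():
                raise IntegrityError("relative humidity outside [0, 100]")
        self._df = df.sort_values("date").reset_index(drop=True)

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    def between(self, start: date, end: date) -> pd.DataFrame:
        d = self._df["date"]
        return self._df[(d >= start) & (d <= end)]


def _default_year_offset(month: int) -> int:
    return -1 if month >= _AUTUMN_ANCHOR_MONTH else 0


@dataclass(frozen=True)
class WindowSpec:
    """A month/day window anchored to the harvest year.

    Year offsets are relative to the harvest year; ``None`` picks the
    autumn-sowing default (September-December -> year before harvest).
    """

    start_month: int
    start_day: int = 1
    end_month: int = 0  # 0 -> same as start_month
    end_day: int = 0    # 0 -> last day of end month
    start_year_offset: int | None = None
    end_year_offset: int | None = None

    def resolve(self, harvest_year: int) -> tuple[date, date]:
        sm = self.start_month
        em = self.end_month or sm
        so = (
            self.start_year_offset
            if self.start_year_offset is not None
            else _default_year_offset(sm)
        )
        eo = (
            self.end_year_offset
            if self.end_year_offset is not None
            else _default_year_offset(em)
        )
        start = date(harvest_year + so, sm, self.start_day)
        ed = self.end_day or calendar.monthrange(harvest_year + eo, em)[1]
        end = date(harvest_year + eo, em, ed)
        if end < start:
            raise IntegrityError(f"window {self} is empty for harvest year {harvest_year}")
        return start, end

    def n_days(self, harvest_year: int) -> int:
        start, end = self.resolve(harvest_year)
        return (end - start).days + 1


@dataclass(frozen=True)
class WeatherCovariate:
    """A named windowed aggregate of one daily weather variable."""

    name: str
    variable: str          # rain | temperature | radiation
    statistic: str         # sum | mean
    window: WindowSpec

    def __post_init__(self) -> None:
        if self.variable not in ("rain", "temperature", "radiation"):
            raise IntegrityError(f"unknown weather variable {self.variable!r}")
        if self.statistic not in ("sum", "mean"):
            raise IntegrityError(f"unknown statistic {self.statistic!r}")


@dataclass(frozen=True)
class CorrelationResult:
    """One Pearson correlation with its significance."""

    trait: str
    covariate: str
    r: float
    n: int
    p: float
    stars: str

    @property
    def df(self) -> int:
        return self.n - 2


def significance_stars(p: float) -> str:
    """Conventional star coding: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def aggregate_weather(
    series: DailyWeather,
    env: EnvironmentRecord,
    covariate: WeatherCovariate,
) -> float:
    """Aggregate one site's daily weather over a harvest-anchored window.

    Rain and radiation are summed; temperature is the mean of the daily
    midrange (tmin + tmax) / 2.  Returns NaN (with a warning) when more
    than 10% of the window days are absent from the series.
    """
    start, end = covariate.window.resolve(env.harvest_date.year)
    n_expected = (end - start).days + 1
    sub = series.between(start, end)
    if covariate.variable == "temperature":
        daily = (sub["tmin"] + sub["tmax"]) / 2.0
    else:
        col = "rain" if covariate.variable == "rain" else "radiation"
        if col not in sub.columns:
            daily = pd.Series(dtype=float)
        else:
            daily = sub[col]
    daily = daily.dropna()
    n_missing = n_expected - len(daily)
    if n_missing > MAX_MISSING_FRACTION * n_expected:
        warnings.warn(
            f"covariate {covariate.name!r}, environment {env.environment_id}: "
            f"{n_missing}/{n_expected} window days absent; value set missing",
            stacklevel=2,
        )
        return float("nan")
    if covariate.statistic == "sum":
        return float(daily.sum())
    return float(daily.mean())


def pearson(x, y, trait: str = "x", covariate: str = "y") -> CorrelationResult:
    """Pearson product-moment correlation with pairwise deletion.

    The two-sided p-value comes from ``t = r sqrt(df / (1 - r^2))`` on
    ``df = n - 2`` degrees of freedom.  Requires >= 3 complete pairs
    and non-zero variance in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise IntegrityError("paired vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        raise DegenerateInputError(f"need >= 3 complete pairs, have {n}")
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise DegenerateInputError("zero variance: correlation undefined")
    r, p = stats.pearsonr(xs, ys)
    return CorrelationResult(trait, covariate, float(r), n, float(p), significance_stars(p))


def correlation_table(
    env_means: pd.DataFrame,
    covariates: pd.DataFrame,
    exclude=(),
) -> pd.DataFrame:
    """Trait x covariate Pearson correlation grid over environments.

    Parameters
    ----------
    env_means
        Per-environment trait means, environments as index, one column
        per trait; NaN allowed (e.g. traits not recorded at a site).
    covariates
        Per-environment covariate values on the same index.
    exclude
        Environment labels dropped up front (e.g. a spring-sown trial
        in an autumn-sown series).

    Returns a tidy frame with columns ``trait, covariate, r, n, df, p,
    stars, reason``; pairwise deletion per cell, so traits with missing
    environments lose only their own degrees of freedom.  Cells whose
    correlation is undefined carry NaN and the reason.
    """
    exclude = set(exclude)
    keep = ~env_means.index.isin(exclude)
    if keep.sum() < 3:
        raise DegenerateInputError(
            f"only {int(keep.sum())} environments survive the exclusions"
        )
    em = env_means.loc[keep]
    cv = covariates.reindex(em.index)
    rows = []
    for trait in em.columns:
        for cov in cv.columns:
            try:
                res = pearson(em[trait], cv[cov], trait=trait, covariate=cov)
                rows.append(
                    dict(trait=trait, covariate=cov, r=res.r, n=res.n,
                         df=res.df, p=res.p, stars=res.stars, reason="")
                )
            except DegenerateInputError as exc:
                rows.append(
                    dict(trait=trait, covariate=cov, r=np.nan, n=0, df=0,
                         p=np.nan, stars="", reason=str(exc))
                )
    return pd.DataFrame(rows)
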