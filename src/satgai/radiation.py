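"""Seasonal GAI courses, weather processing and absorbed-PAR cumulation.

The monitoring chain turns dated per-cell GAI estimates into the total
absorbed effective photosynthetically active radiation (APAR) between the
start of the season and harvest:

1. the dated GAI observations are complemented with boundary points —
   0.3 m²/m² on 1 February (or the first observed value if that is lower)
   and 0 m²/m² at harvest — and interpolated linearly in calendar days;
2. hourly weather is aggregated to daily mean temperature and daily incoming
   PAR; the PAR is weighted by a trapezoidal temperature-response function
   (0 below 2.5 °C, rising to 1 at 9.5 °C, plateau to 20 °C, falling to 0 at
   35 °C) to account for the temperature dependency of photosynthesis;
3. daily absorbed radiation follows Lambert–Beer,
   ``absorbed = weighted_PAR · (1 − e^{−k·GAI})`` with extinction
   coefficient k = 0.7, and is cumulated in daily steps until harvest.

Thermal time (base 0 °C) is computed for reference; interpolation runs on
calendar days.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EXTINCTION_COEFFICIENT = 0.7
START_GAI_DEFAULT = 0.3


@dataclasses.dataclass(frozen=True)
class TrapezoidParams:
    """Transition points (°C) of the temperature-response trapezoid."""

    t1: float = 2.5
    t2: float = 9.5
    t3: float = 20.0
    t4: float = 35.0
    base_temperature: float = 0.0

    def __post_init__(self) -> None:
        if not (self.t1 < self.t2 <= self.t3 < self.t4):
            raise ValueError("trapezoid transitions must satisfy t1 < t2 <= t3 < t4")


DEFAULT_TRAPEZOID = TrapezoidParams()


@dataclasses.dataclass
class WeatherSeries:
    """Hourly or daily weather records (air temperature, incoming PAR)."""

    data: pd.DataFrame  # columns: timestamp, temp_c, par_mj_m2
    params: TrapezoidParams = DEFAULT_TRAPEZOID

    def __post_init__(self) -> None:
        df = self.data
        for col in ("timestamp", "temp_c", "par_mj_m2"):
            if col not in df.columns:
                raise ValueError(f"weather data lacks column {col!r}")
        ts = pd.to_datetime(df["timestamp"])
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValueError("timestamps must be strictly increasing")
        if (df["par_mj_m2"] < 0).any():
            raise ValueError("PAR must be non-negative")
        self.data = df.assign(timestamp=ts).reset_index(drop=True)

    @property
    def is_hourly(self) -> bool:
        ts = self.data["timestamp"]
        if len(ts) < 2:
            return False
        step = (ts.iloc[1] - ts.iloc[0]).total_seconds()
        return step < 24 * 3600


def temperature_weight(t_mean, params: TrapezoidParams = DEFAULT_TRAPEZOID):
    """Trapezoidal temperature response in [0, 1] for photosynthesis.

    Zero at and below ``t1``, rising linearly to 1 at ``t2``, flat to
    ``t3``, falling linearly to zero at ``t4`` and beyond.
    """
    t = np.asarray(t_mean, dtype=float)
    w = np.interp(t, [params.t1, params.t2, params.t3, params.t4], [0.0, 1.0, 1.0, 0.0])
    return w if w.ndim else float(w)


def daily_weather(series: WeatherSeries, max_gap_hours: float = 3.0) -> pd.DataFrame:
    """Aggregate weather to daily records with temperature-weighted PAR.

    Hourly input is averaged (temperature) and summed (PAR) per calendar
    day; daily input passes through.  Returns columns
    ``date, t_mean, par, weighted_par``.
    """
    df = series.data
    if series.is_hourly:
        steps = df["timestamp"].diff().dropna().dt.total_seconds() / 3600.0
        if (steps > max_gap_hours).any():
            raise ValueError("gap in hourly weather records exceeds tolerance")
        grouped = df.groupby(df["timestamp"].dt.date)
        out = grouped.agg(t_mean=("temp_c", "mean"), par=("par_mj_m2", "sum"))
        out = out.reset_index().rename(columns={"timestamp": "date"})
    else:
        gaps = df["timestamp"].diff().dropna().dt.days
        if (gaps > 1).any():
            raise ValueError("gap in daily weather records exceeds tolerance")
        out = pd.DataFrame(
            {
                "date": df["timestamp"].dt.date,
                "t_mean": df["temp_c"].to_numpy(dtype=float),
                "par": df["par_mj_m2"].to_numpy(dtype=float),
            }
        )
    out["weighted_par"] = out["par"] * temperature_weight(
        out["t_mean"].to_numpy(), series.params
    )
    return out


def thermal_time(series: WeatherSeries) -> pd.DataFrame:
    """Cumulative thermal time (°C·day above the base temperature) per day."""
    daily = daily_weather(series)
    base = series.params.base_temperature
    inc = np.maximum(daily["t_mean"].to_numpy() - base, 0.0)
    return pd.DataFrame(
        {"date": daily["date"], "thermal_time": np.cumsum(inc)}
    )


@dataclasses.dataclass
class GaiCourse:
    """Ordered (date, GAI) support points spanning one season."""

    dates: list
    gai: np.ndarray
    season_start: dt.date
    harvest: dt.date

    def __post_init__(self) -> None:
        self.gai = np.asarray(self.gai, dtype=float)
        ords = np.array([d.toordinal() for d in self.dates])
        if len(self.dates) != self.gai.size:
            raise ValueError("dates and GAI values must align")
        if np.any(np.diff(ords) <= 0):
            raise ValueError("course dates must be strictly increasing")
        if np.any(self.gai < 0):
            raise ValueError("GAI must be non-negative")


def assemble_gai_course(
    observations: Iterable[tuple[dt.date, float]],
    season_start: dt.date,
    harvest: dt.date,
    start_gai_default: float = START_GAI_DEFAULT,
) -> GaiCourse:
    """Complement dated GAI observations with the season boundary points.

    The course starts at ``season_start`` with ``start_gai_default``
    (0.3 m²/m²), or with the first observed GAI if that is lower, and ends
    with 0 m²/m² at harvest unless an observation falls on the harvest date.
    Negative observations are clipped to 0.
    """
    obs = sorted(observations, key=lambda p: p[0])
    if not obs:
        raise ValueError("empty observations")
    dates = [p[0] for p in obs]
    if len(set(dates)) != len(dates):
        raise ValueError("duplicate observation dates")
    if dates[0] <= season_start or dates[-1] > harvest:
        raise ValueError("observation outside (season_start, harvest]")
    gai = np.maximum(np.array([p[1] for p in obs], dtype=float), 0.0)

    start_val = min(start_gai_default, float(gai[0]))
    out_dates = [season_start, *dates]
    out_gai = [start_val, *gai.tolist()]
    if dates[-1] != harvest:
        out_dates.append(harvest)
        out_gai.append(0.0)
    return GaiCourse(out_dates, np.array(out_gai), season_start, harvest)


def interpolate_gai(course: GaiCourse, dates: Sequence[dt.date]) -> np.ndarray:
    """Piecewise-linear GAI (in calendar days) at the requested dates."""
    q = np.array([d.toordinal() for d in dates], dtype=float)
    lo, hi = course.season_start.toordinal(), course.harvest.toordinal()
    if q.size and (q.min() < lo or q.max() > hi):
        raise ValueError("query date outside the course span")
    xp = np.array([d.toordinal() for d in course.dates], dtype=float)
    return np.interp(q, xp, course.gai)


def absorbed_radiation(
    course: GaiCourse,
    daily: pd.DataFrame,
    k: float = EXTINCTION_COEFFICIENT,
) -> pd.DataFrame:
    """Daily Lambert–Beer absorption and its cumulative sum until harvest.

    ``daily`` must carry ``date`` and ``weighted_par`` columns covering
    every calendar day from season start to harvest.  Returns columns
    ``date, gai, weighted_par, absorbed, cumulative_absorbed``.
    """
    span = pd.date_range(course.season_start, course.harvest, freq="D").date
    wp = dict(zip(daily["date"], daily["weighted_par"].to_numpy(dtype=float)))
    missing = [d for d in span if d not in wp]
    if missing:
        raise ValueError(f"weather coverage gap: {missing[0]} (and possibly later)")
    wpar = np.array([wp[d] for d in span])
    gai = interpolate_gai(course, list(span))
    absorbed = wpar * (1.0 - np.exp(-k * gai))
    return pd.DataFrame(
        {
            "date": list(span),
            "gai": gai,
            "weighted_par": wpar,
            "absorbed": absorbed,
            "cumulative_absorbed": np.cumsum(absorbed),
        }
    )


def cumulative_apar(
    observations: Iterable[tuple[dt.date, float]],
    daily: pd.DataFrame,
    season_start: dt.date,
    harvest: dt.date,
    k: float = EXTINCTION_COEFFICIENT,
) -> float:
    """Total APAR at harvest for one set of dated GAI observations."""
    course = assemble_gai_course(observations, season_start, harvest)
    series = absorbed_radiation(course, daily, k=k)
    return float(series["cumulative_absorbed"].iloc[-1])
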