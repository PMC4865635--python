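"""Daily weather forcing: file I/O, FAO-56 reference evapotranspiration,
atmospheric N deposition fluxes and a seeded synthetic generator for the
semi-arid North China Plain climate.

The synthetic generator is a statistical stand-in for the unavailable
station record: monsoonal precipitation (most of the annual total between
June and September), a sinusoidal annual temperature cycle with
autocorrelated daily noise, and radiation tied to day length and
cloudiness on wet days.  Annual totals are drawn from the envelope the
field seasons span (330-600 mm precipitation, 11.8-13.2 degC mean).
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError
from .parameters import DepositionConfig

_COLUMNS = ["date", "t_mean", "t_min", "t_max", "precipitation",
            "global_radiation", "wind_speed", "relative_humidity"]

#: W/m2 (24 h mean) -> MJ/m2/d
WM2_TO_MJ = 0.0864


@dataclass(frozen=True)
class DailyWeather:
    """One day of forcing.  Radiation is the 24-h mean in W/m2."""

    date: dt.date
    t_mean: float
    t_min: float
    t_max: float
    precipitation: float      # mm/d
    global_radiation: float   # W/m2
    wind_speed: float         # m/s
    relative_humidity: float  # %

    def __post_init__(self):
        if self.precipitation < 0:
            raise DomainError(f"{self.date}: precipitation must be >= 0")
        if not self.t_min <= self.t_mean <= self.t_max:
            raise DomainError(f"{self.date}: require t_min <= t_mean <= t_max")
        if not 0.0 <= self.relative_humidity <= 100.0:
            raise DomainError(f"{self.date}: relative humidity outside [0, 100]")
        if self.global_radiation < 0:
            raise DomainError(f"{self.date}: global radiation must be >= 0")


@dataclass
class WeatherSeries:
    """Gap-free daily series plus station metadata and deposition config."""

    frame: pd.DataFrame
    latitude: float = 37.9
    altitude: float = 50.0
    deposition: DepositionConfig | None = None

    def __post_init__(self):
        df = self.frame.reset_index(drop=True).copy()
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"weather frame lacks columns {missing}")
        dates = pd.to_datetime(df["date"]).dt.date.to_numpy()
        deltas = np.array([(b - a).days for a, b in zip(dates[:-1], dates[1:])])
        if len(dates) == 0:
            raise FormatError("weather series is empty")
        if np.any(deltas != 1):
            i = int(np.argmax(deltas != 1))
            missing_day = dates[i] + dt.timedelta(days=1)
            raise FormatError(f"missing {missing_day.isoformat()}")
        df["date"] = dates
        self.frame = df[_COLUMNS]

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def start(self) -> dt.date:
        return self.frame["date"].iloc[0]

    @property
    def end(self) -> dt.date:
        return self.frame["date"].iloc[-1]

    def day(self, date: dt.date) -> DailyWeather:
        offset = (date - self.start).days
        if offset < 0 or offset >= len(self.frame):
            raise DomainError(f"date {date} outside weather series {self.start}..{self.end}")
        row = self.frame.iloc[offset]
        return DailyWeather(**{c: (row[c] if c == "date" else float(row[c])) for c in _COLUMNS})

    def iter_days(self) -> Iterator[DailyWeather]:
        for row in self.frame.itertuples(index=False):
            yield DailyWeather(*row)


def read_weather(path: str | Path) -> WeatherSeries:
    """Read the delimited-text weather format written by :func:`write_weather`."""
    path = Path(path)
    latitude, altitude = 37.9, 50.0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].split()
            if len(parts) == 2 and parts[0] in ("latitude", "altitude"):
                if parts[0] == "latitude":
                    latitude = float(parts[1])
                else:
                    altitude = float(parts[1])
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise FormatError(f"cannot parse weather file {path}: {exc}") from exc
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            [float(v) for v in row[1:]]
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: unparseable field on data line {i}: {exc}") from exc
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return WeatherSeries(frame=df, latitude=latitude, altitude=altitude)


def write_weather(series: WeatherSeries, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# leachsim weather file v1\n")
        fh.write(f"# latitude {series.latitude!r}\n")
        fh.write(f"# altitude {series.altitude!r}\n")
        series.frame.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FAO-56 reference evapotranspiration (daily form)

def saturation_vapour_pressure(t: float) -> float:
    """kPa at air temperature t (degC)."""
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def extraterrestrial_radiation(day_of_year: int, latitude: float) -> float:
    """Ra in MJ/m2/d for a calendar day and latitude (degrees)."""
    j = day_of_year
    phi = np.radians(latitude)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * j / 365.0)
    delta = 0.409 * np.sin(2.0 * np.pi * j / 365.0 - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0))
    return (24.0 * 60.0 / np.pi) * 0.0820 * dr * (
        ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws)
    )


def day_length(day_of_year: int, latitude: float) -> float:
    """Daylight hours."""
    phi = np.radians(latitude)
    delta = 0.409 * np.sin(2.0 * np.pi * day_of_year / 365.0 - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0))
    return 24.0 / np.pi * ws


def reference_et_fao56(day: DailyWeather, latitude: float, altitude: float,
                       ea_kpa: float | None = None) -> float:
    """Daily grass reference evapotranspiration ET0 (mm/d), FAO-56 form.

    Actual vapour pressure defaults to mean relative humidity applied to
    the mean of the saturation pressures at t_min and t_max; pass
    ``ea_kpa`` to use an independently derived value (e.g. from dew point
    or RH extremes).
    """
    if not 0.0 <= day.relative_humidity <= 100.0:
        raise DomainError("relative humidity outside [0, 100]")
    t = day.t_mean
    es = 0.5 * (saturation_vapour_pressure(day.t_max) + saturation_vapour_pressure(day.t_min))
    ea = day.relative_humidity / 100.0 * es if ea_kpa is None else ea_kpa
    delta = 4098.0 * saturation_vapour_pressure(t) / (t + 237.3) ** 2
    pressure = 101.3 * ((293.0 - 0.0065 * altitude) / 293.0) ** 5.26
    gamma = 0.000665 * pressure

    rs = day.global_radiation * WM2_TO_MJ
    doy = day.date.timetuple().tm_yday
    ra = extraterrestrial_radiation(doy, latitude)
    rso = (0.75 + 2e-5 * altitude) * ra
    rns = 0.77 * rs
    sigma = 4.903e-9
    rel = np.clip(rs / rso, 0.3, 1.0) if rso > 0 else 1.0
    rnl = sigma * 0.5 * ((day.t_max + 273.16) ** 4 + (day.t_min + 273.16) ** 4) \
        * (0.34 - 0.14 * np.sqrt(max(ea, 0.0))) * (1.35 * rel - 0.35)
    rn = rns - rnl

    u2 = day.wind_speed
    num = 0.408 * delta * rn + gamma * (900.0 / (t + 273.0)) * u2 * max(es - ea, 0.0)
    et0 = num / (delta + gamma * (1.0 + 0.34 * u2))
    return max(float(et0), 0.0)


# ---------------------------------------------------------------------------
# atmospheric N deposition

def deposition_flux(day: DailyWeather, config: DepositionConfig) -> tuple[float, float]:
    """(NH4-N, NO3-N) deposition in kg N/ha/d.

    Wet flux = concentration (mg N/L) x precipitation (mm) x 0.01; dry
    flux = annual value spread uniformly over the actual year length.
    """
    days_in_year = 366.0 if calendar.isleap(day.date.year) else 365.0
    wet_factor = day.precipitation * 0.01
    nh4 = config.wet_nh4 * wet_factor + config.dry_nh4 / days_in_year
    no3 = config.wet_no3 * wet_factor + config.dry_no3 / days_in_year
    return nh4, no3


# ---------------------------------------------------------------------------
# synthetic NCP weather

@dataclass(frozen=True)
class ClimateSpec:
    """Envelope of the semi-arid NCP climate emulated by the generator."""

    annual_precip_range: tuple[float, float] = (330.0, 600.0)
    annual_tmean_range: tuple[float, float] = (11.8, 13.2)
    temp_amplitude: float = 14.5          # degC, annual half-range
    coldest_doy: int = 15                 # mid January
    diurnal_half_range: float = 5.0       # degC around the daily mean
    monthly_precip_weights: tuple = (0.01, 0.02, 0.02, 0.04, 0.06, 0.13,
                                     0.28, 0.22, 0.11, 0.06, 0.04, 0.01)
    wet_day_probability: tuple = (0.05, 0.06, 0.08, 0.10, 0.12, 0.25,
                                  0.40, 0.38, 0.25, 0.12, 0.08, 0.05)
    latitude: float = 37.9
    altitude: float = 50.0


def synthetic_ncp_weather(seed: int, n_years: int, climate_spec: ClimateSpec | None = None,
                          start_year: int = 2001) -> WeatherSeries:
    """Reproducible synthetic daily weather for ``n_years`` calendar years."""
    spec = climate_spec or ClimateSpec()
    rng = np.random.default_rng(seed)
    records: list[dict] = []

    for year in range(start_year, start_year + n_years):
        n_days = 366 if calendar.isleap(year) else 365
        doy = np.arange(1, n_days + 1)

        annual_p = rng.uniform(*spec.annual_precip_range)
        tmean_target = rng.uniform(*spec.annual_tmean_range)

        # temperature: sinusoid + AR(1) noise, re-centred on the target mean
        base = tmean_target - spec.temp_amplitude * np.cos(
            2.0 * np.pi * (doy - spec.coldest_doy) / n_days)
        noise = np.empty(n_days)
        eps = rng.normal(0.0, 1.5, n_days)
        noise[0] = eps[0]
        for i in range(1, n_days):
            noise[i] = 0.7 * noise[i - 1] + eps[i]
        noise -= noise.mean()
        t_mean = base + noise

        # precipitation: monthly totals from the monsoonal weights, spread
        # over randomly chosen wet days with gamma-distributed amounts
        precip = np.zeros(n_days)
        month_of_day = np.array([dt.date(year, 1, 1) + dt.timedelta(days=int(d) - 1)
                                 for d in doy])
        months = np.array([d.month for d in month_of_day])
        for m in range(1, 13):
            idx = np.where(months == m)[0]
            target = annual_p * spec.monthly_precip_weights[m - 1]
            if target <= 0:
                continue
            n_wet = max(1, int(round(spec.wet_day_probability[m - 1] * len(idx))))
            wet = rng.choice(idx, size=min(n_wet, len(idx)), replace=False)
            amounts = rng.gamma(0.9, 1.0, size=len(wet))
            precip[wet] = amounts / amounts.sum() * target

        # radiation: clear-sky fraction reduced on wet days
        ra = np.array([extraterrestrial_radiation(int(d), spec.latitude) for d in doy])
        clear = 0.75 + 2e-5 * spec.altitude
        cloud = np.where(precip > 0.0,
                         rng.uniform(0.30, 0.55, n_days),
                         rng.uniform(0.60, 0.78, n_days))
        radiation = ra * clear * cloud / 0.78 / WM2_TO_MJ  # W/m2

        rh = np.where(precip > 0.0,
                      rng.normal(85.0, 5.0, n_days),
                      rng.normal(55.0, 10.0, n_days))
        rh = np.clip(rh, 15.0, 100.0)
        wind = np.clip(rng.lognormal(0.55, 0.45, n_days), 0.2, 12.0)

        half = np.clip(rng.normal(spec.diurnal_half_range, 1.0, n_days), 1.0, None)
        for i in range(n_days):
            records.append({
                "date": month_of_day[i],
                "t_mean": round(float(t_mean[i]), 3),
                "t_min": round(float(t_mean[i] - half[i]), 3),
                "t_max": round(float(t_mean[i] + half[i]), 3),
                "precipitation": round(float(precip[i]), 4),
                "global_radiation": round(float(max(radiation[i], 0.0)), 3),
                "wind_speed": round(float(wind[i]), 3),
                "relative_humidity": round(float(rh[i]), 2),
            })

    frame = pd.DataFrame.from_records(records)
    return WeatherSeries(frame=frame, latitude=spec.latitude, altitude=spec.altitude)
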