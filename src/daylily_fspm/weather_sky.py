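"""Daily weather, solar geometry and the discretized sky dome.

This module drives everything upstream of the canopy: it reads (or
synthesizes) one row of weather per simulated day, converts the day's
temperature range and cloud cover into at-surface global radiation with a
cloud-cover-based solar radiation model (CSRM), and discretizes the sky into
72 diffuse directional sources plus one direct sun source whose radiant
weights close exactly on the day's flux.

Radiation bookkeeping convention: all fluxes handled here are 24-hour mean
global shortwave irradiances on the horizontal (W m-2).  The canopy light
pass rescales to daylight-mean intensity (see :mod:`daylily_fspm.simulator`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WeatherDay",
    "SolarGeometry",
    "SkyDome",
    "SyntheticWeatherConfig",
    "SOLAR_CONSTANT",
    "PPFD_PER_WATT",
    "extraterrestrial_radiation",
    "csrm_daily_radiation",
    "csrm_clearness_ratio",
    "build_sky_dome",
    "radiation_to_ppfd",
    "generate_synthetic_weather",
    "read_weather_csv",
    "write_weather_csv",
]

#: Solar constant (W m-2).
SOLAR_CONSTANT = 1367.0

#: Conversion from shortwave irradiance (W m-2) to PPFD (umol m-2 s-1).
PPFD_PER_WATT = 2.275

#: CSRM clearness coefficients: H/H_o = A0 + A1*sqrt(Tmax-Tmin) + A2*cloud.
CSRM_A0, CSRM_A1, CSRM_A2 = -0.08, 0.21, -0.012

WEATHER_COLUMNS = ["doy", "tmax_c", "tmin_c", "cloud", "rh", "co2_ppm", "wind_ms"]


@dataclass(frozen=True)
class WeatherDay:
    """One day of driving climate."""

    doy: int
    tmax: float  # degC
    tmin: float  # degC
    cloud: float  # mean cloud cover fraction, 0-1
    rh: float  # relative humidity fraction, 0-1
    co2: float  # ppm
    wind: float  # m s-1

    def __post_init__(self) -> None:
        if self.tmax < self.tmin:
            raise ValueError(f"tmax ({self.tmax}) < tmin ({self.tmin}) on doy {self.doy}")
        if not 0.0 <= self.cloud <= 1.0:
            raise ValueError(f"cloud cover {self.cloud} outside [0, 1]")
        if self.co2 <= 0:
            raise ValueError("co2 must be positive (ppm)")

    @property
    def tmean(self) -> float:
        return 0.5 * (self.tmax + self.tmin)


def _declination(doy: int) -> float:
    """Solar declination (radians), Cooper's formula."""
    return math.radians(23.45) * math.sin(2.0 * math.pi * (284 + doy) / 365.0)


def _eccentricity(doy: int) -> float:
    """Earth-sun distance correction factor E0 = (r0/r)^2."""
    return 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)


@dataclass(frozen=True)
class SolarGeometry:
    """Site latitude/longitude and day-of-year; exposes the solar trajectory.

    Default site is the Datong daylily production base (40.13 N, 113.90 E).
    """

    latitude: float = 40.13
    longitude: float = 113.90
    doy: int = 172

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError("latitude outside [-90, 90]")

    @property
    def declination(self) -> float:
        return _declination(self.doy)

    @property
    def sunset_hour_angle(self) -> float:
        """Sunset hour angle omega_s (radians); 0 for polar night, pi for polar day."""
        phi = math.radians(self.latitude)
        x = -math.tan(phi) * math.tan(self.declination)
        return math.acos(min(1.0, max(-1.0, x)))

    @property
    def daylength_hours(self) -> float:
        return 24.0 / math.pi * self.sunset_hour_angle

    @property
    def daylength_seconds(self) -> float:
        return 3600.0 * self.daylength_hours

    def elevation(self, hour: float) -> float:
        """Solar elevation (radians) at local solar time ``hour`` (0-24)."""
        phi = math.radians(self.latitude)
        delta = self.declination
        omega = math.radians(15.0 * (hour - 12.0))
        sin_el = math.sin(phi) * math.sin(delta) + math.cos(phi) * math.cos(delta) * math.cos(omega)
        return math.asin(min(1.0, max(-1.0, sin_el)))

    def azimuth(self, hour: float) -> float:
        """Solar azimuth (radians, 0 = North, pi = South, clockwise)."""
        phi = math.radians(self.latitude)
        delta = self.declination
        omega = math.radians(15.0 * (hour - 12.0))
        el = self.elevation(hour)
        cos_az = (math.sin(delta) - math.sin(phi) * math.sin(el)) / max(
            1e-12, math.cos(phi) * math.cos(el)
        )
        az = math.acos(min(1.0, max(-1.0, cos_az)))
        return az if omega <= 0 else 2.0 * math.pi - az

    def mean_sun_direction(self) -> np.ndarray:
        """Irradiance-weighted daily-mean sun direction (unit vector, pointing
        from the scene toward the sun).

        Azimuth averages to solar noon (due south in the northern hemisphere);
        the effective elevation weights instantaneous elevation by sin(el),
        i.e. by the instantaneous horizontal irradiance of a clear day.
        """
        ws = self.sunset_hour_angle
        if ws <= 0.0:
            return np.array([0.0, 0.0, 1.0])
        hours = np.linspace(12.0 - ws * 12.0 / math.pi, 12.0 + ws * 12.0 / math.pi, 101)
        sin_el = np.array([max(0.0, math.sin(self.elevation(h))) for h in hours])
        if sin_el.sum() <= 0:
            return np.array([0.0, 0.0, 1.0])
        eff_sin = float((sin_el**2).sum() / sin_el.sum())
        el = math.asin(min(1.0, eff_sin))
        az = math.pi if self.latitude >= 0 else 0.0  # due south / north
        return np.array(
            [math.cos(el) * math.sin(az), -math.cos(el) * math.cos(az), math.sin(el)]
        )


def extraterrestrial_radiation(geom: SolarGeometry) -> float:
    """Daily-mean extraterrestrial radiation H_o on the horizontal (W m-2).

    Standard daily integral of the solar beam over the day arc:

        H_o = (Gsc / pi) * E0 * (omega_s sin(phi) sin(delta)
                                 + cos(phi) cos(delta) sin(omega_s))

    expressed as a 24-h mean flux.  Returns 0 during polar night.
    """
    phi = math.radians(geom.latitude)
    delta = geom.declination
    ws = geom.sunset_hour_angle
    e0 = _eccentricity(geom.doy)
    h_o = (SOLAR_CONSTANT / math.pi) * e0 * (
        ws * math.sin(phi) * math.sin(delta) + math.cos(phi) * math.cos(delta) * math.sin(ws)
    )
    return max(0.0, h_o)


def csrm_clearness_ratio(tmax: float, tmin: float, cloud: float) -> float:
    """CSRM atmospheric transmission H/H_o, clamped to [0, 1].

    The empirical regression -0.08 + 0.21 (Tmax - Tmin)^0.5 - 0.012 N maps
    the diurnal temperature range (a clearness proxy) and mean cloud cover N
    (fraction, 0-1) to the daily clearness index.  The raw regression can
    leave [0, 1] for extreme inputs; it is clamped to physical bounds.
    """
    if tmax < tmin:
        raise ValueError("negative temperature range")
    ratio = CSRM_A0 + CSRM_A1 * math.sqrt(tmax - tmin) + CSRM_A2 * cloud
    return min(1.0, max(0.0, ratio))


def csrm_daily_radiation(day: WeatherDay, h_o: float) -> float:
    """Daily-mean global radiation at the surface H (W m-2), via the CSRM."""
    if h_o < 0:
        raise ValueError("H_o must be >= 0")
    return h_o * csrm_clearness_ratio(day.tmax, day.tmin, day.cloud)


def radiation_to_ppfd(irradiance: float | np.ndarray) -> float | np.ndarray:
    """Convert shortwave irradiance (W m-2) to PPFD (umol m-2 s-1), factor 2.275."""
    if np.any(np.asarray(irradiance) < 0):
        raise ValueError("irradiance must be >= 0")
    return PPFD_PER_WATT * irradiance


# --- sky dome -------------------------------------------------------------

#: Elevation band edges (deg) for the 6 x 12 diffuse discretization.
_BAND_EDGES = np.linspace(0.0, 90.0, 7)
_N_AZIMUTH = 12


@dataclass
class SkyDome:
    """72 diffuse directional sources + 1 direct sun source.

    ``directions`` are unit vectors pointing from the scene toward each
    source; ``weights`` are the sources' contributions to horizontal
    irradiance (W m-2) and sum (diffuse + sun) to ``total_flux`` exactly.
    """

    diffuse_directions: np.ndarray  # (72, 3)
    diffuse_weights: np.ndarray  # (72,)
    sun_direction: np.ndarray  # (3,)
    sun_weight: float
    total_flux: float

    def __post_init__(self) -> None:
        if self.diffuse_directions.shape != (72, 3):
            raise ValueError("sky dome must have exactly 72 diffuse sources")
        if np.any(self.diffuse_weights < 0) or self.sun_weight < 0:
            raise ValueError("dome weights must be >= 0")

    @property
    def all_directions(self) -> np.ndarray:
        return np.vstack([self.diffuse_directions, self.sun_direction[None, :]])

    @property
    def all_weights(self) -> np.ndarray:
        return np.append(self.diffuse_weights, self.sun_weight)


def _diffuse_grid() -> tuple[np.ndarray, np.ndarray]:
    """Unit directions and relative (unnormalized) weights of the 72 sources.

    6 elevation bands x 12 azimuth sectors; each source carries the solid
    angle of its sector times cos(zenith) at the band center, i.e. a
    standard-overcast-like weighting that favors high-elevation sky.
    """
    dirs = []
    wts = []
    for i in range(6):
        lo, hi = math.radians(_BAND_EDGES[i]), math.radians(_BAND_EDGES[i + 1])
        el = 0.5 * (lo + hi)
        solid = 2.0 * math.pi * (math.sin(hi) - math.sin(lo)) / _N_AZIMUTH
        for j in range(_N_AZIMUTH):
            az = 2.0 * math.pi * (j + 0.5) / _N_AZIMUTH
            dirs.append(
                [math.cos(el) * math.sin(az), -math.cos(el) * math.cos(az), math.sin(el)]
            )
            wts.append(solid * math.sin(el))  # sin(el) = cos(zenith)
    return np.array(dirs), np.array(wts)


_DIFFUSE_DIRS, _DIFFUSE_RELW = _diffuse_grid()


def diffuse_fraction(cloud: float) -> float:
    """Diffuse fraction of global radiation, linear in cloud cover.

    Anchored at ~23% diffuse under a clear sky and 100% under full overcast.
    """
    return min(1.0, 0.23 + 0.77 * cloud)


def build_sky_dome(h: float, geom: SolarGeometry, cloud: float) -> SkyDome:
    """Discretize the day's radiation into the 72+1 source dome.

    ``h`` is the daily-mean global radiation on the horizontal (W m-2); the
    direct share goes to one source at the daily-mean sun position, the rest
    is spread over the 72 diffuse sources.  Weights close on ``h`` exactly.
    """
    if h < 0:
        raise ValueError("H must be >= 0")
    f_d = diffuse_fraction(cloud)
    sun_dir = geom.mean_sun_direction()
    if h == 0.0:
        dw = np.zeros(72)
        return SkyDome(_DIFFUSE_DIRS.copy(), dw, sun_dir, 0.0, 0.0)
    diffuse_total = f_d * h
    dw = _DIFFUSE_RELW / _DIFFUSE_RELW.sum() * diffuse_total
    sun_w = h - diffuse_total
    return SkyDome(_DIFFUSE_DIRS.copy(), dw, sun_dir, sun_w, h)


# --- synthetic weather ----------------------------------------------------


@dataclass
class SyntheticWeatherConfig:
    """Season statistics the generator reproduces (2022 Datong defaults).

    The defaults emulate the measured season: 24-h mean global radiation
    248.7 W m-2, mean temperature 19.1 degC, mean cloud cover 0.4, mean wind
    2.4 m s-1, over days 91-242 at 40.13 N.
    """

    mean_radiation: float = 248.7  # W m-2, 24-h season mean of H
    mean_temperature: float = 19.1  # degC
    mean_cloud: float = 0.4
    mean_wind: float = 2.4
    mean_rh: float = 0.55
    co2_ppm: float = 420.0
    start_doy: int = 91
    end_doy: int = 242
    latitude: float = 40.13
    temp_seasonal_amplitude: float = 7.5  # degC, sinusoidal trend
    temp_noise: float = 1.5  # degC, day-to-day sd
    cloud_noise: float = 0.15
    wind_noise: float = 0.8
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_cloud <= 1.0:
            raise ValueError("mean cloud outside [0, 1]: infeasible configuration")
        if not 91 <= self.start_doy < self.end_doy <= 242:
            raise ValueError("day range must lie within 91-242")


def _season_h_mean(dtr: float, cfg: SyntheticWeatherConfig, cloud: np.ndarray,
                   h_o: np.ndarray) -> float:
    ratio = np.clip(CSRM_A0 + CSRM_A1 * np.sqrt(max(dtr, 0.0)) + CSRM_A2 * cloud, 0.0, 1.0)
    return float(np.mean(h_o * ratio))


def generate_synthetic_weather(cfg: SyntheticWeatherConfig) -> list[WeatherDay]:
    """Seeded synthetic daily weather reproducing the configured season means.

    Temperature follows a sinusoid peaking in late July plus Gaussian noise;
    cloud and wind are noisy around their means; the diurnal temperature
    range is solved (secant on one scalar) so that the CSRM-implied season
    mean radiation matches ``cfg.mean_radiation`` to well under 2%.
    """
    rng = np.random.default_rng(cfg.seed)
    doys = np.arange(cfg.start_doy, cfg.end_doy + 1)
    n = len(doys)

    # seasonal temperature trend: sinusoid peaking around doy 205 (late July)
    trend = np.cos(2.0 * np.pi * (doys - 205) / 365.0)
    trend = trend - trend.mean()
    tmean = cfg.mean_temperature + cfg.temp_seasonal_amplitude * trend
    t_noise = rng.normal(0.0, cfg.temp_noise, n)
    tmean = tmean + t_noise - t_noise.mean()  # preserve the configured mean exactly

    c_noise = rng.normal(0.0, cfg.cloud_noise, n)
    cloud = np.clip(cfg.mean_cloud + c_noise - c_noise.mean(), 0.0, 1.0)
    if abs(float(cloud.mean()) - cfg.mean_cloud) > 1e-9:  # re-center after clipping
        cloud = np.clip(cloud + (cfg.mean_cloud - cloud.mean()), 0.0, 1.0)

    w_noise = rng.normal(0.0, cfg.wind_noise, n)
    wind = np.clip(cfg.mean_wind + w_noise - w_noise.mean(), 0.1, None)

    rh = np.clip(cfg.mean_rh + rng.normal(0.0, 0.08, n), 0.15, 0.98)

    h_o = np.array(
        [extraterrestrial_radiation(SolarGeometry(cfg.latitude, 113.9, int(d))) for d in doys]
    )

    # solve the base diurnal temperature range so mean(H) hits the target
    lo, hi = 0.5, 40.0
    f_lo = _season_h_mean(lo, cfg, cloud, h_o) - cfg.mean_radiation
    f_hi = _season_h_mean(hi, cfg, cloud, h_o) - cfg.mean_radiation
    if f_lo > 0 or f_hi < 0:
        raise ValueError("configured mean radiation unreachable at this latitude/season")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _season_h_mean(mid, cfg, cloud, h_o) < cfg.mean_radiation:
            lo = mid
        else:
            hi = mid
    dtr = 0.5 * (lo + hi)

    days = []
    for k, d in enumerate(doys):
        days.append(
            WeatherDay(
                doy=int(d),
                tmax=float(tmean[k] + 0.5 * dtr),
                tmin=float(tmean[k] - 0.5 * dtr),
                cloud=float(cloud[k]),
                rh=float(rh[k]),
                co2=cfg.co2_ppm,
                wind=float(wind[k]),
            )
        )
    return days


# --- CSV interface --------------------------------------------------------


def write_weather_csv(days: Sequence[WeatherDay], path) -> None:
    df = pd.DataFrame(
        [[d.doy, d.tmax, d.tmin, d.cloud, d.rh, d.co2, d.wind] for d in days],
        columns=WEATHER_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_weather_csv(path) -> list[WeatherDay]:
    df = pd.read_csv(path)
    missing = set(WEATHER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"weather CSV missing columns: {sorted(missing)}")
    return [
        WeatherDay(
            doy=int(r.doy), tmax=float(r.tmax_c), tmin=float(r.tmin_c),
            cloud=float(r.cloud), rh=float(r.rh), co2=float(r.co2_ppm),
            wind=float(r.wind_ms),
        )
        for r in df.itertuples()
    ]
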