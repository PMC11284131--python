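"""Solar geometry and a clear-sky hourly PAR generator.

The simulation experiment needs hourly incident direct and diffuse PAR over
the maize post-silking season (day of year 200-260) at the latitude of
Beijing (39°56' N).  This module supplies a deterministic clear-sky
stand-in: solar altitude from the standard declination/hour-angle formula,
and a one-parameter atmospheric transmissivity model partitioned into a
fixed diffuse share.  Optional seeded cloudiness noise is available but off
by default so that baseline runs are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WeatherConfig",
    "WeatherSeries",
    "solar_declination",
    "solar_altitude",
    "clear_sky_par",
    "generate_season",
    "read_weather_csv",
    "write_weather_csv",
]

#: photon-flux to energy-flux conversion for PAR, umol photons per joule
UMOL_PER_JOULE = 4.55

#: solar altitudes at or below this (degrees) are treated as night for the
#: direct beam, avoiding the 1/sin(beta) singularity of the extinction law
BETA_NIGHT_DEG = 1.0

#: length of one simulated hourly step, seconds
SECONDS_PER_STEP = 3600.0


def solar_declination(doy: int | np.ndarray) -> np.ndarray:
    """Solar declination (degrees) for a day of year, Cooper's formula."""
    return -23.45 * np.cos(np.radians(360.0 * (np.asarray(doy) + 10.0) / 365.0))


def solar_altitude(latitude: float, doy, hour) -> np.ndarray:
    """Solar altitude angle (degrees) at local solar time.

    sin(beta) = sin(phi) sin(delta) + cos(phi) cos(delta) cos(h), with the
    hour angle h = 15 deg per hour from solar noon.  Symmetric about noon.

    Parameters
    ----------
    latitude : float
        Site latitude in degrees north, in [-90, 90].
    doy : int or array
        Day of year (1-366).
    hour : float or array
        Local solar time in hours, in [0, 24].
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude {latitude} outside [-90, 90]")
    hour = np.asarray(hour, dtype=float)
    if np.any(hour < 0.0) or np.any(hour > 24.0):
        raise ValueError("hour must lie in [0, 24]")
    phi = np.radians(latitude)
    delta = np.radians(solar_declination(doy))
    h = np.radians(15.0 * (hour - 12.0))
    sin_beta = np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.cos(h)
    return np.degrees(np.arcsin(np.clip(sin_beta, -1.0, 1.0)))


def clear_sky_par(
    beta_deg,
    transmissivity: float = 0.70,
    diffuse_fraction: float = 0.23,
    extraterrestrial_par: float = 2900.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Direct and diffuse incident PAR (umol m-2 s-1) for a solar altitude.

    Global PAR follows the classic clear-sky attenuation
    ``I0 * tau**(1/sin(beta)) * sin(beta)`` for beta above the night
    threshold, zero otherwise; a fixed fraction of the global flux is
    diffuse and the remainder is the direct beam.
    """
    if not 0.0 < transmissivity <= 1.0:
        raise ValueError("transmissivity must lie in (0, 1]")
    if not 0.0 <= diffuse_fraction <= 1.0:
        raise ValueError("diffuse_fraction must lie in [0, 1]")
    beta = np.asarray(beta_deg, dtype=float)
    sin_beta = np.sin(np.radians(beta))
    day = beta > BETA_NIGHT_DEG
    with np.errstate(divide="ignore", over="ignore"):
        global_par = np.where(
            day,
            extraterrestrial_par
            * np.power(transmissivity, 1.0 / np.where(day, sin_beta, 1.0))
            * sin_beta,
            0.0,
        )
    diffuse = diffuse_fraction * global_par
    direct = global_par - diffuse
    return direct, diffuse


@dataclass(frozen=True)
class WeatherConfig:
    """Configuration of the synthetic clear-sky season generator."""

    latitude: float = 39.93
    doy_start: int = 200
    doy_end: int = 260
    transmissivity: float = 0.70
    diffuse_fraction: float = 0.23
    extraterrestrial_par: float = 2900.0
    #: hour centers of the simulated steps; 12 steps spanning the nominal
    #: 06:00-18:00 photoperiod of the Beijing post-silking season
    hours: tuple[float, ...] = tuple(np.arange(6.5, 18.0, 1.0))
    #: stddev of multiplicative lognormal cloudiness noise on global PAR
    #: (0 = deterministic clear sky)
    cloud_noise_sd: float = 0.0
    seed: int | None = None


@dataclass(frozen=True)
class WeatherSeries:
    """Hourly direct/diffuse incident PAR plus solar altitude for a season.

    ``frame`` has columns ``doy, hour, par_direct, par_diffuse, beta``,
    strictly ordered by (doy, hour) with no duplicates; PAR columns are
    non-negative and the direct beam is zero whenever the sun is at or
    below the night threshold.
    """

    frame: pd.DataFrame
    season: tuple[int, int]

    def __post_init__(self) -> None:
        f = self.frame
        required = ["doy", "hour", "par_direct", "par_diffuse", "beta"]
        missing = [c for c in required if c not in f.columns]
        if missing:
            raise ValueError(f"weather frame missing columns {missing}")
        if f[["par_direct", "par_diffuse"]].lt(0).any().any():
            bad = f.index[(f.par_direct < 0) | (f.par_diffuse < 0)][0]
            raise ValueError(f"negative PAR at row {bad}")
        key = list(zip(f.doy, f.hour))
        if len(set(key)) != len(key):
            raise ValueError("duplicate (doy, hour) records")
        if key != sorted(key):
            raise ValueError("records not ordered by (doy, hour)")
        if np.any((f.beta.to_numpy() <= BETA_NIGHT_DEG) & (f.par_direct.to_numpy() > 0)):
            raise ValueError("direct PAR positive while sun below horizon threshold")

    @property
    def n_days(self) -> int:
        return self.season[1] - self.season[0] + 1

    @property
    def doys(self) -> np.ndarray:
        return np.arange(self.season[0], self.season[1] + 1)

    def day_index(self) -> np.ndarray:
        """Index of each record's day within the season (0-based)."""
        return self.frame.doy.to_numpy() - self.season[0]


def generate_season(config: WeatherConfig) -> WeatherSeries:
    """Generate one record per simulated hour per day across the season.

    Deterministic given the config (and its seed when cloudiness noise is
    enabled).
    """
    if config.doy_end < config.doy_start:
        raise ValueError("empty season: doy_end < doy_start")
    if len(config.hours) == 0:
        raise ValueError("no simulated hours configured")
    doys = np.arange(config.doy_start, config.doy_end + 1)
    hours = np.asarray(sorted(config.hours), dtype=float)
    dd, hh = np.meshgrid(doys, hours, indexing="ij")
    dd, hh = dd.ravel(), hh.ravel()
    beta = solar_altitude(config.latitude, dd, hh)
    direct, diffuse = clear_sky_par(
        beta,
        config.transmissivity,
        config.diffuse_fraction,
        config.extraterrestrial_par,
    )
    if config.cloud_noise_sd > 0.0:
        rng = np.random.default_rng(config.seed)
        factor = np.exp(rng.normal(-0.5 * config.cloud_noise_sd**2,
                                   config.cloud_noise_sd, size=dd.shape))
        factor = np.minimum(factor, 1.0)
        total = (direct + diffuse) * factor
        # cloud cover raises the diffuse share toward 1 as the sky dims
        f_diff = config.diffuse_fraction + (1.0 - factor) * (1.0 - config.diffuse_fraction)
        diffuse = f_diff * total
        direct = total - diffuse
    frame = pd.DataFrame(
        {
            "doy": dd.astype(int),
            "hour": hh,
            "par_direct": direct,
            "par_diffuse": diffuse,
            "beta": beta,
        }
    )
    return WeatherSeries(frame=frame, season=(config.doy_start, config.doy_end))


def write_weather_csv(series: WeatherSeries, path) -> None:
    series.frame.to_csv(path, index=False)


def read_weather_csv(path, latitude: float = 39.93) -> WeatherSeries:
    """Read a weather CSV (``doy,hour,par_direct,par_diffuse[,beta]``).

    Rows are sorted by (doy, hour); the solar altitude column is recomputed
    from ``latitude`` when absent.  Malformed files raise ``ValueError``
    naming the offending row.
    """
    frame = pd.read_csv(path)
    required = ["doy", "hour", "par_direct", "par_diffuse"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"weather CSV missing columns {missing}")
    neg = frame.index[(frame.par_direct < 0) | (frame.par_diffuse < 0)]
    if len(neg):
        raise ValueError(f"negative PAR in CSV row {neg[0]}")
    dup = frame.duplicated(subset=["doy", "hour"])
    if dup.any():
        raise ValueError(f"duplicate (doy, hour) in CSV row {frame.index[dup][0]}")
    frame = frame.sort_values(["doy", "hour"], kind="mergesort").reset_index(drop=True)
    if "beta" not in frame.columns:
        frame["beta"] = solar_altitude(latitude, frame.doy.to_numpy(), frame.hour.to_numpy())
    frame = frame[["doy", "hour", "par_direct", "par_diffuse", "beta"]]
    return WeatherSeries(frame=frame, season=(int(frame.doy.min()), int(frame.doy.max())))
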