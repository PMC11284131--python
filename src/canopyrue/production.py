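"""Dry matter accumulation and radiation use efficiency.

Daily canopy assimilation is converted to aboveground dry matter via the
CO2 molar mass and a fixed dry-matter yield per unit CO2 (0.41 for
maize); RUE over the season is the ordinary-least-squares slope of
accumulated dry matter on accumulated intercepted PAR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["B_CONV", "CO2_MOLAR_MASS", "SeasonSummary", "dm_day", "rue_slope", "season_summary"]

#: grams of dry matter produced per gram of assimilated CO2 (maize)
B_CONV = 0.41

#: molar mass of CO2, g mol-1
CO2_MOLAR_MASS = 44.0


def dm_day(a_can_day) -> np.ndarray:
    """Daily dry matter (g m-2 d-1) from daily assimilation (umol m-2 d-1)."""
    a = np.asarray(a_can_day, dtype=float)
    if np.any(a < 0):
        raise ValueError("daily assimilation must be non-negative")
    return CO2_MOLAR_MASS * a * B_CONV * 1e-6


def rue_slope(dm_daily, ipar_daily) -> float:
    """RUE (g MJ-1): OLS slope of cumulative dry matter on cumulative PAR.

    Fitted with a free intercept over the season's cumulative series;
    since both series start near zero the slope is close to the ratio of
    the totals, which callers may report alongside as a diagnostic.
    """
    dm = np.asarray(dm_daily, dtype=float)
    ipar = np.asarray(ipar_daily, dtype=float)
    if dm.shape != ipar.shape or dm.ndim != 1:
        raise ValueError("daily series must be 1-d and equally long")
    if np.count_nonzero(ipar > 0) < 2:
        raise ValueError("RUE undefined: fewer than 2 days with intercepted PAR")
    x = np.cumsum(ipar)
    y = np.cumsum(dm)
    x_c = x - x.mean()
    return float(x_c @ (y - y.mean()) / (x_c @ x_c))


@dataclass(frozen=True)
class SeasonSummary:
    """Season totals and RUE for one scenario."""

    adm: float        # accumulated dry matter, g m-2
    cum_ipar: float   # accumulated intercepted PAR, MJ m-2
    rue: float        # g MJ-1 (regression slope)
    rue_ratio: float  # diagnostic: ADM / cumulative intercepted PAR
    n_days: int


def season_summary(dm_daily, ipar_daily) -> SeasonSummary:
    dm = np.asarray(dm_daily, dtype=float)
    ipar = np.asarray(ipar_daily, dtype=float)
    return SeasonSummary(
        adm=float(dm.sum()),
        cum_ipar=float(ipar.sum()),
        rue=rue_slope(dm, ipar),
        rue_ratio=float(dm.sum() / ipar.sum()),
        n_days=len(dm),
    )
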