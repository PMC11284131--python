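"""Multilayer light transfer: projection, extinction, interception.

A black-leaf canopy is assumed: direct and diffuse PAR attenuate as
Beer's-law exponentials of cumulative LAI, with the direct-beam
extinction coefficient set by the azimuth-averaged leaf projection in the
beam direction (Goudriaan's two-branch expression per inclination class)
and a fixed diffuse extinction coefficient of 0.7.  Each layer is split
into a sunlit part receiving direct plus diffuse light and a shaded part
receiving diffuse light only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .solar import BETA_NIGHT_DEG, SECONDS_PER_STEP, UMOL_PER_JOULE, WeatherSeries
from .structure import LIA_CLASS_MIDPOINTS_DEG, LeafAreaProfile, LIADistribution

__all__ = [
    "K_DIFF_DEFAULT",
    "LightField",
    "leaf_projection",
    "canopy_projection",
    "k_dir",
    "attenuate_profile",
    "sunlit_fractions",
    "intercepted_par_daily",
    "compute_light_field",
]

#: PAR extinction coefficient for diffuse radiation
K_DIFF_DEFAULT = 0.7


def leaf_projection(beta_sun_deg, beta_leaf_deg) -> np.ndarray:
    """Mean projection of unit leaf area onto the solar beam, O_av(a).

    Azimuth-averaged projection for leaves of inclination ``beta_leaf``
    under a sun at altitude ``beta_sun`` (both degrees, broadcastable):

    * sun above the leaf plane (beta_sun >= beta_leaf):
      ``sin(beta_sun) cos(beta_leaf)``;
    * otherwise the two-term arcsin/sqrt expression accounting for the
      azimuth range in which the beam strikes the underside.

    Continuous at beta_sun == beta_leaf.
    """
    bs = np.radians(np.asarray(beta_sun_deg, dtype=float))
    bl = np.radians(np.asarray(beta_leaf_deg, dtype=float))
    if np.any(bs <= 0) or np.any(bs > np.pi / 2 + 1e-12):
        raise ValueError("beta_sun must lie in (0, 90] degrees (night handled upstream)")
    if np.any(bl < 0) or np.any(bl > np.pi / 2 + 1e-12):
        raise ValueError("beta_leaf must lie in [0, 90] degrees")
    bs, bl = np.broadcast_arrays(bs, bl)
    high = bs >= bl
    out = np.where(high, np.sin(bs) * np.cos(bl), 0.0)
    if np.any(~high):
        bs_l, bl_l = bs[~high], bl[~high]
        with np.errstate(invalid="ignore"):
            ratio = np.clip(np.tan(bs_l) / np.tan(bl_l), -1.0, 1.0)
            root = np.sqrt(np.maximum(np.sin(bl_l) ** 2 - np.sin(bs_l) ** 2, 0.0))
        low = (2.0 / np.pi) * (np.sin(bs_l) * np.cos(bl_l) * np.arcsin(ratio) + root)
        out[~high] = low
    return out


def canopy_projection(f_a: np.ndarray, beta_sun_deg) -> np.ndarray:
    """Frequency-weighted canopy-mean projection O_av = sum_a f_a O_av(a)."""
    if abs(np.sum(f_a) - 1.0) > 1e-9:
        raise ValueError("class frequencies must sum to 1")
    proj = leaf_projection(
        np.asarray(beta_sun_deg, dtype=float)[..., None], LIA_CLASS_MIDPOINTS_DEG
    )
    return proj @ np.asarray(f_a)


def k_dir(o_av, beta_sun_deg) -> np.ndarray:
    """Direct-beam extinction coefficient K_dir = O_av / sin(beta_sun)."""
    beta = np.asarray(beta_sun_deg, dtype=float)
    if np.any(beta <= BETA_NIGHT_DEG):
        raise ValueError("K_dir undefined at or below the night threshold")
    return np.asarray(o_av) / np.sin(np.radians(beta))


def attenuate_profile(i0, k, clai_bounds) -> np.ndarray:
    """Beer's-law PAR profile I(n) = I(0) exp(-k CLAI_n) at layer boundaries.

    Broadcasts to shape (n_bounds, ...) for time-varying ``i0`` and ``k``.
    """
    clai = np.asarray(clai_bounds, dtype=float)
    if np.any(np.diff(clai) < -1e-12) or clai[0] != 0.0:
        raise ValueError("CLAI boundaries must be non-decreasing from 0")
    i0, k = np.broadcast_arrays(np.asarray(i0, dtype=float), np.asarray(k, dtype=float))
    return i0 * np.exp(-np.multiply.outer(clai, k))


def sunlit_fractions(k_dir_t, clai_bounds) -> np.ndarray:
    """Sunlit leaf fraction per layer, exp(-K_dir * mid-layer CLAI)."""
    clai = np.asarray(clai_bounds, dtype=float)
    mid = 0.5 * (clai[:-1] + clai[1:])
    return np.exp(-np.multiply.outer(mid, np.asarray(k_dir_t, dtype=float)))


@dataclass(frozen=True)
class LightField:
    """Per-layer, per-hour light environment of one canopy structure.

    All arrays are over the T records of the weather series; layered
    arrays have the layer (or boundary) axis first.
    """

    beta: np.ndarray          # (T,) solar altitude, degrees
    i_dir0: np.ndarray        # (T,) incident direct PAR
    i_diff0: np.ndarray       # (T,) incident diffuse PAR
    o_av_class: np.ndarray    # (9, T) per-class projection
    o_av: np.ndarray          # (T,) canopy-mean projection
    k_dir: np.ndarray         # (T,) direct extinction (0 at night)
    i_dir: np.ndarray         # (11, T) direct PAR at boundaries
    i_diff: np.ndarray        # (11, T) diffuse PAR at boundaries
    d_dir: np.ndarray         # (10, T) per-layer absorbed direct PAR
    d_diff: np.ndarray        # (10, T) per-layer absorbed diffuse PAR
    f_sun: np.ndarray         # (10, T) sunlit leaf fraction
    day_index: np.ndarray     # (T,) day within the season
    n_days: int

    @property
    def i_par_t(self) -> np.ndarray:
        """Whole-canopy intercepted PAR per step, umol m-2 s-1."""
        return (self.d_dir + self.d_diff).sum(axis=0)


def compute_light_field(
    profile: LeafAreaProfile,
    lia: LIADistribution,
    weather: WeatherSeries,
    k_diff: float = K_DIFF_DEFAULT,
) -> LightField:
    """Evaluate the full light field of a canopy over a weather series.

    Night steps (solar altitude at or below the threshold) carry zero
    direct flux and a zero K_dir placeholder; the sunlit fraction is
    irrelevant there because the direct beam is zero.
    """
    f = weather.frame
    beta = f.beta.to_numpy(dtype=float)
    i_dir0 = f.par_direct.to_numpy(dtype=float)
    i_diff0 = f.par_diffuse.to_numpy(dtype=float)
    day = beta > BETA_NIGHT_DEG

    proj = leaf_projection(
        np.maximum(beta, BETA_NIGHT_DEG + 1e-9)[None, :],
        LIA_CLASS_MIDPOINTS_DEG[:, None],
    )
    proj = np.where(day, proj, 0.0)
    o_av = lia.f_a @ proj
    sin_beta = np.sin(np.radians(beta))
    kd = np.where(day, o_av / np.where(day, sin_beta, 1.0), 0.0)

    i_dir = attenuate_profile(i_dir0, kd, profile.clai)
    i_diff = attenuate_profile(i_diff0, k_diff, profile.clai)
    return LightField(
        beta=beta,
        i_dir0=i_dir0,
        i_diff0=i_diff0,
        o_av_class=proj,
        o_av=o_av,
        k_dir=kd,
        i_dir=i_dir,
        i_diff=i_diff,
        d_dir=-np.diff(i_dir, axis=0),
        d_diff=-np.diff(i_diff, axis=0),
        f_sun=sunlit_fractions(kd, profile.clai),
        day_index=weather.day_index(),
        n_days=weather.n_days,
    )


def intercepted_par_daily(light: LightField) -> np.ndarray:
    """Daily whole-canopy intercepted PAR, MJ m-2 d-1.

    3600 s per step, divided by 4.55 umol J-1 and scaled to megajoules.
    """
    per_step = light.i_par_t
    daily = np.bincount(light.day_index, weights=per_step, minlength=light.n_days)
    return SECONDS_PER_STEP * daily / UMOL_PER_JOULE * 1e-6
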