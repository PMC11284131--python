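"""Leaf and canopy photosynthesis via the non-rectangular hyperbola.

Sunlit leaves of each inclination class receive the direct beam scaled by
their class projection plus the layer's diffuse flux; shaded leaves see
the diffuse flux only.  Leaf rates are integrated over inclination
classes, sunlit/shaded fractions and layers to the instantaneous canopy
rate, and over the photoperiod to daily canopy assimilation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .light import LightField
from .solar import BETA_NIGHT_DEG, SECONDS_PER_STEP
from .structure import LeafAreaProfile, LIADistribution, NitrogenProfile

__all__ = [
    "PhotoParams",
    "nrh_assimilation",
    "leaf_irradiance",
    "canopy_rate",
    "daily_assimilation",
]


@dataclass(frozen=True)
class PhotoParams:
    """Non-rectangular hyperbola parameters.

    alpha : apparent quantum efficiency, mol CO2 per mol photons.
    theta : curvature; 0 gives the rectangular hyperbola, 1 the Blackman
        (bilinear) limit.
    """

    alpha: float = 0.05
    theta: float = 0.8

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")


def nrh_assimilation(i, amax, params: PhotoParams = PhotoParams()) -> np.ndarray:
    """Gross assimilation (umol CO2 m-2 s-1) at leaf irradiance ``i``.

    Lower root of theta A^2 - (alpha I + Amax) A + alpha I Amax = 0;
    zero at I = 0 and saturating at Amax.  theta = 0 degenerates to the
    rectangular hyperbola alpha I Amax / (alpha I + Amax), theta = 1 to
    min(alpha I, Amax).
    """
    i = np.asarray(i, dtype=float)
    amax = np.asarray(amax, dtype=float)
    if np.any(i < 0):
        raise ValueError("irradiance must be non-negative")
    if np.any(amax < 0):
        raise ValueError("Amax must be non-negative")
    ai = params.alpha * i
    s = ai + amax
    disc = s * s - 4.0 * params.theta * ai * amax
    # lower quadratic root in the cancellation-free form 2p / (s + sqrt(disc)),
    # exact at theta = 0 (rectangular hyperbola) and stable for small theta
    denom = s + np.sqrt(np.maximum(disc, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, 2.0 * ai * amax / np.where(denom > 0, denom, 1.0), 0.0)


def leaf_irradiance(light: LightField, lap: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Leaf-level PAR of sunlit and shaded leaves.

    Shaded leaves see the layer's absorbed diffuse PAR per unit leaf
    area, ``I_sh(n,t) = dI_diff(n,t) / LAP_n``; sunlit leaves of class a
    add the unattenuated direct beam projected onto the leaf,
    ``I_dir(0,t) O_av(a) / sin(beta) = I_dir(0,t) K_dir(a)``.

    Returns ``(i_sun, i_sh)`` with shapes (layers, classes, T) and
    (layers, T).
    """
    lap = np.asarray(lap, dtype=float)
    if np.any((lap <= 0) & (np.abs(light.d_diff).max(axis=1) > 0)):
        raise ValueError("layer with zero leaf area absorbs diffuse PAR")
    i_sh = light.d_diff / lap[:, None]
    day = light.beta > BETA_NIGHT_DEG
    sin_beta = np.sin(np.radians(light.beta))
    beam = np.where(day, light.i_dir0 / np.where(day, sin_beta, 1.0), 0.0)
    i_sun = beam * light.o_av_class  # (9, T)
    return i_sun[None, :, :] + i_sh[:, None, :], i_sh


def canopy_rate(
    profile: LeafAreaProfile,
    lia: LIADistribution,
    light: LightField,
    nitrogen: NitrogenProfile,
    params: PhotoParams = PhotoParams(),
) -> np.ndarray:
    """Instantaneous canopy assimilation (umol CO2 m-2 ground s-1).

    A_can(t) = sum_n LAP_n [f_sun(n,t) sum_a f_a A_sun(n,a,t)
                            + f_sh(n,t) A_sh(n,t)].
    """
    i_sun, i_sh = leaf_irradiance(light, profile.lap)
    a_sun = nrh_assimilation(i_sun, nitrogen.amax[:, None, None], params)
    a_sh = nrh_assimilation(i_sh, nitrogen.amax[:, None], params)
    sun_mean = np.einsum("a,nat->nt", lia.f_a, a_sun)
    per_layer = light.f_sun * sun_mean + (1.0 - light.f_sun) * a_sh
    return profile.lap @ per_layer


def daily_assimilation(a_can_t: np.ndarray, day_index: np.ndarray, n_days: int) -> np.ndarray:
    """Daily canopy CO2 assimilation, umol m-2 d-1 (3600 s per step)."""
    return SECONDS_PER_STEP * np.bincount(
        np.asarray(day_index), weights=np.asarray(a_can_t, dtype=float), minlength=n_days
    )
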