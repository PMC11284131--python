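"""Virtual canopy structure: leaf angles, leaf area and leaf nitrogen.

Three beta-parameterized ingredients define a virtual maize canopy:

* a leaf-inclination-angle (LIA) distribution, discretized into nine 10
  degree classes with frequencies ``f_a``;
* a bell-shaped cumulative leaf-area profile over ten equally spaced
  canopy layers, with the per-layer maximum at a chosen relative depth;
* a leaf-nitrogen allocation over the same ten layers, from which the
  specific leaf nitrogen (SLN, g N m-2 leaf) and the light-saturated
  photosynthetic capacity Amax of each layer follow.

All profiles conserve their totals exactly (frequencies sum to 1, layer
leaf areas to the LAI, layer nitrogen to the per-plant total).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betainc, gammaln

__all__ = [
    "LIA_CLASS_MIDPOINTS_DEG",
    "LIA_MEANS_DEG",
    "AMAX_CEILING",
    "LIADistribution",
    "LeafAreaProfile",
    "NitrogenProfile",
    "beta_normalizer",
    "lia_density",
    "lia_class_frequencies",
    "calibrate_lia",
    "leaf_area_profile",
    "amax_from_sln",
    "nitrogen_profile",
    "nitrogen_distribution_family",
]

N_LIA_CLASSES = 9

#: midpoints of the nine 10-degree LIA classes
LIA_CLASS_MIDPOINTS_DEG = np.arange(5.0, 90.0, 10.0)

#: the 28 candidate mean leaf inclination angles of the scenario family
#: (A1 most planophile ... A28 most erectophile)
LIA_MEANS_DEG = (
    13.30, 14.96, 16.94, 18.92, 21.38, 23.94, 26.52, 29.34, 31.65, 33.84,
    36.49, 39.06, 41.65, 43.74, 46.27, 48.35, 50.94, 53.51, 56.16, 58.35,
    60.66, 63.48, 66.06, 68.62, 71.08, 73.06, 75.04, 76.70,
)

#: asymptote of the SLN -> Amax response, umol CO2 m-2 s-1
#: (7.359 g CO2 m-2 h-1 converted via 1e6 / (44 g mol-1 x 3600 s))
AMAX_CEILING = 7.359e6 / (44.0 * 3600.0)

#: SLN at which the logistic crosses zero, g N m-2 leaf
AMAX_SLN_ZERO = 0.25

AMAX_SLOPE = 4.724


def beta_normalizer(mu: float, nu: float) -> float:
    """Beta function B(mu, nu) = Gamma(mu) Gamma(nu) / Gamma(mu + nu)."""
    if mu <= 0 or nu <= 0:
        raise ValueError("beta shape parameters must be positive")
    return float(np.exp(gammaln(mu) + gammaln(nu) - gammaln(mu + nu)))


def lia_density(b, mu: float, nu: float):
    """Leaf-inclination probability density f(b) on the normalized angle.

    ``b = 2 beta_L / pi`` maps the inclination angle onto (0, 1);
    f(b) = (1 - b)^(mu-1) b^(nu-1) / B(mu, nu).
    """
    if mu <= 0 or nu <= 0:
        raise ValueError("beta shape parameters must be positive")
    b = np.asarray(b, dtype=float)
    if np.any(b <= 0.0) or np.any(b >= 1.0):
        raise ValueError("b must lie strictly in (0, 1)")
    return (1.0 - b) ** (mu - 1.0) * b ** (nu - 1.0) / beta_normalizer(mu, nu)


def lia_class_frequencies(mu: float, nu: float) -> np.ndarray:
    """Class frequencies f_a: integrals of f(b) over the nine 10° classes.

    Class a spans b in [(a-1)/9, a/9]; evaluated with the regularized
    incomplete beta function (note f(b) carries nu on b and mu on 1-b).
    """
    if mu <= 0 or nu <= 0:
        raise ValueError("beta shape parameters must be positive")
    edges = np.linspace(0.0, 1.0, N_LIA_CLASSES + 1)
    cdf = betainc(nu, mu, edges)
    return np.diff(cdf)


def _lia_mean_deg(mu: float, nu: float) -> float:
    # mean of b is nu / (mu + nu) under this parameterization
    return 90.0 * nu / (mu + nu)


@dataclass(frozen=True)
class LIADistribution:
    """Beta-parameterized leaf-inclination-angle distribution."""

    mu: float
    nu: float
    f_a: np.ndarray
    mean_angle: float

    def __post_init__(self) -> None:
        if abs(self.f_a.sum() - 1.0) > 1e-9:
            raise ValueError("class frequencies must sum to 1")
        if np.any(self.f_a < 0):
            raise ValueError("class frequencies must be non-negative")


def calibrate_lia(mean_angle: float, concentration: float = 11.0) -> LIADistribution:
    """Build the LIA distribution with a prescribed density mean.

    Moment matching at fixed concentration ``mu + nu``: the density mean
    is 90 * nu / (mu + nu) degrees, so ``nu = concentration * mean/90``
    and ``mu = concentration - nu`` hit the target exactly.  A common
    concentration across the family keeps the peak sharpness comparable
    between candidate canopies.
    """
    if not 0.0 < mean_angle < 90.0:
        raise ValueError("mean_angle must lie in (0, 90) degrees")
    if concentration <= 2.0:
        raise ValueError("concentration must exceed 2")
    nu = concentration * mean_angle / 90.0
    mu = concentration - nu
    return LIADistribution(
        mu=mu, nu=nu, f_a=lia_class_frequencies(mu, nu),
        mean_angle=_lia_mean_deg(mu, nu),
    )


@dataclass(frozen=True)
class LeafAreaProfile:
    """Bell-shaped vertical leaf-area distribution over canopy layers.

    Depth is normalized (0 at the canopy top, 1 at the bottom);
    ``clai`` holds the cumulative LAI at the 11 layer boundaries and
    ``lap`` the per-layer LAI increments.
    """

    lai: float
    zm_fraction: float
    z_bounds: np.ndarray  # 11 boundary depths, 0 (top) .. 1 (bottom)
    clai: np.ndarray      # cumulative LAI at the boundaries
    lap: np.ndarray       # per-layer LAI (10 values)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.clai) < -1e-9):
            raise ValueError("cumulative LAI must be non-decreasing")
        if abs(self.lap.sum() - self.lai) > 1e-9:
            raise ValueError("layer LAIs must sum to the LAI")

    @property
    def n_layers(self) -> int:
        return len(self.lap)

    @property
    def z_mid(self) -> np.ndarray:
        return 0.5 * (self.z_bounds[:-1] + self.z_bounds[1:])

    @property
    def modal_layer(self) -> int:
        """1-based index of the layer with the greatest leaf area."""
        return int(np.argmax(self.lap)) + 1


def cumulative_lai(z, lai: float, zm_fraction: float):
    """Cumulative LAI at normalized depth z (0 top, 1 bottom).

    CLAI(z) = LAI (1 + (1 - z) / (1 - z_m)) z^(1 / (1 - z_m)), the beta
    growth function anchored at CLAI(0) = 0 and CLAI(1) = LAI, whose
    derivative (the leaf-area density) peaks at z = z_m.
    """
    if not 0.0 < zm_fraction < 1.0:
        raise ValueError("zm_fraction must lie strictly in (0, 1)")
    z = np.asarray(z, dtype=float)
    expo = 1.0 / (1.0 - zm_fraction)
    return lai * (1.0 + (1.0 - z) / (1.0 - zm_fraction)) * z**expo


def leaf_area_profile(lai: float, zm_fraction: float, n_layers: int = 10) -> LeafAreaProfile:
    """Discretize the bell-shaped leaf-area profile into equal-depth layers."""
    if lai <= 0:
        raise ValueError("LAI must be positive")
    z = np.linspace(0.0, 1.0, n_layers + 1)
    clai = cumulative_lai(z, lai, zm_fraction)
    clai[0], clai[-1] = 0.0, lai  # exact anchors
    return LeafAreaProfile(lai=lai, zm_fraction=zm_fraction, z_bounds=z,
                           clai=clai, lap=np.diff(clai))


def amax_from_sln(sln):
    """Light-saturated assimilation rate (umol CO2 m-2 s-1) from SLN.

    A symmetric logistic around SLN = 0.25 g m-2, saturating at
    46.458 umol m-2 s-1; the (unphysical) negative branch below
    0.25 g m-2 is clamped to zero.
    """
    sln = np.asarray(sln, dtype=float)
    if np.any(sln < 0):
        raise ValueError("SLN must be non-negative")
    raw = AMAX_CEILING * (2.0 / (1.0 + np.exp(-AMAX_SLOPE * (sln - AMAX_SLN_ZERO))) - 1.0)
    return np.maximum(raw, 0.0)


@dataclass(frozen=True)
class NitrogenProfile:
    """Per-layer leaf nitrogen, SLN and photosynthetic capacity."""

    fractions: np.ndarray    # share of total leaf N per layer
    lnc_tot_mg: float        # total leaf N per plant, mg
    lnc_mg: np.ndarray       # leaf N per plant per layer, mg
    la_m2: np.ndarray        # leaf area per plant per layer, m2
    sln: np.ndarray          # g N m-2 leaf
    amax: np.ndarray         # umol CO2 m-2 s-1
    rho: float               # plants m-2

    def __post_init__(self) -> None:
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("nitrogen fractions must sum to 1")
        if abs(self.lnc_mg.sum() - self.lnc_tot_mg) > 1e-6:
            raise ValueError("layer nitrogen must sum to the plant total")

    @property
    def modal_layer(self) -> int:
        return int(np.argmax(self.fractions)) + 1


def nitrogen_profile(
    fractions,
    lnc_tot_mg: float,
    profile: LeafAreaProfile,
    rho: float = 6.5,
) -> NitrogenProfile:
    """Distribute a plant's leaf nitrogen over the canopy layers.

    LNC_n = LNC_tot * fraction_n (mg per plant), the layer leaf area per
    plant is LA_n = LAP_n / rho, and SLN_n = LNC_n / LA_n converted to
    g m-2; Amax_n follows from the SLN response.
    """
    fractions = np.asarray(fractions, dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if len(fractions) != profile.n_layers:
        raise ValueError("fraction vector does not match the layer count")
    if np.any((profile.lap <= 0) & (fractions > 0)):
        raise ValueError("positive nitrogen fraction in a layer with no leaf area")
    lnc = lnc_tot_mg * fractions
    la = profile.lap / rho
    with np.errstate(divide="ignore", invalid="ignore"):
        sln_mg = np.where(la > 0, lnc / np.where(la > 0, la, 1.0), 0.0)
    sln = sln_mg / 1000.0  # mg m-2 -> g m-2
    return NitrogenProfile(
        fractions=fractions, lnc_tot_mg=lnc_tot_mg, lnc_mg=lnc,
        la_m2=la, sln=sln, amax=amax_from_sln(sln), rho=rho,
    )


def nitrogen_distribution_family(
    n_distributions: int = 28,
    concentration: float | None = None,
    n_layers: int = 10,
    mode_min: float = 0.24,
    mode_max: float = 0.78,
) -> list[np.ndarray]:
    """Generate the family of candidate leaf-nitrogen allocation vectors.

    Each member is a beta density over normalized canopy depth with its
    mode evenly spaced from the upper canopy (N1) to the lower canopy
    (N28); fractions are per-layer integrals of the density, hence sum
    to 1 exactly, and the mode positions increase strictly across the
    family.

    By default the densities are Beta(1/(1-m), 2) for mode m -- the same
    shape family as the bell-shaped leaf-area profile, whose density is
    Beta(1/(1-z_m), 2) exactly.  With the default mode grid (0.24 to
    0.78 in steps of 0.02) members N4, N9, N14, N19 and N24 replicate
    the vertical pattern of leaf-area peaks at depths 0.3 through 0.7,
    so "matched" nitrogen/leaf-area scenarios have identical profile
    shapes (constant SLN).  Passing ``concentration`` instead builds a
    fixed shape-parameter-sum family with the same modes.
    """
    if n_distributions < 1:
        raise ValueError("need at least one distribution")
    if not 0.0 < mode_min <= mode_max < 1.0:
        raise ValueError("modes must lie in (0, 1) and be ordered")
    modes = np.linspace(mode_min, mode_max, n_distributions)
    edges = np.linspace(0.0, 1.0, n_layers + 1)
    family = []
    for m in modes:
        if concentration is None:
            a = 1.0 / (1.0 - m)   # Beta(a, 2) has mode (a-1)/a = m
            b = 2.0
        else:
            if concentration <= 2.0:
                raise ValueError("concentration must exceed 2 for an interior mode")
            a = 1.0 + m * (concentration - 2.0)   # mode of Beta(a, b) = (a-1)/(a+b-2)
            b = concentration - a
        family.append(np.diff(betainc(a, b, edges)))
    return family
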