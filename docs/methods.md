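# Methods

## Model overview

`canopyrue` implements a one-dimensional, multilayer, sunlit/shaded
canopy photosynthesis model for maize and a factorial simulation
experiment built on top of it. The canopy is a horizontally homogeneous
turbid medium divided into 10 equal-depth layers; leaves are black
(absorptance 1, no scattering beyond the fixed diffuse extinction
coefficient), azimuthally uniform, and share one inclination
distribution at every depth. There is no leaf respiration, no
temperature or CO₂ response, and no senescence: the conversion factor
from assimilated CO₂ to dry matter (0.41 g g⁻¹) implicitly absorbs
respiratory losses, and all structural and nitrogen profiles are held
constant over the simulated season. These assumptions restrict the
model to *comparative* questions — ranking canopy trait combinations by
radiation use efficiency under a common environment — rather than
absolute yield prediction.

## Components

**Solar geometry and weather.** Solar altitude follows the standard
declination/hour-angle formula with Cooper's declination
(δ = −23.45° cos(360(DOY+10)/365)). Clear-sky global PAR is
`I0 · τ^(1/sin β) · sin β`, partitioned into a fixed diffuse fraction.
The day is discretized into 12 hourly steps at hour centers 6.5–17.5
(a 12-hour photoperiod, each step weighted 3600 s), matching the
nominal 06:00–18:00 midsummer photoperiod at the study latitude. Solar
altitudes at or below 1° are treated as night for the direct beam,
avoiding the 1/sin β singularity in the extinction coefficient.

**Canopy structure.** The leaf-inclination density is a two-parameter
beta distribution on the normalized angle b = 2β_L/π, discretized into
nine 10° classes by exact incomplete-beta integrals. Rather than
hand-tuning (μ, ν) per candidate, distributions are calibrated by
moment matching at fixed concentration μ+ν = 11: since the density
mean is 90·ν/(μ+ν) degrees, the target mean fixes both parameters and
a common concentration keeps peak sharpness comparable across the
28-member family (means 13.30°–76.70°). The cumulative leaf-area
profile is the beta growth function
CLAI(z) = LAI·(1+(1−z)/(1−z_m))·z^(1/(1−z_m)); its density is exactly
a Beta(1/(1−z_m), 2) distribution peaking at depth z_m. Canopy depth
is normalized to 1 (only relative depth enters the profile).

**Nitrogen family.** The 28 candidate nitrogen allocations are beta
densities over normalized depth integrated per layer. The default
family uses the same Beta(1/(1−m), 2) shape as the leaf-area density,
with modes m evenly spaced from 0.24 to 0.78 in steps of 0.02, so that
members 4, 9, 14, 19 and 24 replicate exactly the leaf-area patterns
peaking at depths 0.3–0.7. This makes "matched" nitrogen/leaf-area
scenarios well-defined (identical profile shapes, hence constant
specific leaf nitrogen) and keeps top-layer SLN away from zero, which
a steeper family would not (the Amax response clamps to zero below
0.25 g N m⁻², and a canopy whose most illuminated layer has zero
capacity is both unrealistic and an RUE artifact). A
fixed-concentration variant (`n_concentration`) is available for
sensitivity work. Total plant leaf N is 900 mg; per-layer SLN is layer
N divided by per-plant layer leaf area (layer LAI / plant density).

**Light transfer.** Per-class beam projection uses the two-branch
azimuth-averaged expression (sin β cos β_L when the sun is above the
leaf plane, the arcsin/√ correction otherwise); it was verified against
a Monte-Carlo average of |sun · leaf normal| over uniform azimuths to
better than 10⁻³. Cumulative LAI is stored at 11 layer boundaries; the
flux "at the top of layer n" uses boundary n−1 and the sunlit fraction
uses the mid-layer boundary average. Per-layer absorbed flux is the
telescoping boundary difference, so absorbed + transmitted equals
incident to machine precision each step.

**Leaf and canopy photosynthesis.** Leaf assimilation is the lower
root of the non-rectangular hyperbola, evaluated in the
cancellation-free form 2αI·Amax / (αI+Amax + √((αI+Amax)² −
4θαI·Amax)), which is exact in the rectangular (θ=0) and Blackman
(θ=1) limits and numerically stable for extreme θ. Sunlit leaves of
class a receive the unattenuated beam times the class projection over
sin β plus the layer's absorbed diffuse flux per unit leaf area;
shaded leaves receive the diffuse term only. The leaf-to-beam angle
cosine is realized as the azimuth-averaged class projection, the only
operational reading consistent with azimuthal uniformity. Layer rates
are weighted by class frequencies and sunlit/shaded fractions, summed
with layer LAI weights, and integrated over the 12 steps to daily
assimilation.

**Production and RUE.** Daily dry matter is 44 g mol⁻¹ × daily
assimilation × 0.41 × 10⁻⁶; intercepted PAR converts to MJ via
4.55 µmol J⁻¹. Seasonal RUE is the free-intercept OLS slope of
accumulated dry matter on accumulated intercepted PAR. With a free
intercept the slope is within ~10⁻⁹ of the total-ratio under constant
weather; the ratio is reported alongside as a diagnostic.

**Scenario engine.** The full grid (28 × 28 × 5 × 5 = 19,600) is run
with light-field sharing: nitrogen does not affect light transfer, so
each of the 700 (LIA, LAI, leaf-area-pattern) structures is evaluated
once and its 28 nitrogen members are processed in one vectorized pass
(verified bit-identical to the per-scenario path). The full experiment
takes ~25 s on one CPU. Argmax reports break exact ties toward the
smallest id and surface them explicitly.

**Profile analysis.** The light–nitrogen extinction ratio K_N/K_L is
fitted by nonlinear least squares of rel_SLN = rel_PAR^k on
untransformed relative values (initial guess 1), using the total PAR at
layer-top boundaries at the simulated hour nearest noon of a
mid-season day (DOY 230 by default; the hourly grid has no record at
12:00 sharp, and the extraction metadata records the hour used). A
log–log regression slope is reported as a linearized diagnostic. R² is
the squared Pearson correlation; nRMSE is RMSE over the observation
mean.

## Default parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| latitude | 39.93 | °N | Beijing study latitude |
| season | DOY 200–260 | — | maize post-silking period |
| τ (transmissivity) | 0.70 | — | clear-sky atmospheric transmission |
| diffuse fraction | 0.23 | — | diffuse share of global PAR |
| I0 | 2900 | µmol m⁻² s⁻¹ | extraterrestrial PAR (≈ half the solar constant × 4.55 µmol J⁻¹) |
| K_diff | 0.7 | — | diffuse extinction coefficient |
| α | 0.05 | mol CO₂ mol⁻¹ photons | apparent quantum efficiency |
| θ | 0.8 | — | light-response curvature |
| Amax ceiling | 46.458 | µmol CO₂ m⁻² s⁻¹ | logistic asymptote of the SLN response (7.359 g CO₂ m⁻² h⁻¹) |
| LNC_tot | 900 | mg plant⁻¹ | total leaf nitrogen per plant |
| ρ | 6.5 | plants m⁻² | planting density |
| layers | 10 | — | equal-depth canopy layers |
| LAI levels | 3–7 | m² m⁻² | canopy leaf area index factor |
| z_m | 0.3–0.7 | — | leaf-area peak depth factor |

All defaults are overridable through one YAML configuration; unknown
keys are rejected and every grid run writes a `run_manifest.json` with
the resolved configuration and package version.

## What the synthetic weather emulates — and what it does not

The generator produces a deterministic clear-sky hourly direct/diffuse
PAR series for the study latitude and season: midday global PAR
1700–1900 µmol m⁻² s⁻¹ and daily totals declining from ≈11.4 to
≈7.4 MJ m⁻² d⁻¹ across the season — realistic for cloud-free Beijing
midsummer days. It does **not** emulate the multi-year *average* of
measured hourly irradiance that a station record represents: averaging
over cloudy days lowers midday intensity substantially and raises the
diffuse share toward 0.5–0.65. This matters quantitatively for RUE.
With α = 0.05 and 4.55 µmol J⁻¹ the model has a hard efficiency
ceiling of 0.05 × 4.55 × 44 × 0.41 = 4.104 g DM MJ⁻¹, and how closely
a canopy approaches it is set by leaf-level light saturation. Under
the clear-sky default the best canopies reach ≈3.3 g MJ⁻¹ (≈80% of
the ceiling); under a dim, diffuse-rich regime typical of an averaged
record (e.g. τ 0.35–0.45, diffuse fraction 0.55–0.65) the same code
yields ≈3.8–3.9 g MJ⁻¹. Absolute RUE values from the default setup
should therefore be read as clear-sky figures; *rankings and relative
patterns* (which canopy wins, how optima shift with LAI) are robust to
the weather regime, which is what the passing structural tests
establish. An optional seeded multiplicative cloudiness noise (with a
correspondingly increased diffuse share) is available but off by
default to keep baseline runs bit-reproducible.

## Numerical choices

- Incomplete-beta integrals (never quadrature) for all class/layer
  fractions; quadrature appears only as a test oracle.
- Night clamp at β ≤ 1° for the direct beam; such steps carry zero
  direct flux and a zero extinction placeholder.
- Amax is clamped at 0 below SLN = 0.25 g m⁻² (the logistic's negative
  branch has no physical meaning without explicit respiration).
- The NRH root uses the 2p/(s+√disc) form (no catastrophic
  cancellation at small θ).
- Exact argmax ties (floating-point equality within 10⁻¹² relative)
  are broken toward the smallest scenario id and reported.
- Degenerate inputs fail loudly: zero-leaf-area layers with positive
  nitrogen, all-zero-PAR seasons, flat relative-PAR profiles, and
  malformed weather CSVs all raise with the offending row or key named.

## Problem sizes used in tests

The test suite runs the complete 19,600-scenario experiment once
(≈25 s) for the end-to-end checks; unit and property tests use 1–3 day
seasons and small factorial subsets, which exercise every code path at
a fraction of the cost. Monte-Carlo projection oracles use 2 × 10⁶
azimuth samples (standard error ≈ 7 × 10⁻⁴, against a 10⁻³ agreement
bound).

## Known limitations

- No leaf scattering or spectral detail: diffuse extinction is a fixed
  0.7 regardless of canopy structure, and sunlit-leaf irradiance uses
  the geometric projection only.
- Static canopy: no leaf growth, senescence, or nitrogen remobilization
  during grain filling, which biases absolute dry matter upward.
- The sunlit/shaded split ignores penumbra and row structure.
- The RUE regression assumes the whole season contributes one linear
  relationship; strongly non-stationary weather would make the slope
  and the totals ratio diverge.
- The nitrogen family, while anchored to the leaf-area shape family, is
  still a modelling choice; measured maize nitrogen profiles vary more
  irregularly than any two-parameter beta family.
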