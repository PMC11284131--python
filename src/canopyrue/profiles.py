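"""Light-nitrogen profile analysis: the K_N/K_L power law and fit statistics.

Optimization theory predicts that canopy photosynthesis is maximal when
specific leaf nitrogen tracks local light, i.e. when the relative SLN
profile follows the relative PAR profile raised to the power
K_N/K_L = 1.  This module extracts a noon light/SLN profile from a
simulated canopy, fits the exponent by nonlinear least squares, and
provides the R2 / RMSE / nRMSE agreement statistics used to compare
simulated and observed layer profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .engine import ScenarioRun

__all__ = ["ProfileFit", "FitStats", "extract_noon_profile", "fit_kn_kl", "goodness_stats"]


@dataclass(frozen=True)
class ProfileFit:
    """Result of fitting rel_SLN = rel_PAR ** (K_N/K_L)."""

    kn_kl: float
    kn_kl_se: float
    fit_ok: bool
    residual_norm: float
    rel_sln: np.ndarray
    rel_par: np.ndarray
    #: log-log regression slope, a linearized diagnostic alternative
    loglog_slope: float | None = None


@dataclass(frozen=True)
class FitStats:
    """Agreement between observed and simulated layer values."""

    r2: float
    rmse: float
    nrmse: float
    n: int


def extract_noon_profile(
    run: ScenarioRun, doy: int = 230, hour: float = 12.0, exact: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Per-layer relative SLN and relative penetrating PAR near solar noon.

    PAR is the total (direct + diffuse) flux at each layer's top
    boundary, normalized by the above-canopy flux; SLN is normalized by
    the top layer.  With ``exact=False`` the simulated hour closest to
    the request is used (the default hourly grid has no record at 12.0
    sharp); ``exact=True`` requires an exact (doy, hour) record.
    """
    f = run.weather.frame
    day_mask = f.doy.to_numpy() == doy
    if not day_mask.any():
        raise ValueError(f"day {doy} not in the simulated season")
    hours = f.hour.to_numpy()[day_mask]
    if exact:
        if hour not in hours:
            raise ValueError(f"hour {hour} not simulated on day {doy}")
        pick = hour
    else:
        pick = hours[np.argmin(np.abs(hours - hour))]
    (t,) = np.nonzero(day_mask & (f.hour.to_numpy() == pick))
    t = int(t[0])
    par_tops = run.light.i_dir[:-1, t] + run.light.i_diff[:-1, t]
    if par_tops[0] <= 0:
        raise ValueError("no incident PAR at the requested hour")
    rel_par = par_tops / par_tops[0]
    sln = run.nitrogen.sln
    if sln[0] <= 0:
        raise ValueError("top-layer SLN is zero; relative profile undefined")
    return sln / sln[0], rel_par


def fit_kn_kl(rel_sln, rel_par) -> ProfileFit:
    """Estimate K_N/K_L by nonlinear least squares on untransformed values.

    Fits ``rel_sln = rel_par ** k`` with initial guess k = 1.  Layers
    with zero relative PAR are excluded with a warning; degenerate
    profiles (all rel_par equal to 1) raise, since any exponent would
    fit.  Non-convergence is reported via ``fit_ok`` instead of raising.
    """
    rel_sln = np.asarray(rel_sln, dtype=float)
    rel_par = np.asarray(rel_par, dtype=float)
    if rel_sln.shape != rel_par.shape or rel_sln.ndim != 1:
        raise ValueError("profiles must be 1-d and equally long")
    if len(rel_sln) < 3:
        raise ValueError("need at least 3 layers to fit an exponent")
    keep = rel_par > 0
    if not keep.all():
        warnings.warn("excluding layers with zero relative PAR from the fit")
        rel_sln, rel_par = rel_sln[keep], rel_par[keep]
    if np.allclose(rel_par, 1.0):
        raise ValueError("degenerate profile: relative PAR constant at 1")

    def power(x, k):
        return x**k

    try:
        with warnings.catch_warnings():
            # a perfectly flat profile fits with unidentifiable variance
            warnings.simplefilter("ignore", category=OptimizeWarning)
            popt, pcov = curve_fit(power, rel_par, rel_sln, p0=[1.0], maxfev=10000)
        k_hat = float(popt[0])
        se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.nan
        ok = True
    except RuntimeError:
        k_hat, se, ok = np.nan, np.nan, False
    resid = np.nan if not ok else float(np.linalg.norm(rel_par**k_hat - rel_sln))
    interior = (rel_par < 1.0) & (rel_sln > 0)
    loglog = None
    if interior.sum() >= 2:
        loglog = float(np.polyfit(np.log(rel_par[interior]), np.log(rel_sln[interior]), 1)[0])
    return ProfileFit(kn_kl=k_hat, kn_kl_se=se, fit_ok=ok, residual_norm=resid,
                      rel_sln=rel_sln, rel_par=rel_par, loglog_slope=loglog)


def goodness_stats(observed, simulated) -> FitStats:
    """R2 (squared Pearson correlation), RMSE and nRMSE = RMSE / mean(obs)."""
    o = np.asarray(observed, dtype=float)
    s = np.asarray(simulated, dtype=float)
    if o.shape != s.shape or o.ndim != 1 or len(o) == 0:
        raise ValueError("observed and simulated must be equal-length 1-d vectors")
    o_mean = o.mean()
    if o_mean == 0:
        raise ValueError("zero-mean observations: nRMSE undefined")
    rmse = float(np.sqrt(np.mean((s - o) ** 2)))
    o_c, s_c = o - o_mean, s - s.mean()
    denom = np.sqrt((o_c @ o_c) * (s_c @ s_c))
    r2 = float((o_c @ s_c / denom) ** 2) if denom > 0 else 0.0
    return FitStats(r2=r2, rmse=rmse, nrmse=rmse / abs(o_mean), n=len(o))
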