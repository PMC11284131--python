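"""Scenario grid engine: build, run and rank virtual canopies.

The full experiment crosses 28 leaf-inclination distributions (A1-A28),
28 leaf-nitrogen distributions (N1-N28), 5 LAI levels and 5 vertical
leaf-area patterns (P1-P5) into 19,600 scenarios.  Because nitrogen does
not influence light transfer, the light field of each (LIA, LAI, P)
structure is computed once and shared across the 28 nitrogen members,
whose photosynthesis is evaluated in one vectorized pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .light import LightField, compute_light_field, intercepted_par_daily
from .photosynthesis import PhotoParams, canopy_rate, leaf_irradiance, nrh_assimilation
from .production import SeasonSummary, dm_day, season_summary
from .solar import SECONDS_PER_STEP, WeatherSeries
from .structure import (
    LeafAreaProfile,
    LIADistribution,
    NitrogenProfile,
    calibrate_lia,
    leaf_area_profile,
    nitrogen_distribution_family,
    nitrogen_profile,
)

__all__ = [
    "ScenarioSpec",
    "ScenarioRun",
    "GridResult",
    "build_scenario_grid",
    "run_scenario",
    "run_grid",
    "normalize",
    "find_optima",
]

RESULT_COLUMNS = [
    "lia_id", "mean_lia_deg", "n_id", "n_modal_layer", "lai",
    "p_id", "zm_fraction", "lap_modal_layer",
    "adm_g_m2", "cum_ipar_MJ", "rue_g_MJ",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One virtual canopy: LIA family member x N member x LAI x leaf-area pattern."""

    lia_id: str
    mean_lia_deg: float
    n_id: str
    n_index: int          # 0-based index into the nitrogen family
    lai: float
    p_id: str
    zm_fraction: float

    @property
    def key(self) -> tuple:
        return (self.lia_id, self.n_id, self.lai, self.p_id)


def build_scenario_grid(config: RunConfig) -> list[ScenarioSpec]:
    """Full Cartesian product in deterministic (lia, n, lai, zm) order."""
    c = config.canopy
    if not c.lia_means or c.n_distributions < 1:
        raise ValueError("empty factor list")
    grid = []
    for i, mean in enumerate(c.lia_means):
        for j in range(c.n_distributions):
            for lai in c.lai_levels:
                for k, zm in enumerate(c.zm_fractions):
                    grid.append(ScenarioSpec(
                        lia_id=f"A{i + 1}", mean_lia_deg=float(mean),
                        n_id=f"N{j + 1}", n_index=j,
                        lai=float(lai), p_id=f"P{k + 1}", zm_fraction=float(zm),
                    ))
    return grid


@dataclass(frozen=True)
class ScenarioRun:
    """Full per-day / per-hour record of a single scenario simulation."""

    spec: ScenarioSpec
    lia: LIADistribution
    profile: LeafAreaProfile
    nitrogen: NitrogenProfile
    light: LightField
    weather: WeatherSeries
    a_can_t: np.ndarray       # (T,) umol CO2 m-2 ground s-1
    a_can_day: np.ndarray     # (n_days,) umol CO2 m-2 d-1
    dm_daily: np.ndarray      # (n_days,) g m-2 d-1
    ipar_daily: np.ndarray    # (n_days,) MJ m-2 d-1
    summary: SeasonSummary

    def daily_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "doy": self.weather.doys,
            "ipar_day_MJ": self.ipar_daily,
            "acan_day_umol": self.a_can_day,
            "dm_day_g": self.dm_daily,
            "cum_ipar": np.cumsum(self.ipar_daily),
            "cum_dm": np.cumsum(self.dm_daily),
        })

    def structure_frame(self) -> pd.DataFrame:
        """Per-layer structural/functional table of this virtual canopy."""
        p, n = self.profile, self.nitrogen
        return pd.DataFrame({
            "layer": np.arange(1, p.n_layers + 1),
            "z_top": p.z_bounds[:-1],
            "z_bottom": p.z_bounds[1:],
            "clai_top": p.clai[:-1],
            "lap": p.lap,
            "n_fraction": n.fractions,
            "sln": n.sln,
            "amax": n.amax,
        })


def run_scenario(spec: ScenarioSpec, weather: WeatherSeries, config: RunConfig) -> ScenarioRun:
    """Simulate one scenario end to end (reference, non-batched path)."""
    c, p = config.canopy, config.photosynthesis
    lia = calibrate_lia(spec.mean_lia_deg, c.lia_concentration)
    profile = leaf_area_profile(spec.lai, spec.zm_fraction, c.n_layers)
    family = nitrogen_distribution_family(c.n_distributions, c.n_concentration, c.n_layers,
                                          c.n_mode_min, c.n_mode_max)
    nitrogen = nitrogen_profile(family[spec.n_index], c.lnc_tot_mg, profile, c.density)
    light = compute_light_field(profile, lia, weather, p.k_diff)
    params = PhotoParams(alpha=p.alpha, theta=p.theta)
    a_t = canopy_rate(profile, lia, light, nitrogen, params)
    a_day = SECONDS_PER_STEP * np.bincount(light.day_index, weights=a_t, minlength=light.n_days)
    dm = dm_day(a_day)
    ipar = intercepted_par_daily(light)
    return ScenarioRun(
        spec=spec, lia=lia, profile=profile, nitrogen=nitrogen, light=light,
        weather=weather, a_can_t=a_t, a_can_day=a_day, dm_daily=dm,
        ipar_daily=ipar, summary=season_summary(dm, ipar),
    )


@dataclass
class GridResult:
    """One row per scenario, plus any recorded per-scenario failures."""

    frame: pd.DataFrame
    failures: list[tuple[tuple, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frame)


def _cumulative_slopes(y_daily: np.ndarray, x_daily: np.ndarray) -> np.ndarray:
    """OLS slopes of cumsum(y_k) on cumsum(x), vectorized over rows k."""
    x = np.cumsum(x_daily)
    y = np.cumsum(y_daily, axis=-1)
    x_c = x - x.mean()
    denom = x_c @ x_c
    return (y - y.mean(axis=-1, keepdims=True)) @ x_c / denom


def run_grid(
    grid: list[ScenarioSpec],
    weather: WeatherSeries,
    config: RunConfig,
    progress: bool = False,
) -> GridResult:
    """Run every scenario in the grid; bit-identical on rerun.

    Scenarios are grouped by their (LIA, LAI, P) structure so each light
    field is computed once; all nitrogen members of a structure are then
    evaluated in a single vectorized photosynthesis pass.  A failing
    scenario is recorded with its key and does not abort the run.
    """
    keys = [s.key for s in grid]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate scenario ids in grid")
    c, p = config.canopy, config.photosynthesis
    params = PhotoParams(alpha=p.alpha, theta=p.theta)
    family = nitrogen_distribution_family(c.n_distributions, c.n_concentration, c.n_layers,
                                          c.n_mode_min, c.n_mode_max)

    lia_cache: dict[str, LIADistribution] = {}
    groups: dict[tuple, list[ScenarioSpec]] = {}
    for s in grid:
        groups.setdefault((s.lia_id, s.mean_lia_deg, s.lai, s.p_id, s.zm_fraction), []).append(s)

    rows: list[dict] = []
    failures: list[tuple[tuple, str]] = []
    iterator = groups.items()
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm
            iterator = tqdm(iterator, total=len(groups), desc="structures")
        except ImportError:
            pass
    for (lia_id, mean_deg, lai, p_id, zm), members in iterator:
        try:
            if lia_id not in lia_cache:
                lia_cache[lia_id] = calibrate_lia(mean_deg, c.lia_concentration)
            lia = lia_cache[lia_id]
            profile = leaf_area_profile(lai, zm, c.n_layers)
            light = compute_light_field(profile, lia, weather, p.k_diff)
            ipar = intercepted_par_daily(light)
            i_sun, i_sh = leaf_irradiance(light, profile.lap)

            good, nitro = [], []
            for m in members:
                try:
                    nitro.append(nitrogen_profile(family[m.n_index], c.lnc_tot_mg,
                                                  profile, c.density))
                    good.append(m)
                except Exception as exc:  # noqa: BLE001 - per-contract failure capture
                    failures.append((m.key, f"{type(exc).__name__}: {exc}"))
            if not good:
                continue
            members = good
            amax = np.stack([n.amax for n in nitro])             # (K, layers)
            a_sun = nrh_assimilation(i_sun[None], amax[:, :, None, None], params)
            a_sh = nrh_assimilation(i_sh[None], amax[:, :, None], params)
            sun_mean = np.einsum("a,knat->knt", lia.f_a, a_sun)
            per_layer = light.f_sun * sun_mean + (1.0 - light.f_sun) * a_sh
            a_can = np.einsum("n,knt->kt", profile.lap, per_layer)  # (K, T)

            onehot = np.zeros((len(light.day_index), light.n_days))
            onehot[np.arange(len(light.day_index)), light.day_index] = 1.0
            a_day = SECONDS_PER_STEP * (a_can @ onehot)             # (K, days)
            dm = dm_day(a_day)
            rue = _cumulative_slopes(dm, ipar)
            for m, n_prof, adm_k, rue_k in zip(members, nitro, dm.sum(axis=1), rue):
                rows.append({
                    "lia_id": m.lia_id, "mean_lia_deg": m.mean_lia_deg,
                    "n_id": m.n_id, "n_modal_layer": n_prof.modal_layer,
                    "lai": m.lai, "p_id": m.p_id, "zm_fraction": m.zm_fraction,
                    "lap_modal_layer": profile.modal_layer,
                    "adm_g_m2": float(adm_k), "cum_ipar_MJ": float(ipar.sum()),
                    "rue_g_MJ": float(rue_k),
                })
        except Exception as exc:  # noqa: BLE001 - per-contract failure capture
            for m in members:
                failures.append((m.key, f"{type(exc).__name__}: {exc}"))
    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if not frame.empty:
        order = np.lexsort((
            frame.p_id.str.slice(1).astype(int),
            frame.lai.to_numpy(),
            frame.n_id.str.slice(1).astype(int),
            frame.lia_id.str.slice(1).astype(int),
        ))
        frame = frame.iloc[order].reset_index(drop=True)
    return GridResult(frame=frame, failures=failures)


def normalize(result: GridResult) -> GridResult:
    """Add ADM and RUE normalized by their per-LAI grid maxima."""
    frame = result.frame.copy()
    for col, norm in (("adm_g_m2", "adm_norm"), ("rue_g_MJ", "rue_norm")):
        maxima = frame.groupby("lai")[col].transform("max")
        if (maxima <= 0).any():
            raise ValueError("non-positive per-LAI maximum; cannot normalize")
        frame[norm] = frame[col] / maxima
    return GridResult(frame=frame, failures=list(result.failures))


def _argmax_with_ties(frame: pd.DataFrame, by: str = "rue_g_MJ",
                      rtol: float = 1e-12) -> tuple[pd.Series, list[str]]:
    best = frame.loc[frame[by].idxmax()]
    near = frame[np.isclose(frame[by], best[by], rtol=rtol, atol=0.0)]
    ties = []
    if len(near) > 1:
        near = near.sort_values(["lia_id", "n_id"], kind="mergesort")
        ties = [f"{r.lia_id}/{r.n_id}/LAI{r.lai:g}/{r.p_id}" for r in near.itertuples()]
        best = near.iloc[0]
    return best, ties


def find_optima(result: GridResult, metric: str = "rue_g_MJ") -> dict:
    """Locate RUE (or ADM) optima: per (LAI, P) best N, per LAI best LIA, global best.

    Exact ties are broken toward the smallest id and reported under
    ``ties`` rather than hidden.
    """
    frame = result.frame
    if frame.empty:
        raise ValueError("empty grid result")
    report: dict = {"metric": metric, "best_n_per_lai_p": [], "best_lia_per_lai": [], "ties": []}
    for (lai, p_id), sub in frame.groupby(["lai", "p_id"]):
        best, ties = _argmax_with_ties(sub, metric)
        report["best_n_per_lai_p"].append({
            "lai": float(lai), "p_id": p_id, "n_id": best.n_id,
            "n_modal_layer": int(best.n_modal_layer),
            "lap_modal_layer": int(best.lap_modal_layer),
            metric: float(best[metric]),
        })
        report["ties"].extend(ties)
    for lai, sub in frame.groupby("lai"):
        best, ties = _argmax_with_ties(sub, metric)
        report["best_lia_per_lai"].append({
            "lai": float(lai), "lia_id": best.lia_id,
            "mean_lia_deg": float(best.mean_lia_deg), metric: float(best[metric]),
        })
        report["ties"].extend(ties)
    g_best, g_ties = _argmax_with_ties(frame, metric)
    report["global_best"] = {
        "lia_id": g_best.lia_id, "mean_lia_deg": float(g_best.mean_lia_deg),
        "n_id": g_best.n_id, "lai": float(g_best.lai), "p_id": g_best.p_id,
        "zm_fraction": float(g_best.zm_fraction), metric: float(g_best[metric]),
    }
    report["ties"].extend(g_ties)
    return report
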