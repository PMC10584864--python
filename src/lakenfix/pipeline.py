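"""Pipeline driver: rates → features → fluxes → budget → correlations.

Stage order mirrors the analysis: bottle-level rate estimation with
censoring, hydrographic feature extraction per station, depth integration
and turbulent/advective flux estimation, basin budget assembly, and
cross-station Spearman diagnostics.  Every stage is a pure function of its
input tables plus the :class:`~lakenfix.config.PipelineConfig`.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict

import numpy as np
import pandas as pd

from lakenfix import budget as budget_mod
from lakenfix import fluxes as flux_mod
from lakenfix.budget import BudgetTerm, format_budget_table, ratio_diagnostics, total_new_production
from lakenfix.config import PipelineConfig
from lakenfix.correlation import spearman_one_sided
from lakenfix.profiles import DepthProfile, extract_features
from lakenfix.rates import IncubationBottle, nloss_rates, summarize_depth

log = logging.getLogger("lakenfix")


def compute_rates(
    bottles: list[IncubationBottle], config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Replicate-summarised, censored rates per station/depth."""
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    groups: dict[tuple[str, float], dict[str, list[IncubationBottle]]] = {}
    for b in bottles:
        grp = groups.setdefault((b.station, b.depth_m), {"control": [], "treatment": []})
        grp[b.role].append(b)

    rows = []
    for (station, depth), grp in sorted(groups.items()):
        if not grp["treatment"]:
            continue
        control = grp["control"][0] if grp["control"] else None
        pairs = [(control, t) for t in grp["treatment"]]
        est = summarize_depth(pairs, min_excess_permil=config.lod_excess_permil)
        rows.append(
            {
                "station": station,
                "depth_m": depth,
                "rate_nmol_l_d": est.rate,
                "se_nmol_l_d": est.se,
                "censored": est.censored,
                "n_replicates": est.n_replicates,
                "flags": ";".join(est.flags),
            }
        )
    df = pd.DataFrame(rows)
    log.info("rates: %d depth estimates from %d bottles in %.3f s",
             len(df), len(bottles), time.perf_counter() - t0)
    return df


def compute_features(profiles: dict[str, DepthProfile]) -> pd.DataFrame:
    """Hydrographic features, one row per station."""
    t0 = time.perf_counter()
    rows = [asdict(extract_features(profiles[s])) for s in sorted(profiles, key=str)]
    df = pd.DataFrame(rows)
    log.info("features: %d stations in %.3f s", len(df), time.perf_counter() - t0)
    return df


def _nutrient_interface(profile: DepthProfile, analyte: str, zmin: float) -> float | None:
    """Depth of steepest increase of an analyte below ``zmin`` — used to
    place the NH₄⁺ flux interface at the deep nutricline."""
    vals = profile.get(analyte, censored_as=0.0)
    z = profile.depths_m
    ok = np.isfinite(vals) & (z >= zmin)
    if np.sum(ok) < 2:
        return None
    zv, cv = z[ok], vals[ok]
    grad = np.diff(cv) / np.diff(zv)
    i = int(np.argmax(grad))
    if grad[i] <= 0:
        return None
    return float(0.5 * (zv[i] + zv[i + 1]))


def compute_fluxes(
    rates_df: pd.DataFrame,
    profiles: dict[str, DepthProfile],
    features_df: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Station-level areal fluxes (µmol N m⁻² d⁻¹), tidy format.

    Biological integrals use the configured euphotic/anoxic/total
    intervals.  The upward nitrate flux into the euphotic zone is evaluated
    at the thermocline (falling back to the euphotic depth); stations with
    a configured upwelling velocity gain an advective term c·v with c the
    nitrate concentration at the interface.  Nitrate supply into the anoxic
    zone is the magnitude of the diffusive flux across the anoxic boundary,
    and the ammonium flux is evaluated at the deep ammonium nutricline.
    """
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    feats = features_df.set_index("station") if len(features_df) else pd.DataFrame()
    rows = []

    stations = sorted(set(rates_df["station"]) | set(profiles), key=str)
    for station in stations:
        # biological depth integrals
        sub = rates_df[rates_df["station"] == station].sort_values("depth_m")
        if len(sub):
            z = sub["depth_m"].to_numpy(float)
            r = sub["rate_nmol_l_d"].to_numpy(float)
            cens = sub["censored"].to_numpy(bool)
            for name, (z0, z1) in (
                ("nfix_euphotic", config.euphotic_interval_m),
                ("nfix_anoxic", config.anoxic_interval_m),
                ("nfix_total", config.total_interval_m),
            ):
                if np.any((z >= z0) & (z <= z1)):
                    est = flux_mod.depth_integrate(z, r, z0, z1, censored=cens)
                    rows.append(
                        {"station": station, "kind": name, "interface_m": np.nan,
                         "z0_m": z0, "z1_m": z1, "value_umol_m2_d": est.value,
                         "flags": ";".join(est.flags)}
                    )

        if station not in profiles:
            continue
        profile = profiles[station]
        f = feats.loc[station] if station in feats.index else None

        # upward NO3 flux into the euphotic zone at the thermocline
        if profile.has("no3"):
            interface = None
            if f is not None:
                interface = f.get("z_thermocline") or f.get("z_eu")
            if interface is None or not np.isfinite(interface):
                interface = config.euphotic_interval_m[1]
            try:
                grad = flux_mod.gradient_at_interface(
                    profile.depths_m,
                    profile.get("no3", censored_as=0.0),
                    float(interface),
                    config.gradient_window_m,
                )
            except ValueError:
                grad = None
            if grad is not None:
                j = flux_mod.diffusive_flux(grad, config.kz_m2_s, float(interface))
                v = config.upwelling_velocity_m_d.get(str(station), 0.0)
                kind = "no3_flux_euphotic"
                if v > 0:
                    c = float(
                        np.interp(interface, profile.depths_m,
                                  profile.get("no3", censored_as=0.0))
                    )
                    q = flux_mod.total_upward_flux(j, c, v)
                    rows.append(
                        {"station": station, "kind": kind,
                         "interface_m": float(interface), "z0_m": np.nan,
                         "z1_m": np.nan, "value_umol_m2_d": q.value,
                         "flags": "diffusive+advective"}
                    )
                else:
                    rows.append(
                        {"station": station, "kind": kind,
                         "interface_m": float(interface), "z0_m": np.nan,
                         "z1_m": np.nan, "value_umol_m2_d": j.value, "flags": ""}
                    )

        z_anoxic = None
        if f is not None and f.get("z_anoxic") is not None and np.isfinite(f.get("z_anoxic")):
            z_anoxic = float(f["z_anoxic"])
        if z_anoxic is not None and profile.has("no3"):
            try:
                grad = flux_mod.gradient_at_interface(
                    profile.depths_m, profile.get("no3", censored_as=0.0),
                    z_anoxic, config.gradient_window_m,
                )
                j = flux_mod.diffusive_flux(grad, config.kz_m2_s, z_anoxic)
                rows.append(
                    {"station": station, "kind": "no3_flux_anoxic",
                     "interface_m": z_anoxic, "z0_m": np.nan, "z1_m": np.nan,
                     "value_umol_m2_d": abs(j.value), "flags": "magnitude-into-zone"}
                )
            except ValueError:
                pass
        if z_anoxic is not None and profile.has("nh4"):
            nh4_interface = _nutrient_interface(profile, "nh4", z_anoxic)
            if nh4_interface is not None:
                try:
                    grad = flux_mod.gradient_at_interface(
                        profile.depths_m, profile.get("nh4", censored_as=0.0),
                        nh4_interface, config.gradient_window_m,
                    )
                    j = flux_mod.diffusive_flux(grad, config.kz_m2_s, nh4_interface)
                    rows.append(
                        {"station": station, "kind": "nh4_flux_anoxic",
                         "interface_m": nh4_interface, "z0_m": np.nan,
                         "z1_m": np.nan, "value_umol_m2_d": max(j.value, 0.0),
                         "flags": ""}
                    )
                except ValueError:
                    pass

    df = pd.DataFrame(rows)
    log.info("fluxes: %d estimates in %.3f s", len(df), time.perf_counter() - t0)
    return df


_FLUX_TO_BUDGET = {
    "nfix_euphotic": ("euphotic", "n_fixation"),
    "no3_flux_euphotic": ("euphotic", "no3_flux"),
    "nfix_anoxic": ("anoxic", "n_fixation"),
    "no3_flux_anoxic": ("anoxic", "no3_flux"),
    "nh4_flux_anoxic": ("anoxic", "nh4_flux"),
}


def compute_budget(fluxes_df: pd.DataFrame, config: PipelineConfig | None = None) -> dict:
    """Basin budgets from the station flux table; returns budgets plus
    derived totals and diagnostics."""
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    station_fluxes: dict[str, dict] = {}
    for _, row in fluxes_df.iterrows():
        if row["kind"] not in _FLUX_TO_BUDGET:
            continue
        key = _FLUX_TO_BUDGET[row["kind"]]
        station_fluxes.setdefault(str(row["station"]), {})[key] = row["value_umol_m2_d"]

    budgets = budget_mod.assemble_budget(
        station_fluxes, basin_map=config.basin_map, external=config.external_inputs
    )
    for basin, value in config.n_removal_mmol.items():
        if basin in budgets:
            budgets[basin].anoxic["n_removal"] = BudgetTerm(value=float(value))

    derived = {}
    for basin, bb in budgets.items():
        entry = {"total_new_production": total_new_production(bb).value}
        entry.update(
            {k: v for k, v in ratio_diagnostics(bb).items() if k != "flags"}
        )
        derived[basin] = entry
    log.info("budget: %d basins in %.3f s", len(budgets), time.perf_counter() - t0)
    return {"budgets": budgets, "derived": derived,
            "table": format_budget_table(budgets, config.reporting_decimals)}


def compute_correlations(
    fluxes_df: pd.DataFrame,
    colonies: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cross-station Spearman diagnostics (one-sided, a-priori directions).

    Pairs the upward nitrate flux against depth-integrated fixation and
    against depth-integrated colony abundance (both expected to decline
    with increasing nitrate supply), and colony abundance against fixation
    (expected positive).
    """
    wide = fluxes_df.pivot_table(
        index="station", columns="kind", values="value_umol_m2_d", aggfunc="first"
    )
    series: dict[str, pd.Series] = {}
    if "no3_flux_euphotic" in wide:
        series["no3_flux"] = wide["no3_flux_euphotic"]
    if "nfix_total" in wide:
        series["nfix_integrated"] = wide["nfix_total"]
    if colonies is not None and len(colonies):
        col_int = {}
        for station, grp in colonies.groupby("station"):
            grp = grp.sort_values("depth_m")
            col_int[str(station)] = float(
                np.trapezoid(grp["colonies_per_ml"], grp["depth_m"])
            )
        series["colonies_integrated"] = pd.Series(col_int)

    tests = [
        ("no3_flux", "nfix_integrated", "negative"),
        ("no3_flux", "colonies_integrated", "negative"),
        ("colonies_integrated", "nfix_integrated", "positive"),
    ]
    rows = []
    for xname, yname, direction in tests:
        if xname not in series or yname not in series:
            continue
        pair = pd.concat([series[xname], series[yname]], axis=1, keys=["x", "y"]).dropna()
        if len(pair) < 4:
            continue
        res = spearman_one_sided(pair["x"], pair["y"], direction)
        rows.append(
            {"x": xname, "y": yname, "direction": direction, "n": res["n"],
             "rho": res["rho"], "r_squared": res["r_squared"], "p": res["p"],
             "method": res["method"], "significant_95": res["significant_95"],
             "significant_80": res["significant_80"]}
        )
    return pd.DataFrame(rows)


def compute_nloss(timeseries: dict) -> pd.DataFrame:
    """²⁹/³⁰N₂ production slopes per station."""
    rows = []
    for station in sorted(timeseries, key=str):
        res = nloss_rates(timeseries[station])
        rows.append({"station": station, "experiment": timeseries[station].experiment, **res})
    return pd.DataFrame(rows)


def run_pipeline(
    bottles: list[IncubationBottle],
    profiles: dict[str, DepthProfile],
    config: PipelineConfig | None = None,
    timeseries: dict | None = None,
    colonies: pd.DataFrame | None = None,
) -> dict:
    """Run every stage; returns a dict of output tables.

    Keys: ``rates``, ``features``, ``fluxes``, ``nloss`` (when time series
    are given), ``budgets``/``derived``/``table`` from the budget stage,
    and ``correlations``.  Deterministic given identical inputs.
    """
    config = config or PipelineConfig()
    rates_df = compute_rates(bottles, config)
    features_df = compute_features(profiles)
    fluxes_df = compute_fluxes(rates_df, profiles, features_df, config)
    out = {
        "rates": rates_df,
        "features": features_df,
        "fluxes": fluxes_df,
        "correlations": compute_correlations(fluxes_df, colonies),
    }
    if timeseries:
        out["nloss"] = compute_nloss(timeseries)
    out.update(compute_budget(fluxes_df, config))
    return out
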