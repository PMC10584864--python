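"""Synthetic expedition data with known ground truth.

Generates the four data products the pipeline consumes — depth profiles,
¹⁵N₂ incubation bottles, ²⁹/³⁰N₂ time series and cyanobacteria colony
counts — from regime templates describing the two hydrodynamic end members
of a deep meromictic rift lake:

* ``stratified`` (northern/central basin): deep thermocline (~55 m),
  surface chlorophyll maximum, deep oxygen-deficient boundary (~115 m) and
  a deep anoxic chlorophyll maximum sustained by anoxygenic phototrophs;
* ``upwelling`` (southern basin): shallow thermocline (~20 m) pushed up by
  trade-wind upwelling, a deeper oxycline (~135 m) and no anoxic maximum.

Profile shapes are sigmoid (temperature, oxygen, nutrients), Gaussian
(chlorophyll peaks) and exponential (PAR).  Measurement noise is additive
Gaussian on δ¹⁵N (IRMS precision) and temperature, and multiplicative
lognormal on concentrations; below-detection values are censored at the
analytes' detection limits.  Treatment-bottle enrichments are obtained by
inverting the tracer mass balance at the imposed true rate, so every
generated observable has a stored truth and a single integer seed fully
determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lakenfix.fluxes import depth_integrate
from lakenfix.isotopes import R_AIR, atom_percent_from_delta, delta_from_atom_percent
from lakenfix.profiles import DEFAULT_DETECTION_LIMITS, DepthProfile
from lakenfix.rates import IncubationBottle, N2TimeSeries

#: Measured labelling strength of the N₂ pool by campaign, atom % ¹⁵N.
LABEL_AT_PERCENT_2017 = 4.7
LABEL_AT_PERCENT_2018 = 6.3

#: Default IRMS noise on δ¹⁵N, ‰ (standard reproducibility better than 0.5 ‰).
DEFAULT_IRMS_SIGMA_PERMIL = 0.25


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class RegimeTemplate:
    """Parametric description of one hydrodynamic regime's water column."""

    regime: str  # "stratified" | "upwelling"
    thermocline_depth_m: float
    euphotic_depth_m: float
    nitracline_depth_m: float
    nitrate_max_um: float = 8.5
    srp_surface_um: float = 0.15
    srp_max_um: float = 1.4
    o2_surface_um: float = 250.0
    o2_deficiency_depth_m: float = 115.0
    chl_peaks: list[tuple[float, float, float]] = field(default_factory=list)
    chl_baseline: float = 0.15
    acm_present: bool = True
    surface_temp_c: float = 27.0
    deep_temp_c: float = 23.6
    thermocline_width_m: float = 4.0
    noise: dict[str, float] = field(
        default_factory=lambda: {
            "conc_lognorm_sigma": 0.05,
            "temp_sigma_c": 0.05,
            "d15n_sigma_permil": DEFAULT_IRMS_SIGMA_PERMIL,
            "par_lognorm_sigma": 0.02,
        }
    )

    def __post_init__(self):
        for name in ("thermocline_depth_m", "euphotic_depth_m", "nitracline_depth_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for zc, amp, width in self.chl_peaks:
            if amp < 0 or width <= 0 or zc < 0:
                raise ValueError("chlorophyll peaks need depth >= 0, amp >= 0, width > 0")


def stratified_template(**overrides) -> RegimeTemplate:
    """Northern/central-basin end member: deep thermocline, surface
    chlorophyll maximum and a deep anoxic chlorophyll maximum."""
    params = dict(
        regime="stratified",
        thermocline_depth_m=55.0,
        euphotic_depth_m=46.0,
        nitracline_depth_m=50.0,
        o2_deficiency_depth_m=115.0,
        chl_peaks=[(12.0, 0.8, 12.0), (150.0, 1.0, 8.0)],
        acm_present=True,
    )
    params.update(overrides)
    return RegimeTemplate(**params)


def upwelling_template(**overrides) -> RegimeTemplate:
    """Southern-basin end member: shallow wind-lifted thermocline, deeper
    oxycline, productive mid-depth chlorophyll maximum, no anoxic maximum."""
    params = dict(
        regime="upwelling",
        thermocline_depth_m=20.0,
        euphotic_depth_m=30.0,
        nitracline_depth_m=30.0,
        o2_deficiency_depth_m=135.0,
        chl_peaks=[(25.0, 1.8, 10.0)],
        acm_present=False,
        srp_surface_um=0.30,
    )
    params.update(overrides)
    return RegimeTemplate(**params)


def generate_profile(
    template: RegimeTemplate,
    depths_m=None,
    seed=0,
    station: str = "synthetic",
) -> DepthProfile:
    """Draw one noisy depth profile from a regime template.

    With all noise levels set to zero the profile equals the template's
    analytic curves exactly.  Below-detection nutrient values are stored at
    the detection limit with the censored flag set.
    """
    rng = _rng(seed)
    z = np.asarray(
        depths_m if depths_m is not None else np.arange(0.0, 201.0, 10.0), dtype=float
    )
    t = template
    noise = t.noise

    temp = t.deep_temp_c + (t.surface_temp_c - t.deep_temp_c) * _sigmoid(
        (t.thermocline_depth_m - z) / t.thermocline_width_m
    )
    k_par = np.log(100.0) / t.euphotic_depth_m
    par = 100.0 * np.exp(-k_par * z)
    w_o2 = 8.0
    z0_o2 = t.o2_deficiency_depth_m - w_o2 * np.log(t.o2_surface_um / 10.0 - 1.0)
    o2 = t.o2_surface_um / (1.0 + np.exp((z - z0_o2) / w_o2))
    no3 = (
        t.nitrate_max_um
        * _sigmoid((z - t.nitracline_depth_m) / 6.0)
        * _sigmoid((160.0 - z) / 10.0)
    )
    srp = t.srp_surface_um + t.srp_max_um * _sigmoid((z - 55.0) / 10.0)
    nh4 = 0.10 + 2.5 * _sigmoid((z - 155.0) / 8.0)
    chl = t.chl_baseline + sum(
        amp * np.exp(-((z - zc) ** 2) / (2.0 * width**2)) for zc, amp, width in t.chl_peaks
    )
    pon = 8.0 + 20.0 * chl  # ug N / L, tracks biomass
    d15n_pon = 1.4 - 1.7 * _sigmoid((50.0 - z) / 8.0)

    s_conc = noise.get("conc_lognorm_sigma", 0.0)
    if s_conc > 0:
        for arr in (o2, no3, srp, nh4, chl, pon):
            arr *= rng.lognormal(0.0, s_conc, size=z.size)
    if noise.get("temp_sigma_c", 0.0) > 0:
        temp = temp + rng.normal(0.0, noise["temp_sigma_c"], size=z.size)
    if noise.get("par_lognorm_sigma", 0.0) > 0:
        par = par * rng.lognormal(0.0, noise["par_lognorm_sigma"], size=z.size)
    if noise.get("d15n_sigma_permil", 0.0) > 0:
        d15n_pon = d15n_pon + rng.normal(0.0, noise["d15n_sigma_permil"], size=z.size)

    properties = {
        "temperature": temp,
        "o2": o2,
        "no3": no3,
        "srp": srp,
        "nh4": nh4,
        "chl": chl,
        "par": par,
        "pon": pon,
        "d15n_pon": d15n_pon,
    }
    censored = {}
    for analyte, lod in DEFAULT_DETECTION_LIMITS.items():
        if analyte in properties:
            mask = properties[analyte] < lod
            properties[analyte] = np.where(mask, lod, properties[analyte])
            censored[analyte] = mask
    return DepthProfile(
        station=station,
        depths_m=z,
        properties=properties,
        censored=censored,
        detection_limits=dict(DEFAULT_DETECTION_LIMITS),
    )


def generate_incubation(
    true_rate_nmol_l_d: float,
    pon_conc_ug_l: float = 14.0,
    label_at_percent: float = LABEL_AT_PERCENT_2018,
    duration_d: float = 1.0,
    irms_sigma_permil: float = DEFAULT_IRMS_SIGMA_PERMIL,
    n_treatments: int = 2,
    seed=0,
    station: str = "synthetic",
    depth_m: float = 0.0,
    volume_l: float = 4.5,
    natural_delta_permil: float = -0.3,
) -> list[IncubationBottle]:
    """Control + duplicate treatment bottles for one imposed true rate.

    The treatment δ¹⁵N is set by inverting the tracer mass balance at the
    true rate, then IRMS noise is added; with zero noise the rate
    estimator recovers the truth exactly.  Raises when the imposed rate
    would require PON enrichment at or beyond the labelled N₂ pool within
    the incubation (physically infeasible).
    """
    if true_rate_nmol_l_d < 0:
        raise ValueError("true rate cannot be negative")
    if pon_conc_ug_l <= 0 or duration_d <= 0 or volume_l <= 0:
        raise ValueError("pon_conc, duration and volume must be positive")
    rng = _rng(seed)

    from lakenfix.rates import N_ATOMIC_MASS

    pon_nmol_l = pon_conc_ug_l * 1000.0 / N_ATOMIC_MASS
    ap_control = atom_percent_from_delta(natural_delta_permil, R_AIR)
    # invert the mass balance: ap_sample from the imposed rate
    ap_sample = ap_control + true_rate_nmol_l_d * duration_d / pon_nmol_l * (
        label_at_percent - ap_control
    )
    if ap_sample >= label_at_percent:
        raise ValueError(
            f"true rate {true_rate_nmol_l_d} nmol/L/d would enrich PON to "
            f"{ap_sample:.2f} at% >= the labelled pool ({label_at_percent} at%)"
        )
    delta_sample = delta_from_atom_percent(ap_sample, R_AIR)

    bottles = [
        IncubationBottle(
            station=station,
            depth_m=depth_m,
            role="control",
            delta15n_pon=natural_delta_permil + rng.normal(0.0, irms_sigma_permil),
            pon_mass_ug=pon_conc_ug_l * volume_l,
            volume_l=volume_l,
            duration_d=duration_d,
        )
    ]
    for _ in range(n_treatments):
        bottles.append(
            IncubationBottle(
                station=station,
                depth_m=depth_m,
                role="treatment",
                delta15n_pon=delta_sample + rng.normal(0.0, irms_sigma_permil),
                pon_mass_ug=pon_conc_ug_l * volume_l,
                volume_l=volume_l,
                duration_d=duration_d,
                label_atom_percent=label_at_percent,
            )
        )
    return bottles


def generate_n2_timeseries(
    p29_nmol_l_d: float,
    p30_nmol_l_d: float,
    times_d=(0.0, 0.25, 0.5, 0.75, 1.0, 1.25),
    sigma_nmol_l: float = 0.05,
    seed=0,
    experiment: str = "15NO3",
) -> N2TimeSeries:
    """Linear ²⁹/³⁰N₂ production with additive Gaussian noise."""
    rng = _rng(seed)
    t = np.asarray(times_d, dtype=float)
    c29 = p29_nmol_l_d * t
    c30 = p30_nmol_l_d * t
    if sigma_nmol_l > 0:
        c29 = c29 + rng.normal(0.0, sigma_nmol_l, size=t.size)
        c30 = c30 + rng.normal(0.0, sigma_nmol_l, size=t.size)
    return N2TimeSeries(experiment=experiment, times_d=t, conc_29n2=c29, conc_30n2=c30)


# ---------------------------------------------------------------------------
# Whole-expedition generator
# ---------------------------------------------------------------------------

#: True volumetric fixation-rate field parameters per regime
#: (euphotic peak nmol/L/d, anoxic peak nmol/L/d).  The stratified:upwelling
#: euphotic contrast is 5x, matching the basin-scale contrast observed
#: between permanently stratified and upwelling-influenced conditions.
TRUE_EUPHOTIC_PEAK = {"stratified": 10.0, "upwelling": 2.0}
TRUE_ANOXIC_PEAK = {"stratified": 0.5, "upwelling": 0.1}
#: Between-station lognormal scatter on the rate-field amplitude.
STATION_SIGMA = 0.1

INCUBATION_DEPTHS_M = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 125.0, 145.0, 160.0, 175.0)


def true_rate_field(
    z, euphotic_peak: float, anoxic_peak: float
) -> np.ndarray:
    """Imposed volumetric fixation-rate field (nmol L⁻¹ d⁻¹): a surface
    bloom peak at 20 m and a small deep peak at 145 m."""
    z = np.asarray(z, dtype=float)
    return euphotic_peak * np.exp(-((z - 20.0) ** 2) / (2.0 * 12.0**2)) + (
        anoxic_peak * np.exp(-((z - 145.0) ** 2) / (2.0 * 8.0**2))
    )


@dataclass
class SyntheticTruth:
    """Imposed ground truth stored alongside the generated observations."""

    seed: int
    station_regime: dict[str, str]
    station_rate_fields: dict[str, pd.DataFrame]  # depth_m, true_rate
    true_euphotic_integrals: dict[str, float]  # umol m^-2 d^-1, 0-50 m
    true_anoxic_integrals: dict[str, float]  # umol m^-2 d^-1, 125-175 m
    true_contrast_ratio: float  # stratified / upwelling basin-mean euphotic


@dataclass
class SyntheticExpedition:
    """One complete synthetic field campaign plus its ground truth."""

    profiles: dict[str, DepthProfile]
    incubations: list[IncubationBottle]
    timeseries: dict[str, N2TimeSeries]
    colonies: pd.DataFrame
    truth: SyntheticTruth


def generate_expedition(
    seed: int = 0,
    n_north: int = 6,
    n_south: int = 3,
    label_at_percent: float = LABEL_AT_PERCENT_2018,
    irms_sigma_permil: float = DEFAULT_IRMS_SIGMA_PERMIL,
    station_sigma: float = STATION_SIGMA,
    incubation_depths_m=INCUBATION_DEPTHS_M,
) -> SyntheticExpedition:
    """Generate a full transect: stratified stations then upwelling stations.

    Stations are labelled "1"…"n"; the first ``n_north`` use the
    stratified template (5× higher imposed euphotic fixation), the rest
    the upwelling template.  A single seed drives one split RNG stream per
    data product, so output is reproducible byte for byte.
    """
    ss = np.random.SeedSequence(seed)
    rng_profiles, rng_inc, rng_ts, rng_col, rng_amp = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    stations = [str(i + 1) for i in range(n_north + n_south)]
    regimes = {
        s: ("stratified" if i < n_north else "upwelling")
        for i, s in enumerate(stations)
    }

    profiles: dict[str, DepthProfile] = {}
    incubations: list[IncubationBottle] = []
    timeseries: dict[str, N2TimeSeries] = {}
    colony_rows = []
    rate_fields: dict[str, pd.DataFrame] = {}
    eu_int: dict[str, float] = {}
    an_int: dict[str, float] = {}

    inc_z = np.asarray(incubation_depths_m, dtype=float)
    for station in stations:
        regime = regimes[station]
        template = stratified_template() if regime == "stratified" else upwelling_template()
        profiles[station] = generate_profile(template, seed=rng_profiles, station=station)

        amp = float(rng_amp.lognormal(0.0, station_sigma)) if station_sigma > 0 else 1.0
        rates_true = amp * true_rate_field(
            inc_z, TRUE_EUPHOTIC_PEAK[regime], TRUE_ANOXIC_PEAK[regime]
        )
        rate_fields[station] = pd.DataFrame(
            {"depth_m": inc_z, "true_rate_nmol_l_d": rates_true}
        )
        eu_int[station] = depth_integrate(inc_z, rates_true, 0.0, 50.0).value
        an_int[station] = depth_integrate(inc_z, rates_true, 125.0, 175.0).value

        pon_profile = profiles[station]
        for z, r_true in zip(inc_z, rates_true):
            pon_ug_l = float(
                np.interp(z, pon_profile.depths_m, pon_profile.get("pon"))
            )
            incubations.extend(
                generate_incubation(
                    true_rate_nmol_l_d=float(r_true),
                    pon_conc_ug_l=pon_ug_l,
                    label_at_percent=label_at_percent,
                    irms_sigma_permil=irms_sigma_permil,
                    seed=rng_inc,
                    station=station,
                    depth_m=float(z),
                )
            )

        p29, p30 = (0.30, 0.15) if regime == "stratified" else (0.10, 0.05)
        timeseries[station] = generate_n2_timeseries(p29, p30, seed=rng_ts)

        # filamentous cyanobacteria track the imposed surface fixation bloom
        col_peak = 22.0 * amp * (1.0 if regime == "stratified" else 0.05)
        for z in inc_z[inc_z <= 125.0]:
            density = col_peak * np.exp(-((z - 20.0) ** 2) / (2.0 * 12.0**2))
            density = max(0.0, density + rng_col.normal(0.0, 0.3))
            colony_rows.append(
                {
                    "station": station,
                    "depth_m": float(z),
                    "colonies_per_ml": float(density),
                    "cells_per_colony": 30.0,
                }
            )

    north = [s for s in stations if regimes[s] == "stratified"]
    south = [s for s in stations if regimes[s] == "upwelling"]
    contrast = float(
        np.mean([eu_int[s] for s in north]) / np.mean([eu_int[s] for s in south])
    )
    truth = SyntheticTruth(
        seed=seed,
        station_regime=regimes,
        station_rate_fields=rate_fields,
        true_euphotic_integrals=eu_int,
        true_anoxic_integrals=an_int,
        true_contrast_ratio=contrast,
    )
    return SyntheticExpedition(
        profiles=profiles,
        incubations=incubations,
        timeseries=timeseries,
        colonies=pd.DataFrame(colony_rows),
        truth=truth,
    )
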