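"""Hydrographic feature extraction from vertical station profiles.

A :class:`DepthProfile` holds one station's discretely sampled water-column
properties (temperature, oxygen, nutrients, chlorophyll, PAR, PON and its
δ¹⁵N) on a strictly increasing depth grid, metres positive downward, with
per-analyte detection-limit censoring.  Features extracted from it:

* euphotic depth — 1 % surface-irradiance horizon, log-linear interpolated;
* thermocline — midpoint of the sampling interval of maximum |dT/dz|;
* oxygen boundaries — first crossings of the 10 µM (oxygen-deficient) and
  1 µM (anoxic) horizons, linearly interpolated;
* chlorophyll maxima — primary maximum above the anoxic boundary and, when
  sufficiently prominent, a deep anoxic chlorophyll maximum below it;
* N:P classification — fraction of samples with molar DIN:SRP below the
  Redfield ratio of 16.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EUPHOTIC_CUTOFF = 0.01  # fraction of surface irradiance
ANOXIC_O2_UM = 1.0
DEFICIENT_O2_UM = 10.0
REDFIELD_NP = 16.0

#: Nominal analytical detection limits, µM (chl in µg L⁻¹), used when a
#: profile does not declare its own.
DEFAULT_DETECTION_LIMITS = {"no3": 0.20, "srp": 0.22, "nh4": 0.34, "no2": 0.03}


@dataclass
class DepthProfile:
    """One station's sampled vertical property grid.

    ``properties`` maps analyte names (``temperature``, ``o2``, ``no3``,
    ``srp``, ``nh4``, ``no2``, ``chl``, ``par``, ``pon``, ``d15n_pon``) to
    per-depth arrays; ``censored`` marks below-detection observations whose
    stored value is the analyte's detection limit.  Depths are sorted and
    exact duplicate depths collapsed on construction, so feature extraction
    is invariant to duplicated rows.
    """

    station: str
    depths_m: np.ndarray
    properties: dict[str, np.ndarray]
    censored: dict[str, np.ndarray] = field(default_factory=dict)
    detection_limits: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        z = np.asarray(self.depths_m, dtype=float)
        if z.size == 0:
            raise ValueError("profile needs at least one sampled depth")
        order = np.argsort(z, kind="stable")
        z = z[order]
        props = {k: np.asarray(v, dtype=float)[order] for k, v in self.properties.items()}
        cens = {
            k: np.asarray(v, dtype=bool)[order] for k, v in self.censored.items()
        }
        keep = np.concatenate(([True], np.diff(z) > 0))
        self.depths_m = z[keep]
        self.properties = {k: v[keep] for k, v in props.items()}
        self.censored = {k: v[keep] for k, v in cens.items()}
        for k, v in self.properties.items():
            if v.size != self.depths_m.size:
                raise ValueError(f"property {k!r} length does not match depths")
        self.detection_limits = {**DEFAULT_DETECTION_LIMITS, **self.detection_limits}

    def get(self, analyte: str, censored_as: float | None = None) -> np.ndarray:
        """Values of one analyte; censored entries optionally substituted."""
        vals = np.array(self.properties[analyte], dtype=float)
        if censored_as is not None and analyte in self.censored:
            vals[self.censored[analyte]] = censored_as
        return vals

    def has(self, analyte: str) -> bool:
        return analyte in self.properties and np.any(np.isfinite(self.properties[analyte]))


@dataclass(frozen=True)
class ProfileFeatures:
    """Extracted hydrographic features; ``None`` marks an absent feature."""

    station: str
    z_eu: float | None
    z_thermocline: float | None
    z_anoxic: float | None
    z_deficient: float | None
    pcm_depth: float | None
    acm_depth: float | None
    tc_minus_zeu: float | None
    frac_below_redfield: float | None


def euphotic_depth(profile: DepthProfile, cutoff: float = EUPHOTIC_CUTOFF) -> float | None:
    """Depth where PAR first falls to ``cutoff`` of the surface value.

    Light decays exponentially, so the crossing between bracketing samples
    is located by log-linear interpolation.  Returns ``None`` when the
    profile never dims to the cutoff; raises on a single-depth PAR profile.
    """
    par = profile.get("par")
    z = profile.depths_m
    ok = np.isfinite(par)
    par, z = par[ok], z[ok]
    if par.size < 2:
        raise ValueError("euphotic depth needs PAR at two or more depths")
    if par[0] <= 0:
        raise ValueError("surface PAR must be positive")
    frac = par / par[0]
    below = np.nonzero(frac <= cutoff)[0]
    if below.size == 0:
        return None
    i = below[0]
    if i == 0:
        return float(z[0])
    f0, f1 = frac[i - 1], frac[i]
    if f1 <= 0:
        return float(z[i])
    # log-linear: ln(frac) is linear in depth between samples
    w = (np.log(f0) - np.log(cutoff)) / (np.log(f0) - np.log(f1))
    return float(z[i - 1] + w * (z[i] - z[i - 1]))


def thermocline_depth(
    profile: DepthProfile, min_gradient_c_per_m: float = 0.01
) -> float | None:
    """Midpoint of the sampling interval with maximum |dT/dz|.

    Ties resolve to the shallowest interval.  An effectively isothermal
    profile (max gradient below ``min_gradient_c_per_m``) has no
    thermocline and returns ``None``.
    """
    temp = profile.get("temperature")
    z = profile.depths_m
    ok = np.isfinite(temp)
    temp, z = temp[ok], z[ok]
    if temp.size < 3:
        raise ValueError("thermocline needs temperature at three or more depths")
    grad = np.abs(np.diff(temp) / np.diff(z))
    i = int(np.argmax(grad))  # argmax returns the first (shallowest) maximum
    if grad[i] < min_gradient_c_per_m:
        return None
    return float(0.5 * (z[i] + z[i + 1]))


def _first_crossing(z: np.ndarray, vals: np.ndarray, cutoff: float) -> float | None:
    """Shallowest depth where ``vals`` first falls below ``cutoff``
    (linear interpolation between bracketing samples)."""
    below = np.nonzero(vals < cutoff)[0]
    if below.size == 0:
        return None
    i = below[0]
    if i == 0:
        return float(z[0])
    v0, v1 = vals[i - 1], vals[i]
    w = (v0 - cutoff) / (v0 - v1)
    return float(z[i - 1] + w * (z[i] - z[i - 1]))


def oxygen_boundaries(
    profile: DepthProfile,
    anoxic_cutoff_um: float = ANOXIC_O2_UM,
    deficient_cutoff_um: float = DEFICIENT_O2_UM,
) -> dict:
    """Depths of the oxygen-deficient (<10 µM) and anoxic (<1 µM) horizons."""
    o2 = profile.get("o2")
    z = profile.depths_m
    ok = np.isfinite(o2)
    o2, z = o2[ok], z[ok]
    if o2.size == 0:
        raise ValueError("oxygen boundaries need O2 data")
    return {
        "z_anoxic": _first_crossing(z, o2, anoxic_cutoff_um),
        "z_deficient": _first_crossing(z, o2, deficient_cutoff_um),
    }


def chlorophyll_maxima(
    profile: DepthProfile,
    z_anoxic: float | None,
    prominence_frac: float = 0.2,
) -> dict:
    """Primary (oxic) and anoxic chlorophyll maxima.

    The primary maximum (PCM) is the global chlorophyll maximum at or above
    the anoxic boundary (the whole profile when the water column never goes
    anoxic).  A deep anoxic maximum (ACM) is reported only when a local
    maximum below the boundary stands at least ``prominence_frac`` above
    the lowest chlorophyll between the boundary and the peak — a guard
    against flagging the tail of a monotonically decaying profile.
    """
    chl = profile.get("chl")
    z = profile.depths_m
    ok = np.isfinite(chl)
    chl, z = chl[ok], z[ok]
    if chl.size == 0:
        raise ValueError("chlorophyll maxima need chlorophyll data")

    if z_anoxic is None:
        above = np.ones(z.size, dtype=bool)
    else:
        above = z <= z_anoxic
    if not np.any(above):
        above = np.ones(z.size, dtype=bool)
    pcm_idx = int(np.argmax(np.where(above, chl, -np.inf)))
    pcm_depth = float(z[pcm_idx])

    acm_depth = None
    if z_anoxic is not None:
        deep = np.nonzero(z > z_anoxic)[0]
        if deep.size >= 2:
            peak_local = int(np.argmax(chl[deep]))
            peak_idx = deep[peak_local]
            # background: chlorophyll floor between the boundary and the peak
            background = float(np.min(chl[deep[0] : peak_idx + 1]))
            is_local_max = (
                peak_idx > deep[0]
                and (peak_idx == z.size - 1 or chl[peak_idx] >= chl[peak_idx + 1])
                and chl[peak_idx] >= chl[peak_idx - 1]
            )
            if is_local_max and chl[peak_idx] >= (1.0 + prominence_frac) * background:
                acm_depth = float(z[peak_idx])
    return {"pcm_depth": pcm_depth, "acm_depth": acm_depth}


def np_ratio_classification(profile: DepthProfile, redfield: float = REDFIELD_NP) -> dict:
    """Fraction of samples with molar DIN:SRP below the Redfield ratio.

    DIN sums nitrate, nitrite and ammonium where measured; below-detection
    values enter as 0.  Samples whose SRP is censored (treated as 0) are
    undefined unless DIN is also 0 and are excluded with a flag; when every
    sample is undefined the classification itself is undefined.
    """
    if not profile.has("no3") or not profile.has("srp"):
        raise ValueError("N:P classification needs nitrate and SRP")
    din = profile.get("no3", censored_as=0.0)
    for extra in ("no2", "nh4"):
        if profile.has(extra):
            din = din + profile.get(extra, censored_as=0.0)
    srp = profile.get("srp", censored_as=0.0)

    flags: list[str] = []
    defined = srp > 0
    n_excluded = int(np.sum(~defined & (din > 0)))
    # DIN = SRP = 0: formally 0/0, but unambiguously N-depleted water
    both_zero = ~defined & (din == 0)
    if n_excluded:
        flags.append("srp-censored-samples-excluded")
    usable = defined | both_zero
    if not np.any(usable):
        return {"fraction_below": None, "n_samples": 0, "flags": ["all-srp-censored"]}
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(defined, din / np.where(defined, srp, 1.0), 0.0)
    below = ratio[usable] < redfield
    return {
        "fraction_below": float(np.mean(below)),
        "n_samples": int(np.sum(usable)),
        "flags": flags,
        "ratios": ratio[usable],
    }


def extract_features(profile: DepthProfile, **kwargs) -> ProfileFeatures:
    """All hydrographic features for one station; absent features are None."""
    z_eu = euphotic_depth(profile) if profile.has("par") else None
    z_tc = thermocline_depth(profile) if profile.has("temperature") else None
    if profile.has("o2"):
        ox = oxygen_boundaries(profile)
    else:
        ox = {"z_anoxic": None, "z_deficient": None}
    if profile.has("chl"):
        cm = chlorophyll_maxima(profile, ox["z_anoxic"], **kwargs)
    else:
        cm = {"pcm_depth": None, "acm_depth": None}
    frac = None
    if profile.has("no3") and profile.has("srp"):
        frac = np_ratio_classification(profile)["fraction_below"]
    return ProfileFeatures(
        station=profile.station,
        z_eu=z_eu,
        z_thermocline=z_tc,
        z_anoxic=ox["z_anoxic"],
        z_deficient=ox["z_deficient"],
        pcm_depth=cm["pcm_depth"],
        acm_depth=cm["acm_depth"],
        tc_minus_zeu=(z_tc - z_eu) if (z_tc is not None and z_eu is not None) else None,
        frac_below_redfield=frac,
    )
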