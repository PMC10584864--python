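"""Volumetric N₂-fixation rates from ¹⁵N₂ tracer incubations.

Each incubation set consists of one unamended control bottle (natural-
abundance δ¹⁵N of particulate organic nitrogen, PON) and duplicate
treatment bottles amended with ¹⁵N-labelled N₂.  The bulk fixation rate is
the isotope mass balance

    rate = (at%PON_sample − at%PON_control) / (at%N₂ − at%PON_control)
           × (PON concentration / incubation time)

in nmol N L⁻¹ d⁻¹, with atom-percent values derived from measured δ¹⁵N.
Enrichments below the detection limit (control δ¹⁵N + 4 ‰, or negative
δ/rates) are censored to zero rather than reported as spurious negatives.
N-loss experiments are summarised by the OLS slopes of ²⁹N₂ and ³⁰N₂
concentration against time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from lakenfix.isotopes import R_AIR, atom_percent_from_delta

#: Atomic mass of nitrogen, g mol⁻¹, for µg N → nmol N conversion.
N_ATOMIC_MASS = 14.0067

#: Default detection-limit excess over the control δ¹⁵N, ‰.
DEFAULT_LOD_EXCESS_PERMIL = 4.0


@dataclass(frozen=True)
class IncubationBottle:
    """One incubation bottle (control or ¹⁵N₂-amended treatment).

    ``pon_mass_ug`` is the µg N recovered on the filter, ``volume_l`` the
    filtered volume; their quotient is the PON concentration entering the
    mass balance.  ``label_atom_percent`` is the measured at%¹⁵N of the
    dissolved N₂ pool and is required for treatments, absent for controls.
    """

    station: str
    depth_m: float
    role: str  # "control" | "treatment"
    delta15n_pon: float  # permil vs air
    pon_mass_ug: float
    volume_l: float
    duration_d: float
    label_atom_percent: float | None = None

    def __post_init__(self):
        if self.role not in ("control", "treatment"):
            raise ValueError(f"role must be 'control' or 'treatment', got {self.role!r}")
        if self.volume_l <= 0:
            raise ValueError("filtered volume must be positive")
        if self.duration_d <= 0:
            raise ValueError("incubation duration must be positive")
        if self.pon_mass_ug < 0:
            raise ValueError("PON mass cannot be negative")
        if self.role == "treatment":
            if self.label_atom_percent is None:
                raise ValueError("treatment bottles require label_atom_percent")
            if not (0.0 < self.label_atom_percent < 100.0):
                raise ValueError("label_atom_percent must lie in (0, 100)")

    @property
    def pon_nmol_per_l(self) -> float:
        """PON concentration in nmol N L⁻¹ (µg N L⁻¹ × 1000 / 14.0067)."""
        return self.pon_mass_ug / self.volume_l * 1000.0 / N_ATOMIC_MASS


@dataclass(frozen=True)
class RateEstimate:
    """A volumetric rate with censoring state and replicate summary.

    Censored estimates report ``rate`` 0 (never negative) with
    ``censored`` set; ``flags`` carries data-quality annotations such as
    ``"partially-censored"`` or ``"default-control"``.
    """

    rate: float  # nmol N L^-1 d^-1
    se: float
    censored: bool
    n_replicates: int = 1
    flags: tuple[str, ...] = field(default_factory=tuple)

    def with_flag(self, flag: str) -> "RateEstimate":
        if flag in self.flags:
            return self
        return replace(self, flags=self.flags + (flag,))


def _check_pair(control: IncubationBottle | None, treatment: IncubationBottle) -> None:
    if treatment.role != "treatment":
        raise ValueError("second bottle must have role 'treatment'")
    if control is not None:
        if control.role != "control":
            raise ValueError("first bottle must have role 'control'")
        if control.station != treatment.station or control.depth_m != treatment.depth_m:
            raise ValueError("control and treatment must share station and depth")


def n2_fixation_rate(
    control: IncubationBottle | None,
    treatment: IncubationBottle,
    *,
    default_control_delta: float = 0.0,
    r_standard: float = R_AIR,
) -> RateEstimate:
    """Isotope mass-balance fixation rate for one treatment bottle.

    When ``control`` is None the natural-abundance baseline falls back to
    ``default_control_delta`` (‰) and the estimate is flagged
    ``"default-control"``.  Raises ``ValueError`` when the labelled N₂ pool
    is not enriched above the control PON (no usable tracer gradient).
    """
    _check_pair(control, treatment)
    flags: tuple[str, ...] = ()
    if control is None:
        control_delta = default_control_delta
        flags = ("default-control",)
    else:
        control_delta = control.delta15n_pon

    ap_control = atom_percent_from_delta(control_delta, r_standard)
    ap_sample = atom_percent_from_delta(treatment.delta15n_pon, r_standard)
    ap_n2 = treatment.label_atom_percent
    if ap_n2 <= ap_control:
        raise ValueError(
            f"label at% ({ap_n2}) must exceed control PON at% ({ap_control:.4f})"
        )
    rate = (ap_sample - ap_control) / (ap_n2 - ap_control) * (
        treatment.pon_nmol_per_l / treatment.duration_d
    )
    return RateEstimate(rate=rate, se=0.0, censored=False, n_replicates=1, flags=flags)


def apply_lod(
    control: IncubationBottle | None,
    treatment: IncubationBottle,
    rate: RateEstimate,
    min_excess_permil: float = DEFAULT_LOD_EXCESS_PERMIL,
    *,
    default_control_delta: float = 0.0,
) -> RateEstimate:
    """Censor a single-bottle rate below the detection limit.

    A bottle is below detection when any of the following holds:

    * treatment δ¹⁵N < control δ¹⁵N + ``min_excess_permil`` (default 4 ‰),
    * treatment δ¹⁵N is negative together with a negative computed rate,
    * the computed rate itself is negative.

    Censored estimates carry rate 0 and ``censored=True``.
    """
    control_delta = control.delta15n_pon if control is not None else default_control_delta
    below = (
        treatment.delta15n_pon < control_delta + min_excess_permil
        or (treatment.delta15n_pon < 0.0 and rate.rate < 0.0)
        or rate.rate < 0.0
    )
    if below:
        return replace(rate, rate=0.0, censored=True)
    return rate


def summarize_depth(
    pairs: list[tuple[IncubationBottle | None, IncubationBottle]],
    min_excess_permil: float = DEFAULT_LOD_EXCESS_PERMIL,
    *,
    default_control_delta: float = 0.0,
) -> RateEstimate:
    """Replicate mean and standard error for one station/depth.

    The mean is taken over the rates retained after censoring; the SE is
    sd/√n over those retained replicates.  A mixed outcome (some duplicates
    censored, some retained) keeps the retained mean and is flagged
    ``"partially-censored"``; when every duplicate is censored the summary
    itself is censored (rate 0).
    """
    if not pairs:
        raise ValueError("at least one control/treatment pair is required")
    estimates = []
    inherited: list[str] = []
    for control, treatment in pairs:
        est = n2_fixation_rate(
            control, treatment, default_control_delta=default_control_delta
        )
        est = apply_lod(
            control,
            treatment,
            est,
            min_excess_permil,
            default_control_delta=default_control_delta,
        )
        inherited.extend(est.flags)
        estimates.append(est)

    retained = [e.rate for e in estimates if not e.censored]
    n_total = len(estimates)
    flags = tuple(dict.fromkeys(inherited))
    if not retained:
        return RateEstimate(
            rate=0.0, se=0.0, censored=True, n_replicates=n_total, flags=flags
        )
    mean = float(np.mean(retained))
    se = float(np.std(retained, ddof=1) / np.sqrt(len(retained))) if len(retained) > 1 else 0.0
    if len(retained) == 1 and n_total == 1:
        flags += ("single-replicate",)
    if len(retained) < n_total:
        flags += ("partially-censored",)
    return RateEstimate(
        rate=mean, se=se, censored=False, n_replicates=len(retained), flags=flags
    )


@dataclass(frozen=True)
class N2TimeSeries:
    """²⁹N₂/³⁰N₂ concentration time series from one ¹⁵N amendment experiment.

    ``experiment`` names the amendment design (e.g. "15NO3", "15NH4");
    ``label_fraction`` is the ¹⁵N fraction of the amended substrate pool.
    """

    experiment: str
    times_d: np.ndarray
    conc_29n2: np.ndarray
    conc_30n2: np.ndarray
    label_fraction: float = 1.0

    def __post_init__(self):
        t = np.asarray(self.times_d, dtype=float)
        c29 = np.asarray(self.conc_29n2, dtype=float)
        c30 = np.asarray(self.conc_30n2, dtype=float)
        if t.size < 3:
            raise ValueError("at least 3 time points are required")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if c29.size != t.size or c30.size != t.size:
            raise ValueError("concentration series must match times in length")
        object.__setattr__(self, "times_d", t)
        object.__setattr__(self, "conc_29n2", c29)
        object.__setattr__(self, "conc_30n2", c30)


def nloss_rates(ts: N2TimeSeries) -> dict:
    """²⁹N₂ and ³⁰N₂ production rates as OLS slopes against time.

    Returns ``p29``/``p30`` in nmol L⁻¹ d⁻¹ together with each regression's
    r², intercepts and censoring flags; negative slopes (net consumption or
    noise) are reported as 0 and flagged censored.  The conversion of
    isotopologue production into anammox/denitrification N-removal rates
    depends on isotope-pairing conventions and is intentionally left to the
    caller.
    """
    out: dict = {}
    for name, conc in (("29", ts.conc_29n2), ("30", ts.conc_30n2)):
        res = sps.linregress(ts.times_d, conc)
        slope = float(res.slope)
        censored = slope < 0.0
        out[f"p{name}"] = 0.0 if censored else slope
        out[f"p{name}_censored"] = censored
        out[f"r2_{name}"] = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
        out[f"intercept_{name}"] = float(res.intercept)
    return out


def single_cell_rate(
    volumetric_rate_nmol_l_d: float,
    colonies_per_ml: float,
    cells_per_colony: float,
) -> float:
    """Per-cell fixation rate in fmol N cell⁻¹ d⁻¹.

    Divides a volumetric rate by the cell density implied by colony counts;
    1 nmol = 10⁶ fmol and 1 L = 10³ mL, so
    rate[fmol cell⁻¹ d⁻¹] = rate[nmol L⁻¹ d⁻¹] × 10³ / (colonies mL⁻¹ × cells).
    """
    if colonies_per_ml <= 0 or cells_per_colony <= 0:
        raise ValueError("cell densities must be positive")
    cells_per_l = colonies_per_ml * cells_per_colony * 1000.0
    return volumetric_rate_nmol_l_d / cells_per_l * 1e6
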