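"""Basin-scale nitrogen budgets with diagnostic source/sink ratios.

Station-level areal fluxes (µmol N m⁻² d⁻¹) are averaged into two basins —
the permanently stratified north/central basin (stations 1–6) and the
upwelling-influenced south basin (stations 7–9) — and reported in
mmol N m⁻² d⁻¹ for two compartments:

* euphotic zone: N₂ fixation, upward NO₃⁻ flux, atmospheric deposition and
  riverine input; their sum is the total new production;
* anoxic zone: N₂ fixation, NO₃⁻ and NH₄⁺ fluxes, and fixed-N removal by
  anammox/denitrification.

Two diagnostics relate fixation to fixed-N removal: the percentage of
removal balanced by in-situ anoxic-zone fixation, and the percentage that
export of newly fixed N from the euphotic zone could supply.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt

import numpy as np

NORTH_CENTER = "north_center"
SOUTH = "south"

#: Transect basin membership: stations 1-6 north/central, 7-9 south.
DEFAULT_BASIN_MAP = {**{str(s): NORTH_CENTER for s in range(1, 7)},
                     **{str(s): SOUTH for s in range(7, 10)}}

#: Literature external N inputs, mmol N m^-2 d^-1 (daily downscaled annual
#: loads; the lake-wide deposition estimate is used for both basins).
DEFAULT_EXTERNAL_INPUTS = {
    NORTH_CENTER: {"deposition": 0.13, "rivers": 0.02},
    SOUTH: {"deposition": 0.13, "rivers": 0.003},
}

EUPHOTIC_SOURCE_TERMS = ("n_fixation", "no3_flux", "deposition", "rivers")


def assign_basin(station, basin_map: dict | None = None) -> str:
    """Basin label for a station; unknown stations raise ``ValueError``."""
    basin_map = basin_map or DEFAULT_BASIN_MAP
    key = str(station)
    if key not in basin_map:
        raise ValueError(f"station {station!r} is not in the configured transect")
    return basin_map[key]


@dataclass(frozen=True)
class BudgetTerm:
    """One budget entry in mmol N m⁻² d⁻¹ with SE and station count."""

    value: float
    se: float | None = None
    n: int | None = None
    flags: tuple[str, ...] = field(default_factory=tuple)


def aggregate_basin(values_umol_m2_d) -> BudgetTerm:
    """Basin mean ± SE (sd/√n) over station fluxes, converted µmol → mmol."""
    vals = np.asarray(list(values_umol_m2_d), dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no station values to aggregate")
    mean = float(np.mean(vals)) / 1000.0
    if vals.size == 1:
        return BudgetTerm(value=mean, se=0.0, n=1, flags=("single-station",))
    se = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) / 1000.0
    return BudgetTerm(value=mean, se=se, n=int(vals.size))


@dataclass
class BasinBudget:
    """Per-basin source/sink table (mmol N m⁻² d⁻¹) in two compartments."""

    basin: str
    euphotic: dict[str, BudgetTerm] = field(default_factory=dict)
    anoxic: dict[str, BudgetTerm] = field(default_factory=dict)


def external_inputs(basin: str, config: dict | None = None) -> dict[str, BudgetTerm]:
    """Atmospheric deposition and riverine input for a basin (mmol m⁻² d⁻¹)."""
    table = config if config is not None else DEFAULT_EXTERNAL_INPUTS
    if basin not in table:
        raise KeyError(f"no external inputs configured for basin {basin!r}")
    entry = table[basin]
    out = {}
    for term in ("deposition", "rivers"):
        if term not in entry:
            raise KeyError(f"external input {term!r} missing for basin {basin!r}")
        out[term] = BudgetTerm(value=float(entry[term]))
    return out


def total_new_production(budget: BasinBudget) -> BudgetTerm:
    """Sum of the euphotic source terms; SE propagated in quadrature.

    Missing deposition/river terms default from the configured literature
    values for the basin.
    """
    terms = dict(budget.euphotic)
    for name, term in external_inputs(budget.basin).items():
        terms.setdefault(name, term)
    missing = [t for t in ("n_fixation", "no3_flux") if t not in terms]
    if missing:
        raise ValueError(f"euphotic budget missing terms: {missing}")
    total = sum(terms[t].value for t in EUPHOTIC_SOURCE_TERMS)
    ses = [terms[t].se for t in EUPHOTIC_SOURCE_TERMS if terms[t].se]
    se = sqrt(sum(s**2 for s in ses)) if ses else None
    return BudgetTerm(value=float(total), se=se)


def ratio_diagnostics(budget: BasinBudget) -> dict:
    """Fixation-vs-removal percentages for one basin.

    ``pct_nfix_of_removal``: anoxic-zone fixation as a percentage of the
    fixed-N removal rate.  ``pct_export_supply``: euphotic-zone fixation
    (potential export of newly fixed N) as a percentage of removal.
    """
    if "n_removal" not in budget.anoxic or budget.anoxic["n_removal"].value <= 0:
        return {"pct_nfix_of_removal": None, "pct_export_supply": None,
                "flags": ["zero-or-missing-removal"]}
    removal = budget.anoxic["n_removal"].value
    anoxic_fix = budget.anoxic.get("n_fixation", BudgetTerm(0.0)).value
    euphotic_fix = budget.euphotic.get("n_fixation", BudgetTerm(0.0)).value
    return {
        "pct_nfix_of_removal": 100.0 * anoxic_fix / removal,
        "pct_export_supply": 100.0 * euphotic_fix / removal,
        "flags": [],
    }


def assemble_budget(
    station_fluxes: dict,
    basin_map: dict | None = None,
    external: dict | None = None,
) -> dict[str, BasinBudget]:
    """Assemble per-basin budgets from station-level areal fluxes.

    ``station_fluxes`` maps station → {(compartment, term): value in
    µmol m⁻² d⁻¹}; e.g. ``{"2": {("euphotic", "n_fixation"): 310.0, ...}}``.
    Pure function of its inputs: station order never matters.
    """
    grouped: dict[str, dict[tuple[str, str], list[float]]] = {}
    for station in sorted(station_fluxes, key=str):
        basin = assign_basin(station, basin_map)
        bucket = grouped.setdefault(basin, {})
        for key, value in station_fluxes[station].items():
            if value is not None and np.isfinite(value):
                bucket.setdefault(key, []).append(float(value))

    budgets: dict[str, BasinBudget] = {}
    for basin, terms in grouped.items():
        bb = BasinBudget(basin=basin)
        for (compartment, term), vals in terms.items():
            target = bb.euphotic if compartment == "euphotic" else bb.anoxic
            target[term] = aggregate_basin(vals)
        for name, term in external_inputs(basin, external).items():
            bb.euphotic.setdefault(name, term)
        budgets[basin] = bb
    return budgets


def format_budget_table(budgets: dict[str, BasinBudget], decimals: int = 2) -> str:
    """Render basin budgets as a fixed-width text table (two-decimal style)."""

    def fmt(term: BudgetTerm | None) -> str:
        if term is None:
            return "-"
        s = f"{term.value:.{decimals}f}"
        if term.se is not None and term.n is not None:
            s += f" ± {term.se:.{decimals}f} (n={term.n})"
        return s

    basins = [b for b in (NORTH_CENTER, SOUTH) if b in budgets] or sorted(budgets)
    rows: list[tuple[str, list[str]]] = []
    rows.append(("Euphotic zone", []))
    for term in ("n_fixation", "no3_flux", "deposition", "rivers"):
        rows.append((f"  {term}", [fmt(budgets[b].euphotic.get(term)) for b in basins]))
    rows.append(
        ("  total_new_production", [fmt(total_new_production(budgets[b])) for b in basins])
    )
    rows.append(("Anoxic zone", []))
    for term in ("n_fixation", "no3_flux", "nh4_flux", "n_removal"):
        rows.append((f"  {term}", [fmt(budgets[b].anoxic.get(term)) for b in basins]))

    width = max(len(r[0]) for r in rows) + 2
    colw = 24
    header = " " * width + "".join(b.ljust(colw) for b in basins)
    lines = [
        "Nitrogen fluxes (mmol N m-2 d-1)",
        header,
    ]
    for label, cells in rows:
        lines.append(label.ljust(width) + "".join(c.ljust(colw) for c in cells))
    return "\n".join(lines)
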