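"""Delimited-text readers and writers for every pipeline table.

All schemas are plain UTF-8 CSV with units embedded in the column names
(``depth_m``, ``no3_uM``, …); censoring flags travel in sidecar boolean
columns so that a write/read round trip is lossless.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from lakenfix.profiles import DEFAULT_DETECTION_LIMITS, DepthProfile
from lakenfix.rates import IncubationBottle, N2TimeSeries


class SchemaError(ValueError):
    """An input table violates its declared schema."""


#: analyte name -> CSV column (units in the name)
PROFILE_COLUMNS = {
    "temperature": "temperature_C",
    "o2": "o2_uM",
    "no3": "no3_uM",
    "srp": "srp_uM",
    "nh4": "nh4_uM",
    "chl": "chl_ug_L",
    "par": "par_rel",
    "pon": "pon_ugN_L",
    "d15n_pon": "d15n_pon_permil",
}

INCUBATION_COLUMNS = [
    "station",
    "depth_m",
    "role",
    "delta15N_permil",
    "pon_mass_ugN",
    "volume_L",
    "duration_d",
    "label_atom_percent",
]


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


# -- profiles ---------------------------------------------------------------


def write_profiles_csv(profiles: dict[str, DepthProfile], path) -> None:
    rows = []
    for station in sorted(profiles, key=str):
        p = profiles[station]
        for i, z in enumerate(p.depths_m):
            row: dict = {"station": station, "depth_m": float(z)}
            for analyte, col in PROFILE_COLUMNS.items():
                if analyte in p.properties:
                    row[col] = float(p.properties[analyte][i])
                    if analyte in p.censored:
                        row[f"{col}_censored"] = bool(p.censored[analyte][i])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_profiles_csv(path, detection_limits: dict | None = None) -> dict[str, DepthProfile]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["station", "depth_m"], f"profiles file {path}")
    bad = df.index[~np.isfinite(df["depth_m"])]
    if len(bad):
        raise SchemaError(f"profiles file {path}: non-numeric depth_m at row {bad[0] + 2}")
    limits = {**DEFAULT_DETECTION_LIMITS, **(detection_limits or {})}
    profiles = {}
    for station, grp in df.groupby("station", sort=True):
        properties, censored = {}, {}
        for analyte, col in PROFILE_COLUMNS.items():
            if col in grp.columns:
                properties[analyte] = grp[col].to_numpy(dtype=float)
                flag_col = f"{col}_censored"
                if flag_col in grp.columns:
                    censored[analyte] = grp[flag_col].fillna(False).to_numpy(dtype=bool)
        profiles[str(station)] = DepthProfile(
            station=str(station),
            depths_m=grp["depth_m"].to_numpy(dtype=float),
            properties=properties,
            censored=censored,
            detection_limits=limits,
        )
    return profiles


# -- incubations ------------------------------------------------------------


def write_incubations_csv(bottles: list[IncubationBottle], path) -> None:
    rows = [
        {
            "station": b.station,
            "depth_m": b.depth_m,
            "role": b.role,
            "delta15N_permil": b.delta15n_pon,
            "pon_mass_ugN": b.pon_mass_ug,
            "volume_L": b.volume_l,
            "duration_d": b.duration_d,
            "label_atom_percent": b.label_atom_percent,
        }
        for b in bottles
    ]
    pd.DataFrame(rows, columns=INCUBATION_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_incubations_csv(path) -> list[IncubationBottle]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, INCUBATION_COLUMNS[:-1], f"incubations file {path}")
    bottles = []
    for idx, row in df.iterrows():
        try:
            label = row.get("label_atom_percent")
            bottles.append(
                IncubationBottle(
                    station=str(row["station"]),
                    depth_m=float(row["depth_m"]),
                    role=str(row["role"]),
                    delta15n_pon=float(row["delta15N_permil"]),
                    pon_mass_ug=float(row["pon_mass_ugN"]),
                    volume_l=float(row["volume_L"]),
                    duration_d=float(row["duration_d"]),
                    label_atom_percent=None if pd.isna(label) else float(label),
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"incubations file {path}, row {idx + 2}: {exc}") from exc
    return bottles


# -- N2 time series ---------------------------------------------------------


def write_timeseries_csv(series: dict[str, N2TimeSeries], path) -> None:
    rows = []
    for station in sorted(series, key=str):
        ts = series[station]
        for t, c29, c30 in zip(ts.times_d, ts.conc_29n2, ts.conc_30n2):
            rows.append(
                {
                    "station": station,
                    "experiment": ts.experiment,
                    "time_d": float(t),
                    "conc29_nmol_L": float(c29),
                    "conc30_nmol_L": float(c30),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_timeseries_csv(path) -> dict[str, N2TimeSeries]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(
        df,
        ["station", "experiment", "time_d", "conc29_nmol_L", "conc30_nmol_L"],
        f"timeseries file {path}",
    )
    out = {}
    for (station, experiment), grp in df.groupby(["station", "experiment"], sort=True):
        grp = grp.sort_values("time_d")
        out[str(station)] = N2TimeSeries(
            experiment=str(experiment),
            times_d=grp["time_d"].to_numpy(dtype=float),
            conc_29n2=grp["conc29_nmol_L"].to_numpy(dtype=float),
            conc_30n2=grp["conc30_nmol_L"].to_numpy(dtype=float),
        )
    return out


# -- colony counts ----------------------------------------------------------


def write_colonies_csv(colonies: pd.DataFrame, path) -> None:
    colonies.to_csv(path, index=False, float_format="%.17g")


def read_colonies_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(
        df, ["station", "depth_m", "colonies_per_ml"], f"colonies file {path}"
    )
    df["station"] = df["station"].astype(str)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")
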