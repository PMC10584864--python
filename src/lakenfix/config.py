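"""Pipeline configuration: physical parameters, intervals, basin layout."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from lakenfix.budget import DEFAULT_BASIN_MAP, DEFAULT_EXTERNAL_INPUTS
from lakenfix.fluxes import DEFAULT_GRADIENT_WINDOW_M, DEFAULT_KZ_M2_S
from lakenfix.rates import DEFAULT_LOD_EXCESS_PERMIL


@dataclass
class PipelineConfig:
    """Everything the pipeline driver needs beyond the input tables.

    Units are embedded in field names.  ``upwelling_velocity_m_d`` maps
    station labels to upwelling velocities (stations without an entry get
    a purely diffusive nitrate flux).  ``n_removal_mmol`` optionally
    supplies per-basin fixed-N removal rates (mmol N m⁻² d⁻¹) for the
    budget diagnostics.
    """

    kz_m2_s: float = DEFAULT_KZ_M2_S
    upwelling_velocity_m_d: dict[str, float] = field(
        default_factory=lambda: {"8": 0.05, "9": 0.1}
    )
    euphotic_interval_m: tuple[float, float] = (0.0, 50.0)
    anoxic_interval_m: tuple[float, float] = (125.0, 175.0)
    total_interval_m: tuple[float, float] = (0.0, 175.0)
    gradient_window_m: float = DEFAULT_GRADIENT_WINDOW_M
    lod_excess_permil: float = DEFAULT_LOD_EXCESS_PERMIL
    basin_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_BASIN_MAP))
    external_inputs: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EXTERNAL_INPUTS.items()}
    )
    n_removal_mmol: dict[str, float] = field(default_factory=dict)
    reporting_decimals: int = 2
    seed: int = 0

    def __post_init__(self):
        for name in ("euphotic_interval_m", "anoxic_interval_m", "total_interval_m"):
            z0, z1 = tuple(getattr(self, name))
            if z1 <= z0:
                raise ValueError(f"{name} is degenerate: [{z0}, {z1}]")
            setattr(self, name, (float(z0), float(z1)))
        if self.kz_m2_s <= 0:
            raise ValueError("kz_m2_s must be positive")
        for station in self.upwelling_velocity_m_d:
            if str(station) not in self.basin_map:
                raise ValueError(
                    f"upwelling velocity given for unknown station {station!r}"
                )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for name in ("euphotic_interval_m", "anoxic_interval_m", "total_interval_m"):
            d[name] = list(d[name])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
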