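"""Run configuration: every tunable with defaults, TOML loading, overrides."""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """All tunables across the pipeline, with their defaults.

    The serialized form round-trips losslessly through ``as_dict`` /
    ``from_dict``; CLI flags override config-file values, which override
    the defaults.
    """

    # fluorescence
    band_centers_nm: list[float] = field(
        default_factory=lambda: [304.0, 318.0, 331.0, 344.0, 360.0]
    )
    band_center_bound_nm: float = 2.0
    band_sigma_min_nm: float = 4.0
    band_sigma_max_nm: float = 20.0
    include_minor_bands: bool = False
    rayleigh_half_width_nm: float = 8.0
    tail_start_nm: float = 450.0
    second_derivative_window_pts: int = 11
    second_derivative_poly_order: int = 3
    fit_multistart: int = 5
    r_tolerance: float = 0.045
    polymer_redshift_nm: float = 5.0
    # structure
    sasa_probe_A: float = 1.4
    sasa_sphere_points: int = 960
    hbond_distance_max_A: float = 3.5
    hbond_angle_min_deg: float = 150.0
    saltbridge_distance_max_A: float = 4.0
    occupancy_min: float = 0.5
    sulfur_polar: bool = False
    # free energy
    sigma_apol_cal: float = 49.6
    sigma_pol_cal: float = 19.1
    e_hb_kcal: float = 0.5
    # global
    seed: int = 0
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out.pop("provenance")
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a config from defaults, an optional TOML file, then overrides."""
    data: dict = {}
    provenance: dict = {"config_file": None, "overrides": {}}
    if path is not None:
        with open(path, "rb") as fh:
            data.update(tomllib.load(fh))
        provenance["config_file"] = str(path)
    for key, value in overrides.items():
        if value is not None:
            data[key] = value
            provenance["overrides"][key] = value
    cfg = RunConfig.from_dict(data)
    cfg.provenance = provenance
    return cfg
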