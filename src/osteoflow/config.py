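"""Pipeline configuration (TOML).

All lengths are meters.  Flow rates accept an explicit unit suffix
("0.2 ml/min" or "3.33e-9 m^3/s") or a bare number in m^3/s; inlet
velocities are m/s.  Unknown keys are rejected at load time.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from .geometry import ML_PER_MIN

__all__ = ["ConfigError", "PipelineConfig", "load_config", "parse_flow_rate"]


class ConfigError(ValueError):
    """Malformed or incomplete pipeline configuration."""


def parse_flow_rate(value: float | str) -> float:
    """Flow rate in m^3/s from a number (m^3/s) or suffixed string."""
    if isinstance(value, (int, float)):
        return float(value)
    text = value.strip()
    for suffix, factor in (("ml/min", ML_PER_MIN), ("m^3/s", 1.0), ("m3/s", 1.0)):
        if text.endswith(suffix):
            try:
                return float(text[: -len(suffix)].strip()) * factor
            except ValueError as exc:
                raise ConfigError(f"cannot parse flow rate {value!r}") from exc
    raise ConfigError(
        f"flow rate {value!r} needs an explicit unit suffix ('ml/min' or 'm^3/s')"
    )


@dataclass
class SolverConfig:
    inlet_velocity: float | None = None  # m/s (mean); or derive from flow_rate
    flow_rate: float | str | None = None
    profile: str = "parabolic"
    include_inertia: bool = True
    mode: str = "refine"  # "refine" (mesh sweep) or "fixed"
    grid_spacing: float = 205e-6  # m, used in "fixed" mode
    initial_spacing: float = 205e-6  # m, start of the refinement sweep
    criterion: float = 0.02
    max_levels: int = 8
    tol: float = 1e-8
    max_iter: int = 60


@dataclass
class UctConfig:
    sigma: float = 1.2
    support: int = 1
    threshold: float = 97.5  # mg HA/cm^3
    min_particle_size: int = 50
    connectivity: int = 26


@dataclass
class SynthConfig:
    voxel_size: float = 36e-6  # m
    porosity: float = 0.55
    pore_diameter_min: float = 315e-6
    pore_diameter_max: float = 400e-6
    scaffold_density: float = 30.0  # mg/cm^3
    link_kind: str = "band"
    band_lo: float = 0.55e-3  # Pa
    band_hi: float = 24e-3  # Pa
    rate: float = 0.6
    bonus: float = 0.35
    link_noise: float = 0.0
    weeks: list[int] = field(default_factory=lambda: [2, 3, 4, 5, 6])
    psf_sigma: float = 0.5
    noise_sd: float = 15.0
    mineral_density: float = 200.0


@dataclass
class PipelineConfig:
    seed: int = 0
    geometry: dict = field(default_factory=dict)  # overrides for build_geometry
    fluid: dict = field(default_factory=dict)  # density, viscosity
    porous: dict = field(default_factory=dict)  # porosity, permeability
    solver: SolverConfig = field(default_factory=SolverConfig)
    uct: UctConfig = field(default_factory=UctConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)

    def to_dict(self) -> dict:
        return asdict(self)


_GEOMETRY_KEYS = {
    "scaffold_radius", "scaffold_height", "chamber_radius",
    "tube_radius", "tube_length", "plenum_height_bottom", "plenum_height_top",
}
_FLUID_KEYS = {"density", "viscosity"}
_POROUS_KEYS = {"porosity", "permeability"}


def _fill_section(cls, raw: dict, section: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
    return cls(**raw)


def _check_keys(raw: dict, allowed: set[str], section: str) -> dict:
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
    return raw


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a pipeline configuration from TOML."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    known_sections = {"seed", "geometry", "fluid", "porous", "solver", "uct", "synth"}
    unknown = set(raw) - known_sections
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    cfg = PipelineConfig(
        seed=int(raw.get("seed", 0)),
        geometry=_check_keys(dict(raw.get("geometry", {})), _GEOMETRY_KEYS, "geometry"),
        fluid=_check_keys(dict(raw.get("fluid", {})), _FLUID_KEYS, "fluid"),
        porous=_check_keys(dict(raw.get("porous", {})), _POROUS_KEYS, "porous"),
        solver=_fill_section(SolverConfig, dict(raw.get("solver", {})), "solver"),
        uct=_fill_section(UctConfig, dict(raw.get("uct", {})), "uct"),
        synth=_fill_section(SynthConfig, dict(raw.get("synth", {})), "synth"),
    )
    if cfg.solver.inlet_velocity is None and cfg.solver.flow_rate is None:
        raise ConfigError("missing required key: solver.inlet_velocity (or solver.flow_rate)")
    if cfg.solver.mode not in ("refine", "fixed"):
        raise ConfigError(f"solver.mode must be 'refine' or 'fixed', got {cfg.solver.mode!r}")
    if cfg.solver.flow_rate is not None:
        cfg.solver.flow_rate = parse_flow_rate(cfg.solver.flow_rate)
    return cfg
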