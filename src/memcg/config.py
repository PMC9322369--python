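"""Configuration objects: energy coefficients, membrane grid geometry, Monte
Carlo settings, and the merged run configuration with YAML round-tripping.

Every field has a default so that a bare ``EnergyConfig()`` is a complete,
documented parameterisation; YAML files override fields and unknown keys are
rejected (fail fast).
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Any

import yaml

from .constants import (
    DEFAULT_PKA_WATER,
    DEFAULT_RESIDUE_CLASSES,
    DEFAULT_SIDE_VDW_RADII,
    R_KCAL,
)


@dataclass(frozen=True)
class EnergyConfig:
    """Coefficients and tables of the coarse-grained folding energy.

    ``c2`` and ``c3`` scale backbone solvation and hydrogen bonding
    (0.25 / 0.15); ``c1`` scales the side-chain vdW term and is a package
    default (0.10), not a published value. Charge-charge interactions use a
    uniform effective dielectric ``eps_eff``; ionizable self-energy is linear
    in nonpolar/polar/membrane neighbour counts with saturation at ``n_sat``.
    """

    c1: float = 0.10
    c2: float = 0.25
    c3: float = 0.15
    eps_eff: float = 40.0
    coulomb_k: float = 332.0637
    temperature: float = 300.0
    # self-energy slopes, kcal/mol per neighbour, for a fully charged site
    a_np: float = 0.05
    a_p: float = -0.05
    a_mem: float = 0.20
    n_sat: int = 20
    # pair terms
    cutoff: float = 10.0
    clash_clamp: float = 2.0
    vdw_well_depth: float = 0.10
    vdw_cap: float = 10.0
    k_polar: float = -0.10
    k_hyd: float = 0.10
    k_hyd_mem: float = 0.05
    # backbone terms (unscaled; c2/c3 applied in the total)
    hb_energy: float = -1.0
    hb_d_on: float = 3.0
    hb_d_off: float = 3.5
    hb_min_sep: int = 3
    k_solv: float = 0.20
    burial_radius: float = 6.0
    burial_threshold: int = 12
    # unfolding correction of the side-chain electrostatic term; no published
    # functional form, default 0
    q_dev: float = 0.0
    terminal_ionizable: bool = False
    pka_water: dict = field(default_factory=lambda: dict(DEFAULT_PKA_WATER))
    residue_classes: dict = field(
        default_factory=lambda: dict(DEFAULT_RESIDUE_CLASSES)
    )
    side_vdw_radii: dict = field(
        default_factory=lambda: dict(DEFAULT_SIDE_VDW_RADII)
    )

    @property
    def rt(self) -> float:
        return R_KCAL * self.temperature

    @property
    def ln10_rt(self) -> float:
        """2.3 RT in kcal/mol (1.3712 at 300 K)."""
        return 2.3 * R_KCAL * self.temperature

    def replace(self, **kw) -> "EnergyConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class GridConfig:
    """Membrane slab lattice geometry (slab normal fixed to z)."""

    spacing: float = 3.0
    slab_center_z: float = 0.0
    slab_half_thickness: float = 15.0
    exclusion_radius: float = 2.5
    lateral_margin: float = 15.0

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.slab_half_thickness <= 0:
            raise ValueError("slab_half_thickness must be positive")
        if self.exclusion_radius < 0:
            raise ValueError("exclusion_radius must be non-negative")

    def replace(self, **kw) -> "GridConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo proton-transfer sampling settings.

    One sweep attempts ``n_sites`` moves; a move is a bulk proton exchange
    (toggle one site) or a proton transfer within a site pair, chosen with
    probability ``pair_move_fraction``.
    """

    temperature: float = 300.0
    n_burn_in: int = 2000
    n_production: int = 20000
    pair_move_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.n_burn_in < 0 or self.n_production <= 0:
            raise ValueError("sweep counts must be positive")
        if not 0.0 <= self.pair_move_fraction <= 1.0:
            raise ValueError("pair_move_fraction must be in [0, 1]")

    def replace(self, **kw) -> "MCConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class PathwayConfig:
    """Morphing / profiling settings for conformational pathways."""

    n_frames: int = 21
    relax_steps: int = 50
    relax_step_size: float = 0.1
    pH: float = 7.0
    seeds: tuple = (1, 2, 3)

    def replace(self, **kw) -> "PathwayConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class RunConfig:
    """Merged configuration for the end-to-end pipeline."""

    energy: EnergyConfig = field(default_factory=EnergyConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    mc: MCConfig = field(default_factory=MCConfig)
    pathway: PathwayConfig = field(default_factory=PathwayConfig)

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


_SECTIONS = {
    "energy": EnergyConfig,
    "grid": GridConfig,
    "mc": MCConfig,
    "pathway": PathwayConfig,
}


def _build_section(cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise KeyError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}"
        )
    if cls is PathwayConfig and "seeds" in data:
        data = dict(data, seeds=tuple(data["seeds"]))
    return cls(**data)


def load_run_config(path=None, text: str | None = None) -> RunConfig:
    """Load a :class:`RunConfig` from YAML; missing sections take defaults."""
    if text is None:
        if path is None:
            return RunConfig()
        with open(path) as fh:
            text = fh.read()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("run configuration must be a YAML mapping")
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise KeyError(f"unknown configuration sections: {sorted(unknown)}")
    kwargs = {
        name: _build_section(cls, data.get(name, {}) or {})
        for name, cls in _SECTIONS.items()
    }
    return RunConfig(**kwargs)


def dump_run_config(cfg: RunConfig) -> str:
    """Deterministic YAML snapshot of a run configuration."""
    payload: dict[str, Any] = {}
    for name in _SECTIONS:
        section = dataclasses.asdict(getattr(cfg, name))
        if name == "pathway":
            section["seeds"] = list(section["seeds"])
        payload[name] = section
    return yaml.safe_dump(payload, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(dump_run_config(cfg).encode()).hexdigest()[:16]
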