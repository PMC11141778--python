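"""Run configuration, unit mapping and scenario presets.

The physical-to-lattice mapping is fixed by the lattice spacing
``dx = baseline_diameter / resolution``, the BGK relaxation time ``tau`` and
the physical kinematic viscosity ``nu_phys`` (water-like 1e-2 cm^2/s by
default), giving ``dt = cs^2 (tau - 1/2) dx^2 / nu_phys``.  Gravity levels
are multiples of g = 980 cm/s^2 directed along the vessel axis; positive
levels oppose the flow (point upstream), negative levels assist it.

``gravity_scale`` rescales the gravitational acceleration used by a scenario.
The coarse desk-scale presets use a reduced scale because the lattice sound
speed at coarse resolution cannot support centimetre-scale hydrostatic
heads; the regime structure (NO-suppressed quiescence under assisting
gravity, Ca++-driven pumping under adverse gravity) is preserved.  See
docs/methods.md.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import lattice as lb
from .chemistry import ChemParams
from .errors import ConfigurationError
from .geometry import DomainSpec

G_PHYS = 980.0  # cm/s^2


@dataclass
class FluidConfig:
    tau: float = 1.0
    nu_phys: float = 1.0e-2        # cm^2/s
    rho0: float = 1.0
    rho_tissue: float = 1.004      # far-field tissue density (filling pressure)
    rho_out: float = 1.0           # outlet density (pressure datum)
    max_u: float = 0.15
    gravity_scale: float = 1.0     # fraction of 980 cm/s^2 per gravity unit
    gravity_ramp_s: float = 0.05   # smooth switch-on time of the body force
    body_force_x: float = 0.0      # direct lattice forcing (channel scenarios)

    def __post_init__(self) -> None:
        if self.tau <= 0.5:
            raise ConfigurationError("tau must exceed 0.5")
        if self.rho_out <= 0 or self.rho_tissue <= 0:
            raise ConfigurationError("boundary densities must be positive")


@dataclass
class WallConfig:
    k_tether: float = 0.025    # lattice force / lattice displacement
    c_damp: float = 100.0      # lattice force / (lattice displacement per step)


@dataclass
class ValveConfig:
    n_nodes: int = 14
    k_stretch: float = 0.2
    k_bend: float = 0.01
    k_rest: float = 2.0e-3
    c_damp: float = 0.1
    rest_angle_deg: float = 30.0
    tip_gap_fraction: float = 0.35
    contact_k: float = 0.2
    contact_range: float = 0.5  # lattice units
    mobility: float = 0.5      # direct node mobility on elastic load (lattice)
    ns_seal: float = 0.98      # partial-bounce-back fraction of leaflet fibre cells
    dp_gain: float = 2.0       # transvalvular pressure load per leaflet node


@dataclass
class CellConfig:
    enabled: bool = True
    radius_cm: float = 0.0025
    offset_cm: float = 0.0008
    k_s: float = 2.0e-3
    k_b: float = 8.0e-4
    k_a: float = 8.0e-4
    k_area: float = 0.05
    produces_NO: bool = False
    NO_rate_coeff: float = 0.0
    mobility: float = 0.2      # direct node mobility on the elastic load


SCENARIOS = ("poiseuille_channel", "single_lymphangion", "full_chain")


@dataclass
class RunConfig:
    scenario: str = "full_chain"
    gravity_level: float = 0.0
    duration_s: float = 2.0
    output_interval_s: float = 1.33e-2
    snapshot_interval_s: float = 0.25
    resolution: int = 10
    seed: int = 0
    cell_enabled: bool = True
    domain: DomainSpec = field(default_factory=DomainSpec)
    fluid: FluidConfig = field(default_factory=FluidConfig)
    wall: WallConfig = field(default_factory=WallConfig)
    valve: ValveConfig = field(default_factory=ValveConfig)
    cell: CellConfig = field(default_factory=CellConfig)
    chem: ChemParams = field(default_factory=ChemParams)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")
        if self.output_interval_s < self.dt:
            raise ConfigurationError("output_interval_s must be >= dt")

    # --- unit mapping -----------------------------------------------------
    @property
    def dx(self) -> float:
        return self.domain.baseline_diameter / self.resolution

    @property
    def dt(self) -> float:
        return lb.CS2 * (self.fluid.tau - 0.5) * self.dx**2 / self.fluid.nu_phys

    @property
    def g_lattice_x(self) -> float:
        """Axial lattice body-force acceleration; positive gravity levels
        oppose the +x flow direction."""
        if self.fluid.body_force_x:
            return self.fluid.body_force_x
        g = self.gravity_level * self.fluid.gravity_scale * G_PHYS
        return -g * self.dt**2 / self.dx

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_s / self.dt))

    @property
    def mu_lattice(self) -> float:
        return self.fluid.rho0 * lb.CS2 * (self.fluid.tau - 0.5)

    @property
    def stress_scale(self) -> float:
        """Lattice stress -> dyn/cm^2 (rho_phys = 1 g/cm^3)."""
        return self.dx**2 / self.dt**2

    def to_dict(self) -> dict:
        return asdict(self)


_BLOCK_TYPES = {
    "domain": DomainSpec,
    "fluid": FluidConfig,
    "wall": WallConfig,
    "valve": ValveConfig,
    "cell": CellConfig,
    "chem": ChemParams,
}


def config_from_dict(data: dict) -> RunConfig:
    """Build a RunConfig from nested plain dicts, rejecting unknown keys."""
    data = dict(data)
    bad: list[str] = []
    kwargs: dict = {}
    top_fields = {f.name for f in dataclasses.fields(RunConfig)}
    for key, val in data.items():
        if key not in top_fields:
            bad.append(key)
            continue
        if key in _BLOCK_TYPES:
            typ = _BLOCK_TYPES[key]
            sub_fields = {f.name for f in dataclasses.fields(typ)}
            bad.extend(f"{key}.{k}" for k in val if k not in sub_fields)
            kwargs[key] = typ(**{k: v for k, v in val.items() if k in sub_fields})
        else:
            kwargs[key] = val
    if bad:
        raise ConfigurationError(f"unknown configuration keys: {bad}")
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


# --- scenario presets -----------------------------------------------------

def poiseuille_channel(resolution: int = 33, body_force: float = 1.0e-6,
                       tau: float = 0.8, duration_s: float = 0.5) -> RunConfig:
    """Body-force-driven channel between no-slip walls (fluid validation)."""
    return RunConfig(
        scenario="poiseuille_channel",
        resolution=resolution,
        duration_s=duration_s,
        cell_enabled=False,
        fluid=FluidConfig(tau=tau, body_force_x=body_force, rho_tissue=1.0),
    )


def single_lymphangion(gravity_level: float = 0.0, duration_s: float = 1.0,
                       cell_enabled: bool = False) -> RunConfig:
    """One collecting lymphangion bounded by two valves (short vessel)."""
    dom = DomainSpec(
        vessel_length=0.20,
        initial_segment_length=0.05,
        outlet_stub_length=0.0296,
        n_collecting_lymphangions=1,
    )
    # the single-lymphangion chain holds 2 lymphangions (collecting + outlet)
    return RunConfig(
        scenario="single_lymphangion",
        gravity_level=gravity_level,
        duration_s=duration_s,
        resolution=10,
        cell_enabled=cell_enabled,
        domain=dom,
        fluid=FluidConfig(gravity_scale=0.025),
        cell=CellConfig(radius_cm=0.003),
    )


def full_chain(gravity_level: float = 1.0, duration_s: float = 3.0,
               cell_enabled: bool = True, cell_produces_NO: bool = False,
               resolution: int = 10, seed: int = 0) -> RunConfig:
    """Desk-scale six-lymphangion chain (the paper-style study condition).

    Coarse grid (10 nodes across the lumen), reduced gravity scale (see the
    module docstring), a cell sized to stay resolvable on the coarse lattice.
    """
    return RunConfig(
        scenario="full_chain",
        gravity_level=gravity_level,
        duration_s=duration_s,
        resolution=resolution,
        seed=seed,
        cell_enabled=cell_enabled,
        domain=DomainSpec(),
        fluid=FluidConfig(tau=1.0, gravity_scale=0.025),
        cell=CellConfig(radius_cm=0.003, produces_NO=cell_produces_NO,
                        NO_rate_coeff=2.0 if cell_produces_NO else 0.0),
    )
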