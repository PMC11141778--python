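"""Deformable leukocyte model.

The cell is a closed 20-segment elastic membrane enclosing fluid of the same
density as its surroundings (neutrally buoyant).  The membrane carries
stretching springs on segments, bending springs at vertices, radial anchor
springs to the instantaneous centroid, and a weak area-compressibility
penalty; the total stored elastic energy Epc measures the deviation of the
cell shape from its circular rest configuration.  The membrane is coupled to
the fluid with the immersed-boundary method: elastic forces are spread onto
the lattice and membrane nodes advect with the interpolated fluid velocity
(no-slip membrane).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import elastic, ib
from .errors import ConfigurationError

N_SEGMENTS = 20


@dataclass
class CellMembrane:
    """Closed elastic membrane with centroid anchoring (lattice units)."""

    nodes: np.ndarray            # (20, 2) lattice coords (x, y)
    radius0: float               # rest radius, lattice
    k_s: float                   # stretch stiffness
    k_b: float                   # bending stiffness
    k_a: float                   # radial anchor stiffness
    k_area: float = 0.0          # area-compressibility penalty
    produces_NO: bool = False
    NO_rate_coeff: float = 0.0   # NO production per unit average surface shear
    l0: np.ndarray = field(init=False)
    theta0: np.ndarray = field(init=False)
    A0: float = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.nodes)
        self.l0 = np.full(n, 2.0 * self.radius0 * np.sin(np.pi / n))
        self.theta0 = np.full(n, 2.0 * np.pi / n)
        # rest area of the regular inscribed polygon
        self.A0 = 0.5 * n * self.radius0**2 * np.sin(2.0 * np.pi / n)

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def center(self) -> np.ndarray:
        return self.nodes.mean(axis=0)

    def area(self) -> float:
        return elastic.polygon_area(self.nodes)


def _accumulate(cell: CellMembrane, P: np.ndarray, F: np.ndarray) -> float:
    n = len(P)
    idx = np.arange(n)
    nxt = (idx + 1) % n
    prv = (idx - 1) % n
    E = elastic.stretch(P, idx, nxt, cell.k_s, cell.l0, F)
    E += elastic.bend(P, prv, idx, nxt, cell.k_b, cell.theta0, F)
    E += elastic.radial_anchor(P, cell.k_a, cell.radius0, F)
    if cell.k_area > 0:
        E += elastic.area_penalty(P, cell.k_area, cell.A0, F)
    return E


def membrane_forces(cell: CellMembrane) -> tuple[np.ndarray, float]:
    """Per-node elastic force = exact -dE/dx, and the total energy Epc.

    Net force and net torque vanish on an isolated membrane because every
    energy term is translation- and rotation-invariant.
    """
    F = np.zeros_like(cell.nodes)
    E = _accumulate(cell, cell.nodes, F)
    return F, E


def compute_Epc(cell: CellMembrane) -> float:
    """Total elastic potential energy stored in the membrane springs.

    Zero exactly when all segment lengths, vertex angles, radii (and the
    enclosed area) are at their circular rest values; positive otherwise.
    """
    F = np.zeros_like(cell.nodes)
    return _accumulate(cell, cell.nodes, F)


def cell_fluid_coupling(
    cell: CellMembrane,
    force_field: np.ndarray,
    u_field: np.ndarray,
    extra_force: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """One immersed-boundary coupling step.

    Spreads membrane elastic (+ optional contact) forces into ``force_field``
    and returns the interpolated node velocities and the current Epc.  The
    caller advances the node positions (no-slip membrane).
    """
    F, E = membrane_forces(cell)
    if extra_force is not None:
        F = F + extra_force
    ib.spread(cell.nodes, F, force_field)
    vel = ib.interpolate(u_field, cell.nodes)
    return vel, E


def cell_surface_shear(u_field: np.ndarray, cell: CellMembrane) -> float:
    """Average off-diagonal rate-of-strain magnitude at the membrane nodes.

    Returns the mean |du_x/dy + du_y/dx| interpolated at the nodes, in
    lattice units; multiply by the dynamic viscosity for a stress.
    """
    dudy = np.gradient(u_field[0], axis=0)
    dvdx = np.gradient(u_field[1], axis=1)
    s = ib.interpolate(dudy + dvdx, cell.nodes)
    return float(np.mean(np.abs(s)))


def initialize_cell(
    geom,
    radius_cm: float,
    offset_cm: float = 0.0008,
    k_s: float = 0.05,
    k_b: float = 0.01,
    k_a: float = 0.02,
    k_area: float = 0.05,
    produces_NO: bool = False,
    NO_rate_coeff: float = 0.0,
    x_entry_cm: float | None = None,
) -> CellMembrane:
    """Place a circular cell near the vessel entrance.

    The centroid sits ``offset_cm`` above the lumen centreline (default
    8e-4 cm) at the upstream end of the initial lymphatic.
    """
    r = radius_cm / geom.dx
    off = offset_cm / geom.dx
    half_lumen = (geom.y_top_rest[0] - geom.y_bot_rest[0] - 1.0) / 2.0
    if r >= half_lumen:
        raise ConfigurationError(
            f"cell radius {radius_cm} cm does not fit in the lumen"
        )
    if x_entry_cm is None:
        # mid-way along the first (entrance) lymphangion of the collecting
        # chain: clear of the upstream valve's closing backjet, so the
        # contraction wave carries the cell down the chain
        xc = 0.5 * float(geom.valve_x[0] + geom.valve_x[1])
    else:
        xc = geom.x0 + x_entry_cm / geom.dx
    yc = geom.yc + off
    if abs(off) + r >= half_lumen:
        raise ConfigurationError("cell overlaps the vessel wall at placement")
    th = np.linspace(0.0, 2.0 * np.pi, N_SEGMENTS, endpoint=False)
    nodes = np.stack([xc + r * np.cos(th), yc + r * np.sin(th)], axis=1)
    return CellMembrane(
        nodes=nodes, radius0=r, k_s=k_s, k_b=k_b, k_a=k_a, k_area=k_area,
        produces_NO=produces_NO, NO_rate_coeff=NO_rate_coeff,
    )
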