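"""Passive bi-leaflet intraluminal valves.

Each valve consists of two viscoelastic leaflet chains anchored at opposite
wall nodes, biased open at rest: the rest shape is a straight chain inclined
~30 degrees downstream from the wall, leaving a tip gap of ~40% of the lumen
diameter.  Leaflets carry stretching and bending springs (the base angle is
maintained against a ghost point on the wall tangent) plus velocity damping,
and couple to the fluid through the immersed-boundary kernel.  Opening and
closing are entirely passive: no valve logic, only fluid forces and
leaflet-leaflet/leaflet-cell contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import elastic, ib
from .errors import ConfigurationError


@dataclass
class ValveLeaflet:
    """One leaflet: ordered Lagrangian chain from wall anchor to free tip."""

    nodes: np.ndarray        # (m, 2) lattice coords; node 0 is the anchor
    rest_local: np.ndarray   # (m, 2) rest offsets from the anchor
    anchor_col: int          # index into the wall chain (column)
    anchor_x: float          # fixed axial anchor position (lattice)
    side: int                # +1 top wall, -1 bottom wall
    k_stretch: float
    k_bend: float
    c_damp: float
    k_rest: float = 2.0e-3   # weak spring to the open-bias rest configuration
    l0: np.ndarray = field(init=False)
    theta0: np.ndarray = field(init=False)
    theta0_base: float = field(init=False)
    prev_nodes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        seg = np.diff(self.rest_local, axis=0)
        self.l0 = np.hypot(seg[:, 0], seg[:, 1])
        ang = np.arctan2(seg[:, 1], seg[:, 0])
        self.theta0 = np.diff(ang)
        # base angle of the first segment relative to the wall tangent (+x)
        self.theta0_base = float(ang[0])
        self.prev_nodes = self.nodes.copy()

    @property
    def m(self) -> int:
        return len(self.nodes)

    @property
    def length(self) -> float:
        seg = np.diff(self.nodes, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    @property
    def tip(self) -> np.ndarray:
        return self.nodes[-1]


def make_valve_pair(
    geom,
    valve_index: int,
    n_nodes: int = 10,
    k_stretch: float = 0.3,
    k_bend: float = 0.12,
    c_damp: float = 0.05,
    rest_angle_deg: float = 30.0,
    tip_gap_fraction: float = 0.4,
    k_rest: float = 1.0e-3,
) -> tuple[ValveLeaflet, ValveLeaflet]:
    """Build the two leaflets of valve ``valve_index`` in their open rest shape."""
    x_anchor = int(geom.valve_x[valve_index])
    col = x_anchor - geom.x0
    w = geom.y_top_rest[col] - geom.y_bot_rest[col] - 1.0  # lumen width
    drop = 0.5 * w * (1.0 - tip_gap_fraction)              # vertical extent
    ang = np.deg2rad(rest_angle_deg)
    L = drop / np.sin(ang)
    if L / (n_nodes - 1) < 0.4:
        n_nodes = max(4, int(L / 0.6) + 1)
    s = np.linspace(0.0, L, n_nodes)
    leaflets = []
    for side in (+1, -1):
        local = np.stack([s * np.cos(ang), -side * s * np.sin(ang)], axis=1)
        y_wall = geom.y_top_rest[col] if side > 0 else geom.y_bot_rest[col]
        anchor = np.array([float(x_anchor), y_wall - side * 0.5])
        lf = ValveLeaflet(
            nodes=anchor + local,
            rest_local=local,
            anchor_col=col,
            anchor_x=float(x_anchor),
            side=side,
            k_stretch=k_stretch,
            k_bend=k_bend,
            c_damp=c_damp,
            k_rest=k_rest,
        )
        leaflets.append(lf)
    return tuple(leaflets)


def leaflet_internal_forces(lf: ValveLeaflet) -> tuple[np.ndarray, float]:
    """Stretch + bend (+ base-orientation) forces; exact -dE/dx of the
    leaflet elastic energy with the anchor and wall tangent held fixed."""
    P = lf.nodes
    m = lf.m
    F = np.zeros_like(P)
    ii = np.arange(m - 1)
    E = elastic.stretch(P, ii, ii + 1, lf.k_stretch, lf.l0, F)
    if m > 2:
        a = np.arange(m - 2)
        E += elastic.bend(P, a, a + 1, a + 2, lf.k_bend, lf.theta0, F)
    # base bending against a ghost point on the wall tangent keeps the
    # open-bias orientation; the wall (ghost) takes no reaction here
    ghost = (P[0] - np.array([lf.l0[0], 0.0]))[None, :]
    E += elastic.bend(
        P, np.array([0]), np.array([0]), np.array([1]),
        lf.k_bend, np.array([lf.theta0_base]), F, ghost_a=ghost,
    )
    # weak distributed spring toward the anchor-following open-bias rest
    # configuration: restores a flattened leaflet on a controlled timescale
    # while staying far weaker than the fluid drag that closes the valve
    if lf.k_rest > 0:
        target = P[0] + lf.rest_local
        d = target - P
        F += lf.k_rest * d
        E += 0.5 * lf.k_rest * float(np.sum(d * d))
    # the anchor node is pinned to the wall; its elastic reaction is carried
    # by the wall tether, not by the fluid
    F[0] = 0.0
    return F, E


def leaflet_damping(lf: ValveLeaflet) -> np.ndarray:
    """Viscous force opposing node motion (velocity from the last step)."""
    vel = lf.nodes - lf.prev_nodes
    return -lf.c_damp * vel


def valve_fluid_coupling(
    leaflets: list[ValveLeaflet],
    force_field: np.ndarray,
    u_field: np.ndarray,
    extra: dict[int, np.ndarray] | None = None,
) -> list[np.ndarray]:
    """Spread leaflet forces to the lattice and interpolate node velocities.

    ``extra`` maps leaflet list indices to additional (contact) forces.
    Returns interpolated node velocities per leaflet; the caller advances
    positions and re-pins anchors to the wall.
    """
    vels = []
    for k, lf in enumerate(leaflets):
        F, _ = leaflet_internal_forces(lf)
        F = F + leaflet_damping(lf)
        if extra is not None and k in extra:
            F = F + extra[k]
        ib.spread(lf.nodes, F, force_field)
        vels.append(ib.interpolate(u_field, lf.nodes))
    return vels
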