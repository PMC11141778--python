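"""Lagrangian viscoelastic vessel wall.

Each wall chain node (one per lattice column, top and bottom) is anchored to
the surrounding tissue by a viscoelastic spring oriented along the local wall
normal (vertical for the straight vessel).  The wall is massless/overdamped:
the normal velocity is the net normal load divided by the damping
coefficient, with the per-step displacement capped at half a lattice spacing
so at most one node layer is remapped per step.

The fluid side is a sharp-interface moving bounce-back (in
:func:`lymphflow.lattice.bounce_back_solids`); this module supplies the wall
load, the overdamped update, and the tissue<->fluid node remapping as the
discrete wall row crosses lattice rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import lattice as lb
from .errors import InvalidStateError

DISPLACEMENT_CAP = 0.5  # lattice units per step


@dataclass
class WallState:
    """Positions/velocities of the two wall chains (lattice units).

    ``y_top``/``y_bot`` are continuous wall positions per vessel column;
    velocities are per-step displacements.  Only columns flagged flexible
    ever move.
    """

    y_top: np.ndarray
    y_bot: np.ndarray
    v_top: np.ndarray = field(init=False)
    v_bot: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.v_top = np.zeros_like(self.y_top)
        self.v_bot = np.zeros_like(self.y_bot)

    def diameter(self, geom) -> np.ndarray:
        """Local lumen width in lattice units (node rows between the walls)."""
        return self.y_top - self.y_bot - 1.0


def wall_force(
    displacement: np.ndarray,
    velocity: np.ndarray,
    p_in: np.ndarray,
    p_tissue: np.ndarray,
    k_tether: float,
    c_damp: float,
    ca_force: np.ndarray,
    segment_length: float = 1.0,
) -> np.ndarray:
    """Net outward-normal force per wall node.

    ``displacement`` is the outward normal displacement from the rest
    position; ``p_in``/``p_tissue`` are the pressures sampled on the lumen
    and tissue sides; ``ca_force`` is the inward active contraction force.
    """
    return (
        (p_in - p_tissue) * segment_length
        - k_tether * displacement
        - c_damp * velocity
        - ca_force
    )


def advance_wall(
    y: np.ndarray,
    v: np.ndarray,
    force_wo_damping: np.ndarray,
    c_damp: float,
    outward_sign: float,
    movable: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Overdamped update: normal velocity = load / damping, displacement
    capped at 0.5 lattice units.  Returns (y_new, v_new, n_capped)."""
    vn = force_wo_damping / c_damp
    dy = np.clip(vn, -DISPLACEMENT_CAP, DISPLACEMENT_CAP)
    n_capped = int(np.sum(np.abs(vn) > DISPLACEMENT_CAP))
    dy = np.where(movable, dy, 0.0)
    return y + outward_sign * dy, outward_sign * dy, n_capped


def remap_columns(
    f: np.ndarray,
    node_type: np.ndarray,
    ns_map: np.ndarray,
    cols: np.ndarray,
    j_old: np.ndarray,
    j_new: np.ndarray,
    inward_dir: int,
    tissue_ns: float,
    rho_tissue: float,
    j_opposite: np.ndarray | None = None,
) -> float:
    """Reclassify lattice nodes as a wall chain's discrete row moves.

    ``inward_dir`` is -1 for the top wall (lumen below) and +1 for the bottom
    wall.  When the wall moves outward the vacated row becomes lumen fluid
    with populations extrapolated linearly from the two nearest lumen
    neighbours; when it moves inward the vacated row reverts to porous tissue
    at the far-field density and the newly covered lumen row becomes wall.

    Lumen mass is conserved: populations of a node absorbed by the advancing
    wall are redistributed over the remaining lumen column (pressurising it,
    which is what ejects the stroke volume axially), and the mass of a node
    created by the receding wall is drawn from the column (the suction of
    diastolic refill).  ``j_opposite`` gives the opposite wall row per moved
    column for the rescaling; without it the legacy non-conservative refill
    is used.  Returns the net lattice mass created (bookkeeping).
    """
    dmass = 0.0
    moved = np.nonzero(j_new != j_old)[0]
    for c in moved:
        x = int(cols[c])
        jo, jn = int(j_old[c]), int(j_new[c])
        step = 1 if jn > jo else -1
        if abs(jn - jo) > 1:
            raise InvalidStateError(
                "wall crossed more than one lattice row in a single step"
            )
        outward = (step == -inward_dir)
        if outward:
            # vacated node jo becomes lumen fluid: linear extrapolation from
            # the two nearest interior fluid nodes along the normal
            j1 = jo + inward_dir
            j2 = jo + 2 * inward_dir
            rho1 = f[:, j1, x].sum()
            u1 = (lb.E.T.astype(float) @ f[:, j1, x]) / rho1
            if node_type[j2, x] == lb.FLUID:
                rho2 = f[:, j2, x].sum()
                u2 = (lb.E.T.astype(float) @ f[:, j2, x]) / rho2
                rho_n = max(2 * rho1 - rho2, 0.1)
                u_n = 2 * u1 - u2
            else:
                rho_n, u_n = rho1, u1
            dmass -= f[:, jo, x].sum()
            f[:, jo, x] = lb.equilibrium(np.full(1, rho_n), u_n[:, None])[:, 0]
            dmass += rho_n
            node_type[jo, x] = lb.FLUID
            ns_map[jo, x] = 0.0
            if j_opposite is not None:
                # draw the created mass from the lumen column (suction)
                lum = _lumen_slice(jo, int(j_opposite[c]), inward_dir)
                col_mass = f[:, lum, x].sum()
                if col_mass > 2 * rho_n:
                    f[:, lum, x] *= 1.0 - rho_n / col_mass
                    dmass -= rho_n
            # the newly occupied wall row was tissue
            dmass -= f[:, jn, x].sum()
            f[:, jn, x] = 0.0
            node_type[jn, x] = lb.SOLID
            ns_map[jn, x] = 1.0
        else:
            # wall moves inward: jo reverts to tissue, jn (was lumen) -> wall
            dmass -= f[:, jo, x].sum()
            f[:, jo, x] = lb.equilibrium(
                np.full(1, rho_tissue), np.zeros((2, 1))
            )[:, 0]
            dmass += rho_tissue
            node_type[jo, x] = lb.POROUS
            ns_map[jo, x] = tissue_ns
            swallowed = f[:, jn, x].sum()
            dmass -= swallowed
            f[:, jn, x] = 0.0
            node_type[jn, x] = lb.SOLID
            ns_map[jn, x] = 1.0
            if j_opposite is not None and swallowed > 0:
                # redistribute the swallowed mass over the remaining lumen
                # column: the piston displaces fluid, it does not delete it
                lum = _lumen_slice(jn, int(j_opposite[c]), inward_dir)
                col_mass = f[:, lum, x].sum()
                if col_mass > 0:
                    f[:, lum, x] *= 1.0 + swallowed / col_mass
                    dmass += swallowed
    return dmass


def _lumen_slice(j_wall_row: int, j_opp: int, inward_dir: int) -> slice:
    """Rows of the open lumen between a wall row and the opposite wall row."""
    if inward_dir < 0:  # top wall: lumen below
        return slice(j_opp + 1, j_wall_row)
    return slice(j_wall_row + 1, j_opp)
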