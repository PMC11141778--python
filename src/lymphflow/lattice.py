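"""D2Q9 lattice-Boltzmann fluid core.

Implements the Eulerian fluid solver used throughout the package: BGK
collision with Guo second-order forcing, push streaming, halfway bounce-back
on (possibly moving) solid nodes, Walsh-style partial bounce-back for the
porous interstitial tissue, a Zou-He pressure outlet, and an equilibrium
far-field (tissue) boundary.

All quantities in this module are in lattice units: dx = dt = 1 and the
reference density is ``rho0``.  Conversion to physical units is the job of
:mod:`lymphflow.config`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvalidStateError, NumericalBlowupError

# lattice sound speed squared
CS2 = 1.0 / 3.0

# D2Q9 velocity set, ordered rest / axis / diagonal
E = np.array(
    [[0, 0], [1, 0], [0, 1], [-1, 0], [0, -1], [1, 1], [-1, 1], [-1, -1], [1, -1]],
    dtype=np.int64,
)
W = np.array(
    [4 / 9, 1 / 9, 1 / 9, 1 / 9, 1 / 9, 1 / 36, 1 / 36, 1 / 36, 1 / 36]
)
OPP = np.array([0, 3, 4, 1, 2, 7, 8, 5, 6])

# node classification codes
FLUID = 0
POROUS = 1
SOLID = 2
EQ_BOUNDARY = 3
OUTLET = 4
GAP = 5

#: codes on which the fluid populations evolve
FLUID_LIKE = (FLUID, POROUS, GAP, OUTLET)


@dataclass
class FluidParams:
    """Fluid/lattice parameters.

    Parameters
    ----------
    tau:
        BGK relaxation time in lattice units; must exceed 1/2 for a positive
        kinematic viscosity ``nu = cs^2 (tau - 1/2)``.
    dx, dt:
        Physical lattice spacing (cm) and time step (s) of the mapping.
    rho0:
        Reference lattice density (pressure datum).
    g_lattice:
        Uniform gravity body-force density per unit lattice mass,
        2-vector in lattice units (applied on all fluid-like nodes).
    max_u:
        Stability guardrail; the driver aborts when max |u| exceeds it.
    """

    tau: float
    dx: float
    dt: float
    rho0: float = 1.0
    g_lattice: tuple[float, float] = (0.0, 0.0)
    max_u: float = 0.15

    def __post_init__(self) -> None:
        if self.tau <= 0.5:
            raise ConfigurationError(f"tau must exceed 0.5, got {self.tau}")
        if self.dx <= 0 or self.dt <= 0:
            raise ConfigurationError("dx and dt must be positive")

    @property
    def nu_lattice(self) -> float:
        return CS2 * (self.tau - 0.5)

    @property
    def nu_physical(self) -> float:
        """Kinematic viscosity implied by the unit mapping (cm^2/s)."""
        return self.nu_lattice * self.dx**2 / self.dt


@dataclass
class LatticeState:
    """Eulerian state: populations, moments and the node-type mask."""

    f: np.ndarray          # (9, ny, nx)
    rho: np.ndarray        # (ny, nx)
    u: np.ndarray          # (2, ny, nx)
    node_type: np.ndarray  # (ny, nx) int8
    time: int = 0

    @classmethod
    def uniform(cls, node_type: np.ndarray, rho0: float = 1.0) -> "LatticeState":
        ny, nx = node_type.shape
        rho = np.full((ny, nx), rho0)
        u = np.zeros((2, ny, nx))
        f = equilibrium(rho, u)
        return cls(f=f, rho=rho, u=u, node_type=node_type.astype(np.int8), time=0)

    @property
    def fluid_mask(self) -> np.ndarray:
        return np.isin(self.node_type, FLUID_LIKE)


def equilibrium(rho: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Second-order D2Q9 equilibrium distribution.

    ``rho`` has any shape S, ``u`` has shape (2, *S); returns (9, *S).
    Moments of the result reproduce (rho, rho*u) exactly.
    """
    rho = np.asarray(rho, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(rho <= 0):
        raise InvalidStateError("equilibrium requires rho > 0 everywhere")
    eu = np.tensordot(E.astype(float), u, axes=(1, 0))  # (9, *S)
    u2 = np.sum(u * u, axis=0)
    w = W.reshape((9,) + (1,) * rho.ndim)
    return w * rho * (1.0 + eu / CS2 + 0.5 * eu**2 / CS2**2 - 0.5 * u2 / CS2)


def macroscopic(
    f: np.ndarray,
    force: np.ndarray | None = None,
    fluid_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Density and (force-corrected) velocity moments.

    ``u = (sum_i f_i e_i + F/2) / rho`` -- the half-force shift is the
    Guo-consistent definition of the macroscopic velocity.
    """
    rho = f.sum(axis=0)
    mom = np.tensordot(E.T.astype(float), f, axes=(1, 0))  # (2, ny, nx)
    if force is not None:
        mom = mom + 0.5 * force
    check = rho if fluid_mask is None else rho[fluid_mask]
    if check.size and (np.any(check <= 0) or np.any(~np.isfinite(check))):
        bad = np.argwhere(
            (rho <= 0) | ~np.isfinite(rho)
            if fluid_mask is None
            else fluid_mask & ((rho <= 0) | ~np.isfinite(rho))
        )
        raise NumericalBlowupError(
            f"non-positive/NaN density at nodes (y,x)={bad[:5].tolist()}"
        )
    safe = np.where(rho > 0, rho, 1.0)
    u = mom / safe
    return rho, u


def guo_force_term(u: np.ndarray, force: np.ndarray) -> np.ndarray:
    """Guo et al. second-order forcing populations (before the 1-1/2tau factor)."""
    ef = np.tensordot(E.astype(float), force, axes=(1, 0))  # (9,...)
    eu = np.tensordot(E.astype(float), u, axes=(1, 0))
    uf = np.sum(u * force, axis=0)
    w = W.reshape((9,) + (1,) * u.shape[1:].__len__())
    return w * ((ef - uf) / CS2 + eu * ef / CS2**2)


def collide_and_force(
    f: np.ndarray,
    rho: np.ndarray,
    u: np.ndarray,
    tau: float,
    force: np.ndarray | None = None,
) -> np.ndarray:
    """BGK relaxation toward equilibrium plus Guo forcing.

    ``u`` must already contain the half-force shift (see :func:`macroscopic`);
    the scheme then adds momentum ``F dt`` per node per step exactly.
    """
    if tau <= 0.5:
        raise ConfigurationError(f"tau must exceed 0.5, got {tau}")
    feq = equilibrium(rho, u)
    out = f - (f - feq) / tau
    if force is not None:
        out = out + (1.0 - 0.5 / tau) * guo_force_term(u, force)
    return out


def stream(f: np.ndarray) -> np.ndarray:
    """Advect each population one lattice link (periodic wrap; boundaries
    are repaired afterwards by the boundary-condition fix-ups)."""
    out = np.empty_like(f)
    for i in range(9):
        ex, ey = E[i]
        out[i] = np.roll(f[i], shift=(ey, ex), axis=(0, 1))
    return out


def partial_bounce_back(f_post: np.ndarray, ns: np.ndarray) -> np.ndarray:
    """Walsh-type partial bounce-back for porous nodes.

    At each node a fraction ``ns`` of every post-collision population is
    swapped with its opposite direction before streaming.  ns=0 leaves the
    populations untouched (free fluid); ns=1 reflects everything (solid
    limit).  Mass is conserved node-locally and exactly.
    """
    ns = np.asarray(ns, dtype=float)
    if np.any(ns < 0) or np.any(ns > 1):
        raise ConfigurationError("porous solid fraction ns must lie in [0, 1]")
    if not np.any(ns > 0):
        return f_post
    return (1.0 - ns) * f_post + ns * f_post[OPP]


def solid_receive_masks(solid: np.ndarray) -> list[np.ndarray]:
    """Per-direction masks of fluid nodes whose upwind neighbour is solid.

    Precomputable whenever the solid set changes; passing them to
    :func:`bounce_back_solids` avoids eight mask rolls per step.
    """
    masks = []
    for i in range(1, 9):
        ex, ey = E[i]
        src_solid = np.roll(solid, shift=(ey, ex), axis=(0, 1))
        masks.append(src_solid & ~solid)
    return masks


def bounce_back_solids(
    f_streamed: np.ndarray,
    f_post: np.ndarray,
    solid: np.ndarray,
    u_wall: np.ndarray | None = None,
    rho0: float = 1.0,
    recv_masks: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Halfway bounce-back on (moving) solid nodes, applied after streaming.

    For every fluid node with a solid neighbour in direction ``-e_i`` the
    invalid incoming population is replaced by
    ``f_i = f_post_opp(i) + 2 w_i rho0 (e_i . u_w)/cs^2``
    with ``u_w`` the solid node's velocity (zero for static obstacles).

    Returns the repaired field and the net momentum impulse delivered TO the
    fluid (2-vector, lattice units); the reaction on the structures is its
    negative by construction.
    """
    out = f_streamed.copy()
    impulse = np.zeros(2)
    if recv_masks is None:
        recv_masks = solid_receive_masks(solid)
    for i in range(1, 9):
        ex, ey = E[i]
        mask = recv_masks[i - 1]
        if not np.any(mask):
            continue
        new_val = f_post[OPP[i]][mask]
        if u_wall is not None:
            uw = np.roll(u_wall, shift=(0, ey, ex), axis=(0, 1, 2))
            eu = ex * uw[0][mask] + ey * uw[1][mask]
            new_val = new_val + 2.0 * W[i] * rho0 * eu / CS2
        old_val = out[i][mask]
        out[i][mask] = new_val
        d = np.sum(new_val - old_val)
        impulse[0] += ex * d
        impulse[1] += ey * d
    return out, impulse


def pressure_outlet(
    f: np.ndarray, ys: np.ndarray, x: int, rho_out: float
) -> np.ndarray:
    """Zou-He pressure (density) condition on an east-facing outlet column.

    Reconstructs the three unknown west-pointing populations at nodes
    (ys, x) so the nodal density equals ``rho_out = p_out / cs^2`` with zero
    transverse velocity.
    """
    if rho_out <= 0:
        raise ConfigurationError("outlet density/pressure must be positive")
    fb = f[:, ys, x]
    ux = -1.0 + (fb[0] + fb[2] + fb[4] + 2.0 * (fb[1] + fb[5] + fb[8])) / rho_out
    f[3, ys, x] = fb[1] - (2.0 / 3.0) * rho_out * ux
    f[7, ys, x] = fb[5] + 0.5 * (fb[2] - fb[4]) - (1.0 / 6.0) * rho_out * ux
    f[6, ys, x] = fb[8] - 0.5 * (fb[2] - fb[4]) - (1.0 / 6.0) * rho_out * ux
    return f


def tissue_boundary(
    f: np.ndarray, mask: np.ndarray, rho_tissue: float
) -> np.ndarray:
    """Equilibrium far-field boundary representing quiescent tissue.

    Boundary nodes are clamped to the equilibrium distribution at the
    far-field tissue density with zero velocity; fluid may enter or leave
    across them depending on the interior pressure.
    """
    n = int(mask.sum())
    if n == 0:
        return f
    feq = equilibrium(np.full(n, rho_tissue), np.zeros((2, n)))
    f[:, mask] = feq
    return f
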