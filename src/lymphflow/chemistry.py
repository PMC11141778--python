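"""Ca++/NO mechanochemical regulation of lymphatic contractions.

Calcium lives on the contracting vessel wall (one gap-junction-coupled value
per wall column; the muscle layer is assumed vertically symmetric).  It is
produced at a baseline rate, amplified by calcium-induced calcium release
(CICR, a Hill nonlinearity) and by stretch-activated channels responding to
diameter increase, degraded with first-order kinetics accelerated by local
NO, and diffuses laterally along the wall.  When Ca++ crosses a threshold the
node enters a contracting state during which the active force is
proportional to Ca++ and cytoplasmic Ca++ is depleted; a refractory window
(set by the recharge rate) then suppresses CICR and stretch activation while
baseline kinetics restore the resting level.

NO is produced at wall- and valve-adjacent fluid nodes in proportion to the
local shear stress (optionally also at the cell surface), is advected and
diffuses in the fluid, and decays exponentially with a 0.31 s half-life.

Both concentrations are dimensionless: Ca++ is scaled so the contraction
threshold is 1, NO so that a reference physiological wall shear stress in
steady flow sustains a near-wall level of order 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import lattice as lb
from .errors import ConfigurationError

RESTING, CONTRACTING, REFRACTORY = 0, 1, 2


@dataclass
class ChemParams:
    """Rates in physical units (per second, cm^2/s); concentrations unitless."""

    ca_base: float = 0.5          # baseline Ca++ production (1/s)
    k_ca_deg: float = 0.6         # first-order Ca++ degradation (1/s)
    k_cicr: float = 0.35          # CICR gain (1/s)
    cicr_half: float = 0.5        # CICR half-saturation (Ca units)
    k_stretch: float = 1.0        # stretch gain (1/s per unit relative stretch)
    ca_thresh: float = 1.0        # contraction threshold (Ca scale definition)
    ca_off: float = 0.55          # contraction ends below this level
    ca_spike: float = 1.5         # CICR release level reached at trigger
    f_ca: float = 0.09            # contraction force per unit Ca (lattice force)
    k_deplete: float = 3.0        # cytoplasmic depletion during contraction (1/s)
    recharge_rate: float = 3.0    # 1/refractory duration (1/s)
    D_ca: float = 3.0e-5          # lateral wall diffusivity (cm^2/s)
    k_no_prod: float = 60.0       # NO production per (dyn/cm^2) wall shear (1/s)
    t_half_no: float = 0.31       # NO half-life (s)
    D_no: float = 3.3e-5          # NO diffusivity (cm^2/s)
    k_no_ca: float = 0.8          # NO enhancement of Ca++ degradation
    ca_init_frac: float = 0.95    # initial Ca as a fraction of threshold
    ca_init_jitter: float = 0.002 # seeded uniform jitter on the initial Ca
    ca_init_grad: float = 0.06    # upstream-to-downstream initial Ca drop
    perturb_gravity: float = 2.0  # adverse level requiring a starting kick
    perturb_factor: float = 2.0   # transient multiplier on f_ca
    perturb_window: float = 0.5   # duration of the kick (s)

    def __post_init__(self) -> None:
        if self.t_half_no <= 0:
            raise ConfigurationError("NO half-life must be positive")
        neg = [
            k for k in ("ca_base", "k_ca_deg", "k_cicr", "k_stretch", "f_ca",
                        "k_deplete", "recharge_rate", "D_ca", "k_no_prod",
                        "D_no", "k_no_ca")
            if getattr(self, k) < 0
        ]
        if neg:
            raise ConfigurationError(f"negative chemistry rates: {neg}")

    @property
    def lambda_no(self) -> float:
        return np.log(2.0) / self.t_half_no


@dataclass
class ChemState:
    """Ca++ on the wall chain, NO in the fluid, per-column trigger state."""

    ca: np.ndarray                 # (n_cols,)
    no_field: np.ndarray           # (ny, nx)
    trigger: np.ndarray            # (n_cols,) int in {RESTING, CONTRACTING, REFRACTORY}
    recharge_clock: np.ndarray     # (n_cols,) seconds since contraction end
    f_ca_multiplier: float = 1.0
    n_trigger_events: int = 0
    trigger_log: list = field(default_factory=list)  # (t_s, column) tuples


def initialize_chem(
    params: ChemParams, geom, gravity_level: float,
    rng: np.random.Generator | None = None,
) -> ChemState:
    """Start just below threshold on contracting wall nodes, NO = 0.

    A small seeded jitter on the initial Ca++ breaks the symmetry of the
    uniform start so contractions recruit as a travelling wave rather than
    synchronously.  At high adverse gravity a transient increase of the Ca++
    force constant is scheduled (applied by the driver for
    ``perturb_window`` seconds).
    """
    n = geom.n_cols
    ca = np.zeros(n)
    act = geom.contracting_mask
    ca[act] = params.ca_init_frac * params.ca_thresh
    # upstream pacemaker bias: the upstream end of the chain sits slightly
    # closer to threshold, so contractions recruit as a downstream-travelling
    # peristaltic wave instead of firing synchronously
    if params.ca_init_grad > 0:
        idx = np.nonzero(act)[0]
        ramp = (idx - idx[0]) / max(idx[-1] - idx[0], 1)
        ca[idx] -= params.ca_init_grad * ramp
    if rng is not None and params.ca_init_jitter > 0:
        jit = rng.uniform(-params.ca_init_jitter, 0.0, size=n)
        ca[act] += jit[act]
    st = ChemState(
        ca=ca,
        no_field=np.zeros((geom.ny, geom.nx)),
        trigger=np.zeros(n, dtype=np.int8),
        recharge_clock=np.zeros(n),
    )
    if gravity_level >= params.perturb_gravity:
        st.f_ca_multiplier = params.perturb_factor
    return st


def hill(ca: np.ndarray, half: float) -> np.ndarray:
    """CICR activation: Hill function with exponent 2."""
    c2 = np.maximum(ca, 0.0) ** 2
    return c2 / (c2 + half**2)


def update_calcium(
    chem: ChemState,
    params: ChemParams,
    diameter_rel_stretch: np.ndarray,
    no_at_wall: np.ndarray,
    active: np.ndarray,
    dt: float,
    dx: float,
) -> None:
    """Explicit update of wall Ca++ (in place).

    ``diameter_rel_stretch`` is max(0, (D - D_rest)/D_rest) per column;
    ``active`` marks the wall columns carrying Ca++ dynamics.  During a
    contraction the node only depletes; during refractory CICR and stretch
    terms are suppressed.
    """
    r = params.D_ca * dt / dx**2
    if r > 0.5:
        raise ConfigurationError(
            f"wall Ca++ diffusion CFL violated (D_ca dt/dx^2 = {r:.2f} > 0.5)"
        )
    ca = chem.ca
    lap = np.zeros_like(ca)
    idx = np.nonzero(active)[0]
    if idx.size > 2:
        s = slice(idx[0], idx[-1] + 1)
        seg = ca[s]
        # zero-flux ends along the wall chain
        lap_seg = np.empty_like(seg)
        lap_seg[1:-1] = seg[2:] - 2 * seg[1:-1] + seg[:-2]
        lap_seg[0] = seg[1] - seg[0]
        lap_seg[-1] = seg[-2] - seg[-1]
        lap[s] = lap_seg

    resting = active & (chem.trigger == RESTING)
    refract = active & (chem.trigger == REFRACTORY)
    contract = active & (chem.trigger == CONTRACTING)

    deg = params.k_ca_deg * (1.0 + params.k_no_ca * no_at_wall) * ca
    prod_full = (
        params.ca_base
        + params.k_cicr * hill(ca, params.cicr_half)
        + params.k_stretch * np.maximum(0.0, diameter_rel_stretch)
    )
    dca = np.zeros_like(ca)
    dca[resting] = prod_full[resting] - deg[resting]
    dca[refract] = params.ca_base - deg[refract]
    dca[contract] = -params.k_deplete * ca[contract]
    dca += r * lap / dt  # lap already dimensionless; scale back below
    ca += dt * dca
    np.clip(ca, 0.0, None, out=ca)


def trigger_and_force(
    chem: ChemState,
    params: ChemParams,
    active: np.ndarray,
    dt: float,
    t_now: float,
) -> np.ndarray:
    """State machine + active contraction force per column (lattice units).

    Nodes enter ``contracting`` when Ca++ crosses threshold from below; while
    contracting the force is ``f_ca * ca``; contraction ends when Ca++ has
    depleted below ``ca_off``, followed by a refractory window of duration
    ``1/recharge_rate``.
    """
    ca, trig = chem.ca, chem.trigger
    newly = active & (trig == RESTING) & (ca >= params.ca_thresh)
    if np.any(newly):
        trig[newly] = CONTRACTING
        # rapid CICR release on triggering: the store dumps to the spike
        # level, which sustains recruitment of neighbours via diffusion
        ca[newly] = np.maximum(ca[newly], params.ca_spike)
        cols = np.nonzero(newly)[0]
        chem.n_trigger_events += int(cols.size)
        chem.trigger_log.extend((t_now, int(c)) for c in cols)
    done = active & (trig == CONTRACTING) & (ca <= params.ca_off)
    trig[done] = REFRACTORY
    chem.recharge_clock[done] = 0.0
    ref = trig == REFRACTORY
    chem.recharge_clock[ref] += dt
    recovered = ref & (chem.recharge_clock >= 1.0 / params.recharge_rate)
    trig[recovered] = RESTING

    force = np.zeros_like(ca)
    m = trig == CONTRACTING
    force[m] = params.f_ca * chem.f_ca_multiplier * ca[m]
    return force


def wall_shear_stress(
    u_field: np.ndarray,
    j_wall: np.ndarray,
    cols: np.ndarray,
    inward_dir: int,
    mu_lattice: float,
) -> np.ndarray:
    """Signed tangential wall traction per wall column (lattice units).

    One-sided finite difference of the axial velocity along the wall normal:
    ``tau = mu * u_x(first fluid node) / (half-link distance)`` with the wall
    itself at zero slip.  The sign follows the flow direction.
    """
    ux = u_field[0][j_wall + inward_dir, cols]
    return mu_lattice * ux / 1.0


def update_NO(
    no_field: np.ndarray,
    u_field: np.ndarray,
    source: np.ndarray,
    fluid_mask: np.ndarray,
    params: ChemParams,
    dt: float,
    dx: float,
) -> np.ndarray:
    """Advection-diffusion-decay step for NO (finite-volume, upwind).

    ``source`` is the production rate field (1/s); transport uses the LBM
    velocity converted to physical units by the caller via ``u_field`` given
    in lattice units (converted here with dx/dt).  Solid nodes are treated as
    zero-flux walls.  Negative values are clamped.
    """
    c = np.where(fluid_mask, no_field, 0.0)
    # neighbours, mirrored at solid nodes (zero-flux)
    cE = np.roll(c, -1, axis=1)
    cW = np.roll(c, 1, axis=1)
    cN = np.roll(c, -1, axis=0)
    cS = np.roll(c, 1, axis=0)
    mE = np.roll(fluid_mask, -1, axis=1)
    mW = np.roll(fluid_mask, 1, axis=1)
    mN = np.roll(fluid_mask, -1, axis=0)
    mS = np.roll(fluid_mask, 1, axis=0)
    cE = np.where(mE, cE, c)
    cW = np.where(mW, cW, c)
    cN = np.where(mN, cN, c)
    cS = np.where(mS, cS, c)

    alpha = params.D_no * dt / dx**2
    lap = cE + cW + cN + cS - 4.0 * c

    # first-order upwind advection, velocity in lattice units = CFL number
    ux, uy = u_field[0], u_field[1]
    adv = (
        np.maximum(ux, 0.0) * (c - cW)
        + np.minimum(ux, 0.0) * (cE - c)
        + np.maximum(uy, 0.0) * (c - cS)
        + np.minimum(uy, 0.0) * (cN - c)
    )
    out = c + alpha * lap - adv + dt * (source - params.lambda_no * c)
    np.clip(out, 0.0, None, out=out)
    out[~fluid_mask] = 0.0
    return out
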