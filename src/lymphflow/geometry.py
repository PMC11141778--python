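"""Simulation-domain construction.

Builds the vessel/tissue layout: a blind-ended initial lymphatic whose wall
is 50% permeable gaps (primary valves), a chain of collecting lymphangions
separated by intraluminal valve sites, a rigid non-contracting outlet stub
reaching the pressure outlet, and the surrounding porous tissue seeded with
solid tissue islands.

The vessel axis runs along +x (downstream); the lumen is centred vertically.
Eulerian indices are 0-based; Lagrangian rest positions are stored both in
lattice units and physical cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import lattice as lb
from .errors import ConfigurationError, InvalidStateError


@dataclass
class DomainSpec:
    """Physical layout of the vessel chain and tissue (lengths in cm)."""

    vessel_length: float = 0.56
    baseline_diameter: float = 0.02
    n_collecting_lymphangions: int = 5
    outlet_stub_length: float = 0.0296
    initial_segment_length: float = 0.104
    gap_fraction: float = 0.5
    leak_transmit_fraction: float = 0.15
    tissue_margin: float = 0.02         # tissue thickness above/below vessel
    tissue_ns: float = 0.8              # porous solid fraction of tissue
    island_fraction: float = 0.2        # target solid-island area fraction
    island_size: float = 0.004          # island edge length (cm)

    def __post_init__(self) -> None:
        if not (0.0 <= self.gap_fraction <= 1.0):
            raise ConfigurationError("gap_fraction must lie in [0, 1]")
        if not (0.0 <= self.leak_transmit_fraction <= 1.0):
            raise ConfigurationError("leak_transmit_fraction must lie in [0, 1]")
        collecting = (
            self.vessel_length - self.initial_segment_length - self.outlet_stub_length
        )
        if collecting <= 0:
            raise ConfigurationError(
                "vessel_length must exceed initial segment + outlet stub"
            )

    @property
    def n_lymphangions(self) -> int:
        """Collecting lymphangions plus the outlet lymphangion."""
        return self.n_collecting_lymphangions + 1

    @property
    def lymphangion_length(self) -> float:
        return (
            self.vessel_length - self.initial_segment_length - self.outlet_stub_length
        ) / self.n_lymphangions


@dataclass
class VesselGeometry:
    """Discrete vessel layout on the lattice.

    Wall chains are stored per lattice column of the vessel extent
    ``x0 <= x < nx``: ``y_top_rest``/``y_bot_rest`` are the rest rows of the
    top and bottom wall node chains (integers at build time).
    """

    spec: DomainSpec
    dx: float
    x0: int                       # first vessel column (left cap)
    nx: int
    ny: int
    yc: float                     # lumen centreline row
    y_top_rest: np.ndarray        # (n_cols,) float
    y_bot_rest: np.ndarray
    gap_mask_top: np.ndarray      # (n_cols,) bool — permeable initial-lymphatic nodes
    gap_mask_bot: np.ndarray
    contracting_mask: np.ndarray  # (n_cols,) bool
    flexible_mask: np.ndarray     # (n_cols,) bool — wall free to move
    lymphangion_index: np.ndarray  # (n_cols,) int, -1 outside collecting chain
    valve_x: np.ndarray           # (n_valves,) lattice columns of valve anchors
    x_initial_end: int            # first column of collecting chain
    x_stub_start: int             # first column of the rigid outlet stub

    @property
    def n_cols(self) -> int:
        return self.nx - self.x0

    @property
    def cols(self) -> np.ndarray:
        return np.arange(self.x0, self.nx)

    def measured_length_cm(self) -> float:
        return self.n_cols * self.dx

    def stub_length_cm(self) -> float:
        return (self.nx - self.x_stub_start) * self.dx

    def permeable_fraction(self) -> float:
        init = slice(0, self.x_initial_end - self.x0)
        g = self.gap_mask_top[init].sum() + self.gap_mask_bot[init].sum()
        n = 2 * (self.x_initial_end - self.x0)
        return g / n if n else 0.0


def build_domain(
    spec: DomainSpec, resolution: int
) -> tuple[VesselGeometry, np.ndarray, np.ndarray]:
    """Construct the lattice masks and the vessel geometry.

    ``resolution`` is the number of lattice nodes across the baseline lumen.
    Returns ``(geometry, ns_map, node_type)`` where ``ns_map`` holds the
    porous solid fraction per node and ``node_type`` the classification used
    by the fluid core.
    """
    if resolution < 10:
        raise ConfigurationError("resolution must be at least 10 nodes/diameter")
    dx = spec.baseline_diameter / resolution
    # valve leaflets need >= 3 nodes of tip gap to be representable
    if 0.4 * resolution < 3:
        raise ConfigurationError("resolution too low to represent the valve gap")

    margin = max(4, int(round(spec.tissue_margin / dx)))
    w = resolution                      # lumen width in nodes
    n_vessel = int(round(spec.vessel_length / dx))
    x0 = 2                              # tissue boundary column + one tissue column
    nx = x0 + n_vessel
    ny = w + 2 + 2 * margin
    yc = (ny - 1) / 2.0
    y_top = yc + w / 2.0 + 0.5          # wall node rows (integers for even w)
    y_bot = yc - w / 2.0 - 0.5

    n_cols = nx - x0
    y_top_rest = np.full(n_cols, y_top)
    y_bot_rest = np.full(n_cols, y_bot)

    n_init = int(round(spec.initial_segment_length / dx))
    n_stub = int(round(spec.outlet_stub_length / dx))
    x_initial_end = x0 + n_init
    x_stub_start = nx - n_stub

    # --- valve anchor columns: n_lymphangions + 1 valves in series
    n_lymph = spec.n_lymphangions
    valve_x = np.rint(
        np.linspace(x_initial_end, x_stub_start, n_lymph + 1)
    ).astype(int)

    # --- per-column masks
    cols = np.arange(x0, nx)
    lymphangion_index = np.full(n_cols, -1, dtype=int)
    for k in range(n_lymph):
        sel = (cols >= valve_x[k]) & (cols < valve_x[k + 1])
        lymphangion_index[sel] = k
    contracting_mask = (cols >= x_initial_end) & (cols < x_stub_start)
    flexible_mask = contracting_mask.copy()

    # --- initial-lymphatic permeable gaps: alternating gap/wall segments of
    # equal length chosen so that gap_fraction of the wall is permeable
    gap_mask_top = np.zeros(n_cols, dtype=bool)
    gap_mask_bot = np.zeros(n_cols, dtype=bool)
    if n_init > 0 and spec.gap_fraction > 0:
        # button-junction idealisation: gaps alternate with wall segments of
        # equal length; individual nodes are flipped at the downstream end to
        # hit the requested fraction exactly
        b = max(1, int(round(resolution / 4)))
        local = np.arange(1, n_init)    # keep the cap column solid
        is_gap = (local % (2 * b)) < spec.gap_fraction * 2 * b
        idx = list(local[is_gap])
        target = int(round(spec.gap_fraction * n_init))
        if len(idx) > target:
            idx = idx[:target]
        else:
            extras = [int(i) for i in local[~is_gap]][::-1]
            idx += extras[: target - len(idx)]
        idx = np.array(sorted(idx), dtype=int)
        gap_mask_top[idx] = True
        gap_mask_bot[idx] = True

    # --- Eulerian masks
    ns_map = np.full((ny, nx), spec.tissue_ns)
    node_type = np.full((ny, nx), lb.POROUS, dtype=np.int8)

    jt = np.rint(y_top_rest).astype(int)
    jb = np.rint(y_bot_rest).astype(int)
    for c, x in enumerate(cols):
        node_type[jb[c] + 1 : jt[c], x] = lb.FLUID
        ns_map[jb[c] + 1 : jt[c], x] = 0.0
        for j, gap in ((jt[c], gap_mask_top[c]), (jb[c], gap_mask_bot[c])):
            node_type[j, x] = lb.GAP if gap else lb.SOLID
            ns_map[j, x] = 0.0 if gap else 1.0

    # left cap closes the blind end of the initial lymphatic
    node_type[jb[0] : jt[0] + 1, x0] = lb.SOLID
    ns_map[jb[0] : jt[0] + 1, x0] = 1.0

    # --- solid tissue islands: regular staggered array, clear of the wall
    isl = max(2, int(round(spec.island_size / dx)))
    pitch = max(isl + 1, int(round(isl / np.sqrt(spec.island_fraction))))
    for band, (j_lo, j_hi) in enumerate(
        ((1, jb.min() - 2), (jt.max() + 3, ny - 1))
    ):
        row = 0
        j = j_lo
        while j + isl <= j_hi:
            off = (pitch // 2) if (row % 2) else 0
            for x in range(1 + off, nx - 1 - isl, pitch):
                node_type[j : j + isl, x : x + isl] = lb.SOLID
                ns_map[j : j + isl, x : x + isl] = 1.0
            j += pitch
            row += 1

    # --- domain boundary: equilibrium tissue far field, except lumen outlet
    node_type[0, :] = lb.EQ_BOUNDARY
    node_type[-1, :] = lb.EQ_BOUNDARY
    node_type[:, 0] = lb.EQ_BOUNDARY
    last = nx - 1
    for j in range(ny):
        if node_type[j, last] == lb.FLUID:
            node_type[j, last] = lb.OUTLET
        elif node_type[j, last] != lb.SOLID:
            node_type[j, last] = lb.EQ_BOUNDARY
    ns_map[0, :] = ns_map[-1, :] = ns_map[:, 0] = 0.0

    geom = VesselGeometry(
        spec=spec,
        dx=dx,
        x0=x0,
        nx=nx,
        ny=ny,
        yc=yc,
        y_top_rest=y_top_rest,
        y_bot_rest=y_bot_rest,
        gap_mask_top=gap_mask_top,
        gap_mask_bot=gap_mask_bot,
        contracting_mask=contracting_mask,
        flexible_mask=flexible_mask,
        lymphangion_index=lymphangion_index,
        valve_x=valve_x,
        x_initial_end=x_initial_end,
        x_stub_start=x_stub_start,
    )
    return geom, ns_map, node_type


def primary_valve_flux(
    outgoing_mass: float,
    pressure_gradient_sign: int,
    leak_transmit_fraction: float = 0.15,
) -> tuple[float, float]:
    """Population split at a permeable initial-lymphatic gap node.

    ``pressure_gradient_sign`` is +1 when the gradient favours backflow from
    lumen to tissue and -1 (or 0) when it favours inflow.  Under backflow a
    fraction ``leak_transmit_fraction`` of the outgoing population mass is
    transmitted to the tissue and the rest is reflected to the opposite
    lattice directions; under inflow everything is transmitted.  The two
    parts always sum exactly to the outgoing mass.

    Returns ``(transmitted, reflected)``.
    """
    if not (0.0 <= leak_transmit_fraction <= 1.0):
        raise ConfigurationError("leak_transmit_fraction must lie in [0, 1]")
    if pressure_gradient_sign > 0:
        t = leak_transmit_fraction * outgoing_mass
        return t, outgoing_mass - t
    return outgoing_mass, 0.0


def apply_gap_rule(
    f_post: np.ndarray,
    rho: np.ndarray,
    geom: VesselGeometry,
    node_type: np.ndarray,
) -> np.ndarray:
    """Directional leak rule at the permeable gap nodes, pre-streaming.

    At each gap node, when the local transwall density gradient favours
    backflow (lumen denser than adjacent tissue), populations leaving toward
    the tissue are split: ``leak_transmit_fraction`` continues outward and the
    remainder is reflected to the opposite directions.  Inward-moving
    populations always pass freely.  Mass-conserving by construction.
    """
    ns_gap = 1.0 - geom.spec.leak_transmit_fraction
    out = f_post
    for side, gap_mask, sgn in (
        ("top", geom.gap_mask_top, +1),
        ("bot", geom.gap_mask_bot, -1),
    ):
        cs = geom.cols[gap_mask]
        if cs.size == 0:
            continue
        if side == "top":
            js = np.rint(geom.y_top_rest[gap_mask]).astype(int)
        else:
            js = np.rint(geom.y_bot_rest[gap_mask]).astype(int)
        # backflow-favouring where lumen-side density exceeds tissue-side
        lum = rho[js - sgn, cs]
        tis = rho[js + sgn, cs]
        back = lum > tis
        if not np.any(back):
            continue
        jsb, csb = js[back], cs[back]
        # symmetric partial reflection at the gap node: any population
        # leaving toward the tissue keeps leak_transmit_fraction of its mass
        # and the rest returns to the opposite direction; neutral at
        # equal pressures, mass-conserving by construction
        vals = out[:, jsb, csb]
        out[:, jsb, csb] = (1.0 - ns_gap) * vals + ns_gap * vals[lb.OPP]
    return out
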