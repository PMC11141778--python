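"""Coupled time loop, scenario setup, outputs.

Per time step the coupling order is fixed:

1. macroscopic moments (and stability guards);
2. advect immersed structures (leaflets, cell) with the current velocity;
3. wall/cell shear stresses -> NO transport -> Ca++ update -> trigger and
   active contraction forces;
4. wall loads, overdamped wall advance, tissue<->fluid node remapping;
5. assemble the Eulerian force field (gravity + spread structure forces);
6. BGK collision with Guo forcing, porous partial bounce-back, primary-valve
   leak rule, streaming, moving-wall bounce-back, pressure outlet and
   equilibrium tissue boundary.

Outputs: cell trajectory table, per-lymphangion wall/Ca++ series, exit
velocity profiles, trigger/valve event log, field snapshots and a JSON
manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cell as cell_mod
from . import chemistry as chem_mod
from . import geometry as geo_mod
from . import ib
from . import lattice as lb
from . import valves as valve_mod
from . import wall as wall_mod
from .config import RunConfig
from .errors import NumericalBlowupError

__version__ = "0.1.0"


@dataclass
class RunOutputs:
    trajectory: pd.DataFrame
    wall_series: pd.DataFrame
    events: pd.DataFrame
    exit_t: np.ndarray          # (n_out,)
    exit_profiles: np.ndarray   # (n_out, lumen_width) axial velocity, cm/s
    snapshots: list             # dicts with t, rho, u (cm/s), no
    manifest: dict
    mass_series: pd.DataFrame


class Simulation:
    """One configured run of the coupled model."""

    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self._setup()

    # ------------------------------------------------------------------
    def _setup(self) -> None:
        cfg = self.cfg
        if cfg.scenario == "poiseuille_channel":
            self._setup_channel()
            return
        self.geom, self.ns_map, self.node_type = geo_mod.build_domain(
            cfg.domain, cfg.resolution
        )
        g = self.geom
        self.channel = False
        self.tissue_ns = cfg.domain.tissue_ns
        # initial densities: tissue at far-field density, lumen at outlet datum
        rho = np.where(
            self.node_type == lb.POROUS, cfg.fluid.rho_tissue, cfg.fluid.rho_out
        )
        self.f = lb.equilibrium(
            np.where(rho > 0, rho, 1.0), np.zeros((2, g.ny, g.nx))
        )
        self.wall = wall_mod.WallState(
            y_top=g.y_top_rest.copy(), y_bot=g.y_bot_rest.copy()
        )
        self.jt = np.rint(self.wall.y_top).astype(int)
        self.jb = np.rint(self.wall.y_bot).astype(int)
        self.chem = chem_mod.initialize_chem(cfg.chem, g, cfg.gravity_level, self.rng)
        self.D_rest = (g.y_top_rest - g.y_bot_rest - 1.0).copy()

        self.leaflets: list[valve_mod.ValveLeaflet] = []
        self.valve_of_leaflet: list[int] = []
        for k in range(len(g.valve_x)):
            top, bot = valve_mod.make_valve_pair(
                g, k,
                n_nodes=cfg.valve.n_nodes,
                k_stretch=cfg.valve.k_stretch,
                k_bend=cfg.valve.k_bend,
                c_damp=cfg.valve.c_damp,
                rest_angle_deg=cfg.valve.rest_angle_deg,
                tip_gap_fraction=cfg.valve.tip_gap_fraction,
                k_rest=cfg.valve.k_rest,
            )
            self.leaflets += [top, bot]
            self.valve_of_leaflet += [k, k]

        self.cell = None
        if cfg.cell_enabled:
            self.cell = cell_mod.initialize_cell(
                g,
                radius_cm=cfg.cell.radius_cm,
                offset_cm=cfg.cell.offset_cm,
                k_s=cfg.cell.k_s, k_b=cfg.cell.k_b,
                k_a=cfg.cell.k_a, k_area=cfg.cell.k_area,
                produces_NO=cfg.cell.produces_NO,
                NO_rate_coeff=cfg.cell.NO_rate_coeff,
            )

        self.eq_mask = self.node_type == lb.EQ_BOUNDARY
        out_nodes = np.nonzero(self.node_type[:, g.nx - 1] == lb.OUTLET)[0]
        self.outlet_ys = out_nodes
        self.x_exit = g.nx - 2

        self.t_step = 0
        self.mass_created = 0.0
        self.perturb_steps = (
            int(cfg.chem.perturb_window / cfg.dt)
            if self.chem.f_ca_multiplier != 1.0
            else 0
        )
        self._out_every = max(1, int(round(cfg.output_interval_s / cfg.dt)))
        self._snap_every = max(1, int(round(cfg.snapshot_interval_s / cfg.dt)))
        self._traj_rows: list = []
        self._wall_rows: list = []
        self._exit_rows: list = []
        self._exit_t: list = []
        self._mass_rows: list = []
        self.snapshots: list = []
        self._valve_state = np.ones(len(g.valve_x), dtype=bool)  # open
        self._valve_events: list = []
        self._prev_cell_center = self.cell.center.copy() if self.cell else None
        self.force = np.zeros((2, g.ny, g.nx))
        self.rho = rho.astype(float)
        self.u = np.zeros((2, g.ny, g.nx))

    def _setup_channel(self) -> None:
        cfg = self.cfg
        ny = cfg.resolution + 2
        nx = 8
        node = np.zeros((ny, nx), np.int8)
        node[0, :] = lb.SOLID
        node[-1, :] = lb.SOLID
        self.node_type = node
        self.ns_map = np.zeros((ny, nx))
        self.geom = None
        self.channel = True
        self.f = lb.equilibrium(np.ones((ny, nx)), np.zeros((2, ny, nx)))
        self.cell = None
        self.chem = None
        self.leaflets = []
        self.t_step = 0
        self.mass_created = 0.0
        self._traj_rows = []
        self._wall_rows = []
        self._exit_rows = []
        self._exit_t = []
        self._mass_rows = []
        self.snapshots = []
        self._out_every = max(1, int(round(cfg.output_interval_s / cfg.dt)))
        self.force = np.zeros((2, ny, nx))
        self.rho = np.ones((ny, nx))
        self.u = np.zeros((2, ny, nx))

    # ------------------------------------------------------------------
    @property
    def fluid_like(self) -> np.ndarray:
        if getattr(self, "_fluid_cache", None) is None:
            self._fluid_cache = np.isin(self.node_type, lb.FLUID_LIKE)
        return self._fluid_cache

    @property
    def solid_mask(self) -> np.ndarray:
        if getattr(self, "_solid_cache", None) is None:
            self._solid_cache = self.node_type == lb.SOLID
            self._recv_masks = lb.solid_receive_masks(self._solid_cache)
        return self._solid_cache

    def _invalidate_masks(self) -> None:
        self._fluid_cache = None
        self._solid_cache = None

    def _guard(self, u: np.ndarray, mask: np.ndarray) -> None:
        umax = np.abs(u[:, mask]).max() if mask.any() else 0.0
        if umax > self.cfg.fluid.max_u:
            raise NumericalBlowupError(
                f"max |u| = {umax:.3f} exceeded guardrail "
                f"{self.cfg.fluid.max_u} at step {self.t_step}"
            )

    # ------------------------------------------------------------------
    def step(self) -> None:
        if self.channel:
            self._step_channel()
            return
        cfg, g = self.cfg, self.geom
        fl = self.fluid_like
        rho, u_star = lb.macroscopic(self.f, fluid_mask=fl)
        rho = np.where(fl, rho, cfg.fluid.rho0)
        self._guard(u_star, fl)

        # ---- chemistry
        taus = self._chemistry_step(rho, u_star)

        # ---- wall mechanics and remapping
        self._wall_step(rho, taus)

        # ---- assemble force field: gravity + immersed-structure forces,
        # then advance the structures (drag-coupled overdamped update)
        force = self.force
        force[:] = 0.0
        gmask = fl.copy()
        gmask[:, -1] = False  # no forcing on boundary columns
        ramp = cfg.fluid.gravity_ramp_s
        gfac = min(1.0, self.t_step * cfg.dt / ramp) if ramp > 0 else 1.0
        force[0][gmask] = rho[gmask] * cfg.g_lattice_x * gfac
        self._structures_step(force, u_star, rho)

        # ---- LBM update
        safe_rho = np.where(rho > 0, rho, 1.0)
        u = u_star + 0.5 * force / safe_rho
        f_post = lb.collide_and_force(self.f, rho, u, cfg.fluid.tau, force)
        porous = (self.node_type == lb.POROUS)
        ns = np.where(porous, self.ns_map, 0.0)
        if self.leaflets and cfg.valve.ns_seal > 0:
            # leaflet fibres act as a partial bounce-back curtain: aligned
            # with the flow when open, spanning the lumen when closed, which
            # lets a sealed valve hold a retrograde pressure difference
            np.maximum(ns, self._leaflet_curtain(), out=ns)
        if np.any(ns > 0):
            f_post = lb.partial_bounce_back(f_post, ns)
        f_post = geo_mod.apply_gap_rule(f_post, rho, g, self.node_type)
        f_new = lb.stream(f_post)
        solid = self.solid_mask
        f_new, _ = lb.bounce_back_solids(
            f_new, f_post, solid, self.u_wall_field(), cfg.fluid.rho0,
            recv_masks=self._recv_masks,
        )
        f_new = lb.pressure_outlet(
            f_new, self.outlet_ys, g.nx - 1, cfg.fluid.rho_out
        )
        f_new = lb.tissue_boundary(f_new, self.eq_mask, cfg.fluid.rho_tissue)
        self.f = f_new
        self.rho, self.u = rho, u
        self.t_step += 1
        if self.perturb_steps and self.t_step >= self.perturb_steps:
            self.chem.f_ca_multiplier = 1.0
            self.perturb_steps = 0

        if self.t_step % self._out_every == 0:
            self._record()
        if self.t_step % self._snap_every == 0:
            self._snapshot()

    def _step_channel(self) -> None:
        cfg = self.cfg
        fl = self.fluid_like
        force = self.force
        force[:] = 0.0
        rho, u_star = lb.macroscopic(self.f, force=None, fluid_mask=fl)
        force[0][fl] = rho[fl] * (
            cfg.fluid.body_force_x if cfg.fluid.body_force_x else cfg.g_lattice_x
        )
        safe = np.where(rho > 0, rho, 1.0)
        u = u_star + 0.5 * force / safe
        self._guard(u, fl)
        f_post = lb.collide_and_force(self.f, rho, u, cfg.fluid.tau, force)
        f_new = lb.stream(f_post)
        solid = self.node_type == lb.SOLID
        f_new, _ = lb.bounce_back_solids(f_new, f_post, solid)
        self.f = f_new
        self.rho, self.u = rho, u
        self.t_step += 1
        if self.t_step % self._out_every == 0:
            self._mass_rows.append(
                (self.t_step * cfg.dt, float(self.f[:, fl].sum()))
            )

    # ------------------------------------------------------------------
    def _leaflet_curtain(self) -> np.ndarray:
        g = self.geom
        ov = np.zeros((g.ny, g.nx))
        ns_seal = self.cfg.valve.ns_seal
        rest_gap = self.cfg.valve.tip_gap_fraction * (
            self.geom.y_top_rest[0] - self.geom.y_bot_rest[0] - 1.0
        )
        for idx, lf in enumerate(self.leaflets):
            # curtain strength follows valve closedness: an open leaflet is
            # aligned with the flow and sheds little resistance, a closed
            # valve spans the lumen and behaves like a porous wall
            mate = self.leaflets[idx ^ 1]
            gap = abs(lf.tip[1] - mate.tip[1])
            # the curtain grows only once the leaflets swing inside their
            # bias-open rest gap (i.e. the valve is actually closing); at or
            # beyond the rest gap the fibre is transparent so forward flow
            # and its shear-driven NO are not throttled
            openness = np.clip(
                (gap - 1.0) / max(rest_gap - 1.0, 0.5), 0.0, 1.0
            )
            val = ns_seal * (1.0 - openness)
            if val < 0.05:
                continue
            # dense supercover rasterisation of the fibre polyline; marking
            # floor and ceil rows keeps the curtain 4-connected so no
            # populations slip diagonally between fibre cells
            seg = np.diff(lf.nodes, axis=0)
            ln = np.hypot(seg[:, 0], seg[:, 1])
            npts = np.maximum(2, np.ceil(ln / 0.3).astype(int))
            for i, n in enumerate(npts):
                ts = np.linspace(0.0, 1.0, n)
                px = lf.nodes[i, 0] + ts * seg[i, 0]
                py = lf.nodes[i, 1] + ts * seg[i, 1]
                ii = np.clip(np.rint(px).astype(int), 0, g.nx - 1)
                i2 = np.clip(ii + 1, 0, g.nx - 1)
                jlo = np.clip(np.floor(py).astype(int), 0, g.ny - 1)
                jhi = np.clip(np.ceil(py).astype(int), 0, g.ny - 1)
                # two cells thick in both directions: a near-vertical closed
                # leaflet otherwise leaves a one-cell-thin porous sheet that
                # seeps under a sustained retrograde head
                np.maximum.at(ov, (jlo, ii), val)
                np.maximum.at(ov, (jhi, ii), val)
                np.maximum.at(ov, (jlo, i2), val)
                np.maximum.at(ov, (jhi, i2), val)
        # only on ordinary fluid nodes
        ov[self.node_type != lb.FLUID] = 0.0
        return ov

    def u_wall_field(self) -> np.ndarray:
        g = self.geom
        uw = np.zeros((2, g.ny, g.nx))
        cols = g.cols
        uw[1, self.jt, cols] = self.wall.v_top
        uw[1, self.jb, cols] = self.wall.v_bot
        return uw

    def _structures_step(self, force: np.ndarray, u_star: np.ndarray,
                         rho: np.ndarray) -> None:
        """Immersed-boundary coupling for leaflets and cell.

        Forces are computed from the current configurations and spread onto
        the force field used by this step's collision.  Leaflet nodes then
        advance with the interpolated fluid velocity plus a small direct
        mobility on their elastic+contact load (drag-coupled overdamped
        chain), which keeps stiff leaflets stable under explicit coupling;
        the cell membrane is a classical no-slip immersed boundary.
        """
        cfg, g = self.cfg, self.geom
        vcfg = cfg.valve
        from . import elastic

        cache = getattr(self, "_lf_cache", None)
        if cache is None and self.leaflets:
            m = self.leaflets[0].m
            L = len(self.leaflets)
            offs = np.arange(L) * m
            seg = (np.arange(m - 1)[None, :] + offs[:, None]).ravel()
            tri = (np.arange(m - 2)[None, :] + offs[:, None]).ravel()
            cache = self._lf_cache = {
                "L": L, "m": m, "offs": offs,
                "si": seg, "sj": seg + 1,
                "l0": np.concatenate([lf.l0 for lf in self.leaflets]),
                "ba": tri, "bb": tri + 1, "bc": tri + 2,
                "th0": np.concatenate([lf.theta0 for lf in self.leaflets]),
                "th0b": np.array([lf.theta0_base for lf in self.leaflets]),
                "l0f": np.array([lf.l0[0] for lf in self.leaflets]),
                "sides": np.array([lf.side for lf in self.leaflets]),
                "acols": np.array([lf.anchor_col for lf in self.leaflets]),
                "axs": np.array([lf.anchor_x for lf in self.leaflets]),
                "rest_local": np.stack(
                    [lf.rest_local for lf in self.leaflets]),
                "x_lo": np.array([lf.anchor_x - 1.5 for lf in self.leaflets]),
                "x_hi": np.array(
                    [lf.anchor_x + 1.5 * lf.rest_local[-1, 0] + 2.0
                     for lf in self.leaflets]),
            }
        leaflet_F = None
        if self.leaflets:
            L, m, offs = cache["L"], cache["m"], cache["offs"]
            P = np.concatenate([lf.nodes for lf in self.leaflets])
            Pprev = np.concatenate([lf.prev_nodes for lf in self.leaflets])
            F = np.zeros_like(P)
            elastic.stretch(P, cache["si"], cache["sj"], vcfg.k_stretch,
                            cache["l0"], F)
            if m > 2:
                elastic.bend(P, cache["ba"], cache["bb"], cache["bc"],
                             vcfg.k_bend, cache["th0"], F)
            ghost = P[offs] - np.stack(
                [cache["l0f"], np.zeros(L)], axis=1)
            elastic.bend(P, offs, offs, offs + 1, vcfg.k_bend,
                         cache["th0b"], F, ghost_a=ghost)
            # weak distributed spring to the anchor-following rest shape
            if vcfg.k_rest > 0:
                P3 = P.reshape(L, m, 2)
                target = P3[:, :1, :] + cache["rest_local"]
                F += (vcfg.k_rest * (target - P3)).reshape(-1, 2)
            F[offs] = 0.0  # anchors are pinned; reaction goes to the wall
            F -= vcfg.c_damp * (P - Pprev)
            # leaflet-leaflet contact per valve, batched over valves
            PL = P.reshape(L, m, 2)
            FL3 = F.reshape(L, m, 2)
            d = PL[0::2, :, None, :] - PL[1::2, None, :, :]
            dist = np.hypot(d[..., 0], d[..., 1])
            mask = dist < vcfg.contact_range
            if np.any(mask):
                dist_s = np.where(dist > 1e-12, dist, 1e-12)
                mag = np.where(mask, vcfg.contact_k * (vcfg.contact_range - dist), 0.0)
                fx = mag * d[..., 0] / dist_s
                fy = mag * d[..., 1] / dist_s
                FL3[0::2, :, 0] += fx.sum(axis=2)
                FL3[0::2, :, 1] += fy.sum(axis=2)
                FL3[1::2, :, 0] -= fx.sum(axis=1)
                FL3[1::2, :, 1] -= fy.sum(axis=1)
            leaflet_F = F
        cell_F = None
        self._epc = 0.0
        if self.cell is not None:
            cell_F, self._epc = cell_mod.membrane_forces(self.cell)
            if self.leaflets:
                xc = self.cell.center[0]
                near = np.nonzero(
                    np.abs(cache["axs"] - xc) <= 3 * self.cell.radius0 + 6
                )[0]
                for k in near:
                    FC, FLk = ib.contact_forces(
                        self.cell.nodes, PL[k],
                        vcfg.contact_range, vcfg.contact_k,
                    )
                    cell_F += FC
                    FL3[k] += FLk
        # --- spread to the lattice
        if self.leaflets:
            ib.spread(P, leaflet_F, force)
        if self.cell is not None:
            ib.spread(self.cell.nodes, cell_F, force)
        # --- advance structures
        mob = vcfg.mobility
        if self.leaflets:
            # transvalvular pressure load: the coarse immersed fibre carries
            # little of the form drag, so the axial pressure difference
            # sampled across each valve is applied to the leaflet update
            # directly (negative dP folds the leaflets shut, positive dP
            # sweeps them open toward the wall)
            dP_F = np.zeros_like(leaflet_F)
            rho_now = rho
            for k in range(len(g.valve_x)):
                xv = int(g.valve_x[k])
                cu = max(xv - 3, g.x0 + 1)
                cd = min(xv + 3, g.nx - 2)
                ju = slice(self.jb[cu - g.x0] + 1, self.jt[cu - g.x0])
                jd = slice(self.jb[cd - g.x0] + 1, self.jt[cd - g.x0])
                dp = lb.CS2 * (
                    rho_now[ju, cu].mean() - rho_now[jd, cd].mean()
                )
                dP_F[2 * k * m:(2 * k + 2) * m, 0] = vcfg.dp_gain * dp
            dP_F[offs] = 0.0
            vel = ib.interpolate(u_star, P)
            Pn = P + vel + mob * (leaflet_F + dP_F)
            Pn3 = Pn.reshape(L, m, 2)
            # pin anchors to the (moving) wall
            y_top_a = self.wall.y_top[cache["acols"]]
            y_bot_a = self.wall.y_bot[cache["acols"]]
            y_anchor = np.where(cache["sides"] > 0, y_top_a - 0.5, y_bot_a + 0.5)
            Pn3[:, 0, 0] = cache["axs"]
            Pn3[:, 0, 1] = y_anchor
            # keep nodes inside the lumen (wall contact)
            xs = Pn3[:, :, 0].ravel() - g.x0
            grid = np.arange(g.n_cols)
            ytop = np.interp(xs, grid, self.wall.y_top).reshape(L, m)
            ybot = np.interp(xs, grid, self.wall.y_bot).reshape(L, m)
            # wall clearance: the distal half of each leaflet stays out of
            # the near-wall boundary layer (the sinus pocket), so a
            # reopening jet or backjet can always grab it
            m_half = m // 2
            margin = np.full(m, 0.6)
            margin[m_half:] = 1.4
            Pn3[:, 1:, 1] = np.clip(
                Pn3[:, 1:, 1],
                ybot[:, 1:] + margin[None, 1:],
                ytop[:, 1:] - margin[None, 1:],
            )
            # commissure constraint: leaflets cannot prolapse upstream
            # through the annulus nor stretch far past their rest reach
            Pn3[:, 1:, 0] = np.clip(
                Pn3[:, 1:, 0],
                cache["x_lo"][:, None], cache["x_hi"][:, None],
            )
            # near-inextensible chain: keep consecutive nodes close to the
            # rest spacing so a backjet pivots the leaflet shut instead of
            # crumpling it into a ball with rasterisation holes
            dmin = 0.85 * float(cache["l0"][0])
            for i in range(1, m):
                dseg = Pn3[:, i] - Pn3[:, i - 1]
                dist = np.hypot(dseg[:, 0], dseg[:, 1])
                short = dist < dmin
                if np.any(short):
                    dd = np.where(dist[:, None] > 1e-9,
                                  dseg / np.maximum(dist, 1e-9)[:, None],
                                  np.array([1.0, 0.0]))
                    Pn3[short, i] = Pn3[short, i - 1] + dmin * dd[short]
            for k, lf in enumerate(self.leaflets):
                lf.prev_nodes = lf.nodes
                lf.nodes = Pn3[k].copy()
        if self.cell is not None:
            vel = ib.interpolate(u_star, self.cell.nodes)
            # drag-coupled overdamped membrane: at this resolution (cell
            # diameter ~ kernel width) opposite-side kernels overlap and a
            # purely advected membrane cannot resist spurious through-flow,
            # so the elastic load also acts on the nodes directly
            self.cell.nodes = self.cell.nodes + vel + cfg.cell.mobility * cell_F
            # keep the membrane clear of the blind cap and the outlet column
            self.cell.nodes[:, 0] = np.clip(
                self.cell.nodes[:, 0], g.x0 + 1.6, g.nx - 2.6
            )
            xs = self.cell.nodes[:, 0] - g.x0
            ytop = np.interp(xs, np.arange(g.n_cols), self.wall.y_top)
            ybot = np.interp(xs, np.arange(g.n_cols), self.wall.y_bot)
            self.cell.nodes[:, 1] = np.clip(
                self.cell.nodes[:, 1], ybot + 0.55, ytop - 0.55
            )
            _min_separation_ring(self.cell.nodes, 0.2)

    def _chemistry_step(self, rho: np.ndarray, u: np.ndarray):
        cfg, g = self.cfg, self.geom
        chem, par = self.chem, cfg.chem
        cols = g.cols
        tau_top = chem_mod.wall_shear_stress(u, self.jt, cols, -1, cfg.mu_lattice)
        tau_bot = chem_mod.wall_shear_stress(u, self.jb, cols, +1, cfg.mu_lattice)

        # NO production at wall-adjacent fluid nodes, proportional to |shear|
        source = np.zeros_like(chem.no_field)
        s_top = par.k_no_prod * np.abs(tau_top) * cfg.stress_scale
        s_bot = par.k_no_prod * np.abs(tau_bot) * cfg.stress_scale
        source[self.jt - 1, cols] += s_top
        source[self.jb + 1, cols] += s_bot
        # valve leaflets are endothelial surfaces too
        mu = cfg.mu_lattice
        dudy = np.gradient(u[0], axis=0)
        dvdx = np.gradient(u[1], axis=1)
        shear_field = mu * np.abs(dudy + dvdx) * cfg.stress_scale
        for lf in self.leaflets:
            jj = np.clip(np.rint(lf.nodes[:, 1]).astype(int), 0, g.ny - 1)
            ii = np.clip(np.rint(lf.nodes[:, 0]).astype(int), 0, g.nx - 1)
            source[jj, ii] += par.k_no_prod * shear_field[jj, ii] / lf.m

        self._cell_shear = 0.0
        if self.cell is not None and self.cell.produces_NO:
            self._cell_shear = cell_mod.cell_surface_shear(u, self.cell)
            rate = (
                self.cell.NO_rate_coeff
                * mu * self._cell_shear * cfg.stress_scale
            )
            jj = np.clip(np.rint(self.cell.nodes[:, 1]).astype(int), 0, g.ny - 1)
            ii = np.clip(np.rint(self.cell.nodes[:, 0]).astype(int), 0, g.nx - 1)
            source[jj, ii] += rate / self.cell.n

        chem.no_field = chem_mod.update_NO(
            chem.no_field, u, source, self.fluid_like, par, cfg.dt, cfg.dx
        )

        no_wall = 0.5 * (
            chem.no_field[self.jt - 1, cols] + chem.no_field[self.jb + 1, cols]
        )
        D = self.wall.diameter(g)
        stretch = np.maximum(0.0, (D - self.D_rest) / np.maximum(self.D_rest, 1.0))
        active = g.contracting_mask
        chem_mod.update_calcium(
            chem, par, stretch, no_wall, active, cfg.dt, cfg.dx
        )
        self._ca_force = chem_mod.trigger_and_force(
            chem, par, active, cfg.dt, self.t_step * cfg.dt
        )
        return tau_top, tau_bot

    def _wall_step(self, rho: np.ndarray, taus) -> None:
        cfg, g = self.cfg, self.geom
        cols = g.cols
        movable = g.flexible_mask
        rho_t = cfg.fluid.rho_tissue

        for which, j_row, sign in (("top", self.jt, +1), ("bot", self.jb, -1)):
            y = self.wall.y_top if which == "top" else self.wall.y_bot
            rest = g.y_top_rest if which == "top" else g.y_bot_rest
            p_in = lb.CS2 * rho[j_row - sign, cols]
            j_out = j_row + sign
            out_rho = rho[np.clip(j_out, 0, g.ny - 1), cols]
            porous_out = self.node_type[np.clip(j_out, 0, g.ny - 1), cols] == lb.POROUS
            p_out = lb.CS2 * np.where(porous_out, out_rho, rho_t)
            disp = sign * (y - rest)
            vel = sign * (self.wall.v_top if which == "top" else self.wall.v_bot)
            fn = wall_mod.wall_force(
                disp, np.zeros_like(disp), p_in, p_out,
                cfg.wall.k_tether, cfg.wall.c_damp, self._ca_force,
            )
            y_new, dy, _ = wall_mod.advance_wall(
                y, vel, fn, cfg.wall.c_damp, sign, movable
            )
            if which == "top":
                self.wall.y_top, self.wall.v_top = y_new, dy
            else:
                self.wall.y_bot, self.wall.v_bot = y_new, dy

        jt_new = np.rint(self.wall.y_top).astype(int)
        jb_new = np.rint(self.wall.y_bot).astype(int)
        moved = np.any(jt_new != self.jt) or np.any(jb_new != self.jb)
        if np.any(jt_new != self.jt):
            self.mass_created += wall_mod.remap_columns(
                self.f, self.node_type, self.ns_map, cols,
                self.jt, jt_new, -1, self.tissue_ns, rho_t,
                j_opposite=self.jb,
            )
        if np.any(jb_new != self.jb):
            self.mass_created += wall_mod.remap_columns(
                self.f, self.node_type, self.ns_map, cols,
                self.jb, jb_new, +1, self.tissue_ns, rho_t,
                j_opposite=jt_new,
            )
        self.jt, self.jb = jt_new, jb_new
        if moved:
            self._invalidate_masks()

    # ------------------------------------------------------------------
    def _record(self) -> None:
        cfg, g = self.cfg, self.geom
        t = self.t_step * cfg.dt
        u_cm = cfg.dx / cfg.dt
        # exit profile
        lum = slice(self.jb[-2] + 1, self.jt[-2])
        self._exit_rows.append(self.u[0][lum, self.x_exit] * u_cm)
        self._exit_t.append(t)
        # wall series per lymphangion
        D = self.wall.diameter(g) * cfg.dx
        row = {"t": t}
        for k in range(g.spec.n_lymphangions):
            m = g.lymphangion_index == k
            row[f"D_{k}"] = float(D[m].mean())
            row[f"ca_{k}"] = float(self.chem.ca[m].mean())
        row["n_triggers"] = self.chem.n_trigger_events
        self._wall_rows.append(row)
        # mass audit
        self._mass_rows.append((t, float(self.f[:, self.fluid_like].sum()),
                                self.mass_created))
        # valve open/close events from tip gaps
        for k in range(len(g.valve_x)):
            gap = abs(
                self.leaflets[2 * k].tip[1] - self.leaflets[2 * k + 1].tip[1]
            )
            is_open = gap > 1.5
            if is_open != self._valve_state[k]:
                self._valve_events.append(
                    {"t": t, "kind": "valve_open" if is_open else "valve_close",
                     "which": k}
                )
                self._valve_state[k] = is_open
        # cell trajectory
        if self.cell is not None:
            c = self.cell.center
            vel = (c - self._prev_cell_center) / (self._out_every) * u_cm
            self._prev_cell_center = c.copy()
            col = int(np.clip(round(c[0]) - g.x0, 0, g.n_cols - 1))
            in_valve = bool(np.any(np.abs(g.valve_x - c[0]) < g.spec.baseline_diameter / cfg.dx))
            self._traj_rows.append({
                "t": t,
                "x": (c[0] - g.x0) * cfg.dx,
                "y": (c[1] - g.yc) * cfg.dx,
                "vx": vel[0], "vy": vel[1],
                "Epc": self._epc,
                "ca_local": float(self.chem.ca[col]),
                "no_local": float(self.chem.no_field[
                    int(np.clip(round(c[1]), 0, g.ny - 1)),
                    int(np.clip(round(c[0]), 0, g.nx - 1))]),
                "in_valve": in_valve,
                "retrograde": vel[0] < 0,
            })

    def _snapshot(self) -> None:
        cfg = self.cfg
        u_cm = cfg.dx / cfg.dt
        self.snapshots.append({
            "t": self.t_step * cfg.dt,
            "rho": self.rho.copy(),
            "u": self.u * u_cm,
            "no": self.chem.no_field.copy() if self.chem else None,
            "node_type": self.node_type.copy(),
        })

    # ------------------------------------------------------------------
    def run(self, outdir: str | Path | None = None) -> RunOutputs:
        cfg = self.cfg
        n = cfg.n_steps
        while self.t_step < n:
            self.step()
        out = self._collect()
        if outdir is not None:
            self._write(out, Path(outdir))
        return out

    def _collect(self) -> RunOutputs:
        cfg = self.cfg
        events = list(self._valve_events) if not self.channel else []
        if self.chem is not None:
            g = self.geom
            for t, c in self.chem.trigger_log:
                events.append({
                    "t": t, "kind": "trigger", "which":
                        int(self.geom.lymphangion_index[c]),
                    "col": c,
                })
        manifest = {
            "config": _jsonable(cfg.to_dict()),
            "version": __version__,
            "dx_cm": cfg.dx,
            "dt_s": cfg.dt,
            "n_steps": self.t_step,
            "mass_created": self.mass_created,
            "n_trigger_events": (
                self.chem.n_trigger_events if self.chem else 0
            ),
        }
        return RunOutputs(
            trajectory=pd.DataFrame(self._traj_rows),
            wall_series=pd.DataFrame(self._wall_rows),
            events=pd.DataFrame(events),
            exit_t=np.array(self._exit_t),
            exit_profiles=(
                np.array(self._exit_rows) if self._exit_rows else np.zeros((0, 0))
            ),
            snapshots=self.snapshots,
            manifest=manifest,
            mass_series=pd.DataFrame(
                self._mass_rows, columns=["t", "mass", "mass_created"][
                    : (3 if not self.channel else 2)]
            ),
        )

    def _write(self, out: RunOutputs, outdir: Path) -> None:
        outdir.mkdir(parents=True, exist_ok=True)
        out.trajectory.to_csv(outdir / "trajectory.csv", index=False)
        out.wall_series.to_csv(outdir / "wall.csv", index=False)
        out.events.to_csv(outdir / "events.csv", index=False)
        out.mass_series.to_csv(outdir / "mass.csv", index=False)
        np.savez_compressed(
            outdir / "exit_profiles.npz", t=out.exit_t, ux=out.exit_profiles
        )
        for i, s in enumerate(out.snapshots):
            np.savez_compressed(
                outdir / f"snapshot_{i:04d}.npz",
                t=s["t"], rho=s["rho"], u=s["u"],
                no=(s["no"] if s["no"] is not None else np.zeros(1)),
                node_type=s["node_type"],
            )
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(out.manifest, fh, indent=2, default=str)

    # ------------------------------------------------------------------
    def state_dict(self) -> dict:
        d = {
            "f": self.f.copy(),
            "node_type": self.node_type.copy(),
            "ns_map": self.ns_map.copy(),
            "t_step": self.t_step,
            "mass_created": self.mass_created,
        }
        if not self.channel:
            d.update(
                y_top=self.wall.y_top.copy(), y_bot=self.wall.y_bot.copy(),
                v_top=self.wall.v_top.copy(), v_bot=self.wall.v_bot.copy(),
                ca=self.chem.ca.copy(), no=self.chem.no_field.copy(),
                trigger=self.chem.trigger.copy(),
                recharge=self.chem.recharge_clock.copy(),
                leaflet_nodes=np.concatenate([lf.nodes for lf in self.leaflets]),
                leaflet_prev=np.concatenate(
                    [lf.prev_nodes for lf in self.leaflets]
                ),
                f_ca_multiplier=self.chem.f_ca_multiplier,
                perturb_steps=self.perturb_steps,
                n_trigger_events=self.chem.n_trigger_events,
            )
            if self.cell is not None:
                d["cell_nodes"] = self.cell.nodes.copy()
        return d

    def load_state_dict(self, d: dict) -> None:
        self.f = d["f"].copy()
        self.node_type = d["node_type"].copy()
        self._invalidate_masks()
        self.ns_map = d["ns_map"].copy()
        self.t_step = int(d["t_step"])
        self.mass_created = float(d.get("mass_created", 0.0))
        if not self.channel:
            self.wall.y_top = d["y_top"].copy()
            self.wall.y_bot = d["y_bot"].copy()
            self.wall.v_top = d["v_top"].copy()
            self.wall.v_bot = d["v_bot"].copy()
            self.jt = np.rint(self.wall.y_top).astype(int)
            self.jb = np.rint(self.wall.y_bot).astype(int)
            self.chem.ca = d["ca"].copy()
            self.chem.no_field = d["no"].copy()
            self.chem.trigger = d["trigger"].copy()
            self.chem.recharge_clock = d["recharge"].copy()
            self.chem.f_ca_multiplier = float(d.get("f_ca_multiplier", 1.0))
            self.perturb_steps = int(d.get("perturb_steps", 0))
            self.chem.n_trigger_events = int(d.get("n_trigger_events", 0))
            i = 0
            prev = d.get("leaflet_prev")
            for lf in self.leaflets:
                lf.nodes = d["leaflet_nodes"][i : i + lf.m].copy()
                lf.prev_nodes = (
                    prev[i : i + lf.m].copy() if prev is not None
                    else lf.nodes.copy()
                )
                i += lf.m
            if self.cell is not None and "cell_nodes" in d:
                self.cell.nodes = d["cell_nodes"].copy()
            self._prev_cell_center = (
                self.cell.center.copy() if self.cell else None
            )


def _min_separation(P: np.ndarray, dmin: float) -> None:
    """Keep consecutive chain nodes at least ``dmin`` apart (in place).

    Prevents degenerate zero-length segments when soft chains are pressed
    flat against a wall; the correction is along the previous segment
    direction and leaves well-separated nodes untouched.
    """
    for i in range(1, len(P)):
        d = P[i] - P[i - 1]
        dist = float(np.hypot(d[0], d[1]))
        if dist < dmin:
            if dist < 1e-9:
                direction = np.array([1.0, 0.0])
            else:
                direction = d / dist
            P[i] = P[i - 1] + direction * dmin


def _min_separation_ring(P: np.ndarray, dmin: float) -> None:
    """Symmetric minimal-separation regularisation for a closed polygon."""
    n = len(P)
    for i in range(n):
        j = (i + 1) % n
        d = P[j] - P[i]
        dist = float(np.hypot(d[0], d[1]))
        if dist < dmin:
            if dist < 1e-9:
                direction = np.array([1.0, 0.0])
            else:
                direction = d / dist
            push = 0.5 * (dmin - dist) * direction
            P[i] -= push
            P[j] += push


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def run_config(cfg: RunConfig, outdir: str | Path | None = None) -> RunOutputs:
    """Convenience: build a Simulation from ``cfg`` and run it."""
    return Simulation(cfg).run(outdir)
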