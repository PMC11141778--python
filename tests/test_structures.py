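"""Elastic structures: cell membrane, valve leaflets, IB kernel, contact."""

import numpy as np
import pytest

from lymphflow import cell as cell_mod
from lymphflow import ib
from lymphflow import valves as valve_mod
from lymphflow.cell import CellMembrane, compute_Epc, initialize_cell, membrane_forces
from lymphflow.errors import ConfigurationError
from lymphflow.geometry import DomainSpec, build_domain


def make_cell(r=3.0, jitter=0.0, seed=0):
    th = np.linspace(0, 2 * np.pi, 20, endpoint=False)
    nodes = np.stack([10 + r * np.cos(th), 10 + r * np.sin(th)], axis=1)
    if jitter:
        nodes += np.random.default_rng(seed).normal(0, jitter, nodes.shape)
    return CellMembrane(nodes=nodes, radius0=r, k_s=0.05, k_b=0.01,
                        k_a=0.02, k_area=0.05)


def numeric_gradient(cell, h=1e-7):
    G = np.zeros_like(cell.nodes)
    for i in range(cell.n):
        for d in range(2):
            orig = cell.nodes[i, d]
            cell.nodes[i, d] = orig + h
            ep = compute_Epc(cell)
            cell.nodes[i, d] = orig - h
            em = compute_Epc(cell)
            cell.nodes[i, d] = orig
            G[i, d] = (ep - em) / (2 * h)
    return G


class TestMembrane:
    def test_rest_circle_zero_energy_zero_force(self):
        cell = make_cell()
        F, E = membrane_forces(cell)
        assert E == pytest.approx(0.0, abs=1e-24)
        assert np.abs(F).max() < 1e-12

    def test_epc_zero_iff_rest(self):
        cell = make_cell(jitter=0.05)
        assert compute_Epc(cell) > 0

    def test_single_segment_stretch_energy(self):
        cell = make_cell()
        # stretch one segment by moving a node radially outward changes
        # multiple springs; instead check the pure-stretch formula on an
        # isolated two-node chain via the leaflet machinery
        from lymphflow import elastic
        P = np.array([[0.0, 0.0], [1.1, 0.0]])
        F = np.zeros_like(P)
        E = elastic.stretch(P, np.array([0]), np.array([1]), 2.0,
                            np.array([1.0]), F)
        assert E == pytest.approx(0.5 * 2.0 * 0.1**2)
        assert F[0, 0] == pytest.approx(2.0 * 0.1)
        assert F[1, 0] == pytest.approx(-2.0 * 0.1)

    def test_force_is_negative_energy_gradient(self):
        cell = make_cell(jitter=0.08, seed=3)
        F, _ = membrane_forces(cell)
        G = numeric_gradient(cell)
        rel = np.abs(F + G).max() / np.abs(F).max()
        assert rel < 1e-6

    def test_uniform_inflation_radial_symmetric_forces(self):
        cell = make_cell()
        cell.nodes = 10 + (cell.nodes - 10) * 1.2
        F, E = membrane_forces(cell)
        assert E > 0
        mags = np.hypot(F[:, 0], F[:, 1])
        assert mags.std() / mags.mean() < 1e-10
        # forces point inward (restoring)
        c = cell.center
        for i in range(cell.n):
            r_hat = (cell.nodes[i] - c) / np.linalg.norm(cell.nodes[i] - c)
            assert F[i] @ r_hat < 0

    def test_net_force_and_torque_vanish(self):
        cell = make_cell(jitter=0.1, seed=5)
        F, _ = membrane_forces(cell)
        assert np.abs(F.sum(0)).max() < 1e-12
        tq = np.sum(cell.nodes[:, 0] * F[:, 1] - cell.nodes[:, 1] * F[:, 0])
        assert abs(tq) < 1e-12


class TestInitializeCell:
    @pytest.fixture(scope="class")
    def geom(self):
        return build_domain(DomainSpec(), 10)[0]

    def test_default_offset(self, geom):
        cell = initialize_cell(geom, radius_cm=0.004)
        offset_cm = (cell.center[1] - geom.yc) * geom.dx
        assert offset_cm == pytest.approx(0.0008, rel=1e-9)
        assert cell.n == 20

    def test_zero_offset_on_centerline(self, geom):
        cell = initialize_cell(geom, radius_cm=0.004, offset_cm=0.0)
        assert cell.center[1] == pytest.approx(geom.yc)

    def test_oversized_cell_rejected(self, geom):
        with pytest.raises(ConfigurationError):
            initialize_cell(geom, radius_cm=0.02)


class TestLeaflets:
    @pytest.fixture(scope="class")
    def pair(self):
        geom = build_domain(DomainSpec(), 10)[0]
        return valve_mod.make_valve_pair(geom, 3)

    def test_rest_shape_zero_force(self, pair):
        top, bot = pair
        for lf in (top, bot):
            F, E = valve_mod.leaflet_internal_forces(lf)
            assert E == pytest.approx(0.0, abs=1e-20)
            assert np.abs(F).max() < 1e-10

    def test_biased_open_tips_separated(self, pair):
        top, bot = pair
        gap = abs(top.tip[1] - bot.tip[1])
        lumen = 10.0
        assert 0.2 * lumen < gap < 0.6 * lumen

    def test_force_matches_energy_gradient(self, pair):
        top, _ = pair
        lf = valve_mod.ValveLeaflet(
            nodes=top.nodes + np.random.default_rng(7).normal(0, 0.1, top.nodes.shape),
            rest_local=top.rest_local, anchor_col=top.anchor_col,
            anchor_x=top.anchor_x, side=top.side,
            k_stretch=top.k_stretch, k_bend=top.k_bend, c_damp=top.c_damp,
        )
        # rebuild rest metadata from the unperturbed leaflet
        lf.l0, lf.theta0, lf.theta0_base = top.l0, top.theta0, top.theta0_base
        F, _ = valve_mod.leaflet_internal_forces(lf)

        def energy():
            return valve_mod.leaflet_internal_forces(lf)[1]

        h = 1e-7
        G = np.zeros_like(lf.nodes)
        for i in range(1, lf.m):  # node 0 is pinned; its force is zeroed
            for d in range(2):
                orig = lf.nodes[i, d]
                lf.nodes[i, d] = orig + h
                ep = energy()
                lf.nodes[i, d] = orig - h
                em = energy()
                lf.nodes[i, d] = orig
                G[i, d] = (ep - em) / (2 * h)
        rel = np.abs(F[1:] + G[1:]).max() / np.abs(F[1:]).max()
        assert rel < 1e-6

    def test_damped_relaxation_energy_nonincreasing(self, pair):
        # with the fluid frozen, a perturbed leaflet relaxing under its own
        # mobility dissipates elastic energy monotonically
        top, _ = pair
        lf = valve_mod.ValveLeaflet(
            nodes=top.nodes.copy(), rest_local=top.rest_local,
            anchor_col=top.anchor_col, anchor_x=top.anchor_x, side=top.side,
            k_stretch=top.k_stretch, k_bend=top.k_bend, c_damp=top.c_damp,
        )
        lf.nodes[-1] += np.array([0.5, -0.8])
        energies = []
        for _ in range(600):
            F, E = valve_mod.leaflet_internal_forces(lf)
            energies.append(E)
            lf.nodes[1:] += 0.2 * F[1:]
        assert energies[-1] < 1e-2 * energies[0]
        diffs = np.diff(energies)
        assert np.all(diffs <= 1e-12)


class TestKernelAndContact:
    def test_partition_of_unity(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(4, 10, (7, 2))
        const = np.full((16, 16), 3.7)
        vals = ib.interpolate(const, X)
        assert np.allclose(vals, 3.7, atol=1e-12)

    def test_spread_conserves_total_force(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(4, 10, (5, 2))
        F = rng.normal(0, 1, (5, 2))
        field = np.zeros((2, 16, 16))
        ib.spread(X, F, field)
        assert np.allclose(field.sum(axis=(1, 2)), F.sum(0), atol=1e-12)

    def test_spread_then_interpolate_constant_velocity(self):
        # a uniform velocity field interpolates exactly at any position
        X = np.array([[5.3, 7.8], [6.1, 6.2]])
        u = np.zeros((2, 16, 16))
        u[0] = 0.01
        v = ib.interpolate(u, X)
        assert np.allclose(v[:, 0], 0.01, atol=1e-14)
        assert np.allclose(v[:, 1], 0.0, atol=1e-14)

    def test_contact_zero_beyond_range(self):
        A = np.array([[0.0, 0.0]])
        B = np.array([[3.0, 0.0]])
        FA, FB = ib.contact_forces(A, B, d_c=1.0, k_c=1.0)
        assert np.all(FA == 0) and np.all(FB == 0)

    def test_contact_equal_opposite_along_join(self):
        A = np.array([[0.0, 0.0]])
        B = np.array([[0.5, 0.0]])
        FA, FB = ib.contact_forces(A, B, d_c=1.0, k_c=2.0)
        assert FA[0, 0] == pytest.approx(-1.0)  # pushed away from B
        assert np.allclose(FA, -FB)
        assert FA[0, 1] == 0.0


class TestStiffnessSweep:
    def test_epc_under_fixed_load_decreases_with_stiffness(self):
        # identical pinching force applied to cells of increasing stiffness:
        # softer cells deform more and store more energy
        peak = []
        for scale in (1.0, 2.0, 4.0):
            cell = make_cell()
            cell.k_s *= scale
            cell.k_b *= scale
            cell.k_a *= scale
            cell.k_area *= scale
            pinch = np.zeros_like(cell.nodes)
            pinch[:, 1] = -0.02 * np.sign(cell.nodes[:, 1] - 10)
            for _ in range(2000):
                F, _ = membrane_forces(cell)
                cell.nodes += 2.0 * (F + pinch)
            peak.append(compute_Epc(cell))
        assert peak[0] > peak[1] > peak[2]
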