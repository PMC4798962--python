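"""Hydraulic network solver: closed-form and hand-solved oracles."""

import numpy as np
import pytest

import vesselpol as vp
from vesselpol.graph import Edge, VesselGraph
from vesselpol.hemodynamics import pries_viscosity

from conftest import diamond_graph, straight_tube

MU = 3.5e-3


def uniform_conductance(r, length, mu=MU):
    return np.pi * r ** 4 / (8.0 * mu * length)


class TestSegmentConductance:
    def test_uniform_tube_closed_form(self):
        g = straight_tube(length_um=200.0, radius_um=4.0)
        got = vp.segment_conductance(g.edges[0], MU)
        assert got == pytest.approx(uniform_conductance(4.0, 200.0), rel=1e-12)

    def test_two_tubes_in_series_halve_conductance(self):
        one = straight_tube(length_um=100.0, radius_um=4.0)
        two = straight_tube(length_um=200.0, radius_um=4.0)
        assert vp.segment_conductance(two.edges[0], MU) == pytest.approx(
            0.5 * vp.segment_conductance(one.edges[0], MU), rel=1e-12)

    def test_stepped_tube_matches_hand_series_sum(self):
        # R1=5 over L1=80, R2=3 over L2=120, encoded with a duplicated
        # breakpoint carrying the radius jump
        pts = np.array([[0, 0], [80, 0], [80, 0], [200, 0]], dtype=float)
        radii = np.array([5.0, 5.0, 3.0, 3.0])
        g = VesselGraph()
        g.add_node(0, (0, 0))
        g.add_node(1, (200, 0))
        g.add_edge(Edge(0, 0, 1, pts, radii))
        r_hand = (8 * MU * 80 / (np.pi * 5.0 ** 4)
                  + 8 * MU * 120 / (np.pi * 3.0 ** 4))
        assert vp.segment_conductance(g.edges[0], MU) == pytest.approx(
            1.0 / r_hand, rel=1e-12)

    def test_zero_radius_rejected_with_edge_name(self):
        g = straight_tube()
        g.edges[0].radii_um[0] = -1.0
        with pytest.raises(ValueError, match="edge 0"):
            vp.segment_conductance(g.edges[0], MU)


class TestSolvePressures:
    def test_single_edge_flow(self):
        g = straight_tube(length_um=100.0, radius_um=4.0)
        bc = [vp.BoundaryCondition(0, "fixed_pressure", 100.0),
              vp.BoundaryCondition(1, "fixed_pressure", 0.0)]
        sol = vp.solve_flow(g, bc, viscosity_pa_s=MU)
        expect = 100.0 * uniform_conductance(4.0, 100.0)
        assert sol.edge_flow[0] == pytest.approx(expect, rel=1e-12)

    def test_symmetric_h_network_has_dead_crossbar(self):
        g = diamond_graph(radii=(4.0, 4.0, 4.0, 4.0, 3.0))
        bc = [vp.BoundaryCondition(0, "fixed_pressure", 100.0),
              vp.BoundaryCondition(3, "fixed_pressure", 0.0)]
        sol = vp.solve_flow(g, bc, viscosity_pa_s=MU)
        qmax = max(abs(q) for q in sol.edge_flow.values())
        assert abs(sol.edge_flow[4]) <= 1e-12 * qmax

    def test_diamond_matches_hand_solved_linear_system(self):
        radii = (4.0, 5.0, 6.0, 3.0, 4.5)
        g = diamond_graph(radii=radii)
        lens = [g.edges[i].length for i in range(5)]
        gs = [uniform_conductance(r, L) for r, L in zip(radii, lens)]
        p_in, p_out = 80.0, 0.0
        # Kirchhoff at A and B, written out by hand:
        #   (G1+G3+G5) PA - G5 PB = G1 Pin + G3 Pout
        #   -G5 PA + (G2+G4+G5) PB = G2 Pin + G4 Pout
        a = np.array([[gs[0] + gs[2] + gs[4], -gs[4]],
                      [-gs[4], gs[1] + gs[3] + gs[4]]])
        b = np.array([gs[0] * p_in + gs[2] * p_out,
                      gs[1] * p_in + gs[3] * p_out])
        pa, pb = np.linalg.solve(a, b)
        bc = [vp.BoundaryCondition(0, "fixed_pressure", p_in),
              vp.BoundaryCondition(3, "fixed_pressure", p_out)]
        cond = {i: gs[i] for i in range(5)}
        pressures = vp.solve_nodal_pressures(g, cond, bc)
        assert pressures[1] == pytest.approx(pa, rel=1e-10)
        assert pressures[2] == pytest.approx(pb, rel=1e-10)

    def test_component_without_pressure_node_errors(self):
        g = straight_tube()
        g.add_node(10, (500.0, 500.0))
        g.add_node(11, (600.0, 500.0))
        g.add_edge(Edge(5, 10, 11, np.array([[500.0, 500.0], [600.0, 500.0]]),
                        np.full(2, 3.0)))
        bc = [vp.BoundaryCondition(0, "fixed_pressure", 10.0),
              vp.BoundaryCondition(1, "fixed_pressure", 0.0)]
        with pytest.raises(ValueError, match="component"):
            vp.solve_flow(g, bc)


class TestWss:
    def test_wall_formula_unit_case(self):
        # mu=1, R=1, Q=pi/4 -> tau = 4*1*(pi/4)/(pi*1) = 1 Pa
        assert 4.0 * 1.0 * (np.pi / 4) / (np.pi * 1.0 ** 3) == pytest.approx(1.0)
        g = straight_tube(length_um=10.0, radius_um=1.0)
        gcond = uniform_conductance(1.0, 10.0, mu=1.0)
        dp = (np.pi / 4) / gcond
        bc = [vp.BoundaryCondition(0, "fixed_pressure", dp),
              vp.BoundaryCondition(1, "fixed_pressure", 0.0)]
        sol = vp.solve_flow(g, bc, viscosity_pa_s=1.0)
        assert sol.edge_wss[0] == pytest.approx(1.0, rel=1e-12)

    def test_zero_flow_zero_wss(self):
        g = straight_tube()
        sol = vp.segment_flows_and_wss(g, {0: 5.0, 1: 5.0}, MU)
        assert sol.edge_flow[0] == 0.0
        assert sol.edge_wss[0] == 0.0

    def test_wss_cubic_in_radius_at_fixed_flow(self):
        taus = {}
        for r in (2.0, 4.0):
            g = straight_tube(radius_um=r)
            sol = vp.segment_flows_and_wss(g, {0: 1.0, 1: 0.0}, MU)
            q = sol.edge_flow[0]
            taus[r] = sol.edge_wss[0] / abs(q)  # tau per unit flow
        assert taus[4.0] == pytest.approx(taus[2.0] / 8.0, rel=1e-12)

    def test_reversal_antisymmetry(self, small_scene):
        g = small_scene.graph
        fwd = small_scene.flow
        bcs = [vp.BoundaryCondition(n, k, p)
               for n, k, p in fwd.metadata["boundary"]]
        rev = [vp.BoundaryCondition(bcs[0].node_id, "fixed_pressure",
                                    bcs[1].pressure_pa),
               vp.BoundaryCondition(bcs[1].node_id, "fixed_pressure",
                                    bcs[0].pressure_pa)]
        back = vp.solve_flow(g, rev, viscosity_pa_s=fwd.viscosity_pa_s)
        q_tol = 1e-9 * max(abs(q) for q in fwd.edge_flow.values())
        tau_tol = 1e-9 * max(fwd.edge_wss.values())
        for eid in fwd.edge_flow:
            assert back.edge_flow[eid] == pytest.approx(-fwd.edge_flow[eid],
                                                        rel=1e-9, abs=q_tol)
            assert back.edge_wss[eid] == pytest.approx(fwd.edge_wss[eid],
                                                       rel=1e-9, abs=tau_tol)

    def test_flows_scale_linearly_with_pressure_drop(self):
        g = diamond_graph()
        sols = []
        for dp in (50.0, 150.0):
            bc = [vp.BoundaryCondition(0, "fixed_pressure", dp),
                  vp.BoundaryCondition(3, "fixed_pressure", 0.0)]
            sols.append(vp.solve_flow(g, bc, viscosity_pa_s=MU))
        for eid in sols[0].edge_flow:
            assert sols[1].edge_flow[eid] == pytest.approx(
                3.0 * sols[0].edge_flow[eid], rel=1e-10, abs=1e-15)
            assert sols[1].edge_wss[eid] == pytest.approx(
                3.0 * sols[0].edge_wss[eid], rel=1e-10, abs=1e-15)


class TestWssSampling:
    def test_on_centreline_tangent_oriented_with_flow(self):
        g = straight_tube(length_um=100.0, radius_um=5.0)
        bc = [vp.BoundaryCondition(0, "fixed_pressure", 0.0),
              vp.BoundaryCondition(1, "fixed_pressure", 50.0)]  # reversed
        sol = vp.solve_flow(g, bc, viscosity_pa_s=MU)
        tau, direction = vp.wss_vector_at_point(sol, g, (40.0, 1.0), 10.0)
        assert tau > 0
        np.testing.assert_allclose(direction, [-1.0, 0.0], atol=1e-12)

    def test_far_point_returns_none(self):
        g = straight_tube()
        sol = vp.segment_flows_and_wss(g, {0: 1.0, 1: 0.0}, MU)
        assert vp.wss_vector_at_point(sol, g, (0.0, 500.0), 20.0) is None

    def test_equidistant_tie_breaks_to_lower_edge_id(self):
        g = VesselGraph()
        g.add_node(0, (0.0, 0.0))
        g.add_node(1, (100.0, 0.0))
        g.add_node(2, (0.0, 10.0))
        g.add_node(3, (100.0, 10.0))
        for eid, (u, v) in enumerate([(0, 1), (2, 3)]):
            g.add_edge(Edge(eid, u, v, np.vstack([g.nodes[u], g.nodes[v]]),
                            np.full(2, 3.0)))
        bc = [vp.BoundaryCondition(0, "fixed_pressure", 10.0),
              vp.BoundaryCondition(1, "fixed_pressure", 0.0),
              vp.BoundaryCondition(2, "fixed_pressure", 10.0),
              vp.BoundaryCondition(3, "fixed_pressure", 0.0)]
        sol = vp.solve_flow(g, bc, viscosity_pa_s=MU)
        results = [vp.wss_vector_at_point(sol, g, (50.0, 5.0), 20.0)
                   for _ in range(3)]
        e0 = g.edges[0]
        tau_expect = 4 * MU * abs(sol.edge_flow[0]) / (np.pi * 3.0 ** 3)
        for tau, _ in results:
            assert tau == pytest.approx(tau_expect, rel=1e-12)


def test_conservation_on_synthetic_plexus(small_scene):
    res = vp.conservation_residual(small_scene.graph, small_scene.flow)
    assert res <= 1e-8


def test_pries_viscosity_fahraeus_lindqvist_shape():
    # apparent viscosity dips in capillary-scale tubes, rises toward bulk
    mu_7 = pries_viscosity(7.0)
    mu_50 = pries_viscosity(50.0)
    mu_300 = pries_viscosity(300.0)
    assert mu_7 < mu_50 < mu_300
    assert 1e-3 < mu_7 < mu_300 < 6e-3
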