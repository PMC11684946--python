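"""Poiseuille network: closed-form composition, conservation, construction."""

import math

import numpy as np
import pytest

from alveoflow import tubeflow as tf
from alveoflow.errors import SingularSystemError
from alveoflow.geometry import ConnectivityConfig
from alveoflow.sheetflow import BoundaryConditions, FluidModel


def two_node_net(d=6.3, L=5.9):
    nodes = np.array([[0.0, 0, 0], [L, 0, 0]])
    edges = np.array([[0, 1]])
    return tf.TubeNetwork(nodes=nodes, edges=edges,
                          diameters=np.array([d]), lengths=np.array([L]),
                          port_nodes={"port_0": {"kind": "arteriole",
                                                 "diameter": d, "nodes": [0]},
                                      "port_1": {"kind": "venule",
                                                 "diameter": d, "nodes": [1]}})


class TestConductance:
    def test_reference_value(self):
        g = tf.poiseuille_conductance(6.3, 5.9, 0.002)
        assert g == pytest.approx(3.2766e-15, rel=1e-4)

    def test_scaling_in_length_and_diameter(self):
        g = tf.poiseuille_conductance(6.3, 5.9, 0.002)
        assert tf.poiseuille_conductance(6.3, 11.8, 0.002) == pytest.approx(g / 2)
        assert tf.poiseuille_conductance(12.6, 5.9, 0.002) == pytest.approx(16 * g)


class TestNetworkSolve:
    def test_single_edge_ohm_law(self):
        net = two_node_net()
        bc = BoundaryConditions(inlet_velocity=0.001, outlet_pressure=0.0)
        sol = tf.solve_network(net, FluidModel(), bc, stub_length_um=0.0)
        g = tf.poiseuille_conductance(6.3, 5.9, 0.002)
        Q = 0.001 * math.pi * (0.5 * 6.3e-6) ** 2
        assert sol.edge_flows[0] == pytest.approx(Q, rel=1e-12)
        assert sol.pressure_drop_pa == pytest.approx(Q / g, rel=1e-12)

    def test_series_equals_double_length(self):
        # two identical edges in series vs one edge of double length
        nodes = np.array([[0.0, 0, 0], [5.9, 0, 0], [11.8, 0, 0]])
        series = tf.TubeNetwork(
            nodes=nodes, edges=np.array([[0, 1], [1, 2]]),
            diameters=np.full(2, 6.3), lengths=np.full(2, 5.9),
            port_nodes={"a": {"kind": "arteriole", "diameter": 6.3, "nodes": [0]},
                        "v": {"kind": "venule", "diameter": 6.3, "nodes": [2]}})
        single = two_node_net(L=11.8)
        bc = BoundaryConditions(inlet_velocity=0.001, outlet_pressure=0.0)
        s1 = tf.solve_network(series, FluidModel(), bc, stub_length_um=0.0)
        s2 = tf.solve_network(single, FluidModel(), bc, stub_length_um=0.0)
        assert s1.pressure_drop_pa == pytest.approx(s2.pressure_drop_pa, rel=1e-10)

    def test_parallel_equals_equivalent_conductance(self):
        nodes = np.array([[0.0, 0, 0], [5.9, 5.0, 0], [5.9, -5.0, 0],
                          [11.8, 0, 0]])
        # two parallel two-edge branches between inlet and outlet
        net = tf.TubeNetwork(
            nodes=nodes,
            edges=np.array([[0, 1], [1, 3], [0, 2], [2, 3]]),
            diameters=np.full(4, 6.3), lengths=np.full(4, 5.9),
            port_nodes={"a": {"kind": "arteriole", "diameter": 6.3, "nodes": [0]},
                        "v": {"kind": "venule", "diameter": 6.3, "nodes": [3]}})
        bc = BoundaryConditions(inlet_velocity=0.001, outlet_pressure=0.0)
        sol = tf.solve_network(net, FluidModel(), bc, stub_length_um=0.0)
        g = tf.poiseuille_conductance(6.3, 5.9, 0.002)
        Q = 0.001 * math.pi * (0.5 * 6.3e-6) ** 2
        assert sol.pressure_drop_pa == pytest.approx(Q / g, rel=1e-10)

    def test_no_venule_singular(self):
        net = two_node_net()
        net.port_nodes = {"a": {"kind": "arteriole", "diameter": 6.3, "nodes": [0]}}
        with pytest.raises(SingularSystemError):
            tf.solve_network(net, FluidModel(), BoundaryConditions())

    def test_carreau_matches_newtonian_when_degenerate(self):
        net = two_node_net()
        bc = BoundaryConditions(inlet_velocity=0.001, outlet_pressure=0.0)
        newt = tf.solve_network(net, FluidModel.newtonian(0.002), bc,
                                stub_length_um=0.0)
        pseudo = tf.solve_network(net, FluidModel.carreau(eta0=0.002, eta_inf=0.002),
                                  bc, stub_length_um=0.0)
        assert pseudo.pressure_drop_pa == pytest.approx(newt.pressure_drop_pa,
                                                        rel=1e-9)


@pytest.fixture(scope="module")
def net(base, params):
    return tf.build_tube_network(base, params, ConnectivityConfig(), seed=3)


class TestBuildNetwork:
    def test_deterministic(self, base, params, net):
        again = tf.build_tube_network(base, params, ConnectivityConfig(), seed=3)
        assert np.array_equal(net.nodes, again.nodes)
        assert np.array_equal(net.edges, again.edges)

    def test_interior_degree_at_least_three(self, net):
        deg = np.zeros(len(net.nodes), dtype=int)
        np.add.at(deg, net.edges.ravel(), 1)
        # rim nodes of the mouth may have degree 2; interior nodes never do
        assert np.quantile(deg, 0.1) >= 3

    def test_uniform_diameter_and_positive_lengths(self, net, params):
        assert np.allclose(net.diameters, params.tube_capillary_diameter)
        assert (net.lengths > 0).all()

    def test_solve_conserves_mass(self, net):
        sol = tf.solve_network(net, FluidModel(), BoundaryConditions())
        assert sol.node_balance_residual < 1e-10

    def test_speed_rises_with_arteriolar_area(self, base, params):
        speeds = []
        for n in (1, 3, 5):
            net = tf.build_tube_network(
                base, params, ConnectivityConfig(n_arterioles=n, n_venules=n),
                seed=3)
            sol = tf.solve_network(net, FluidModel(), BoundaryConditions())
            speeds.append(sol.mean_capillary_speed)
        assert speeds[0] < speeds[1] < speeds[2]
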