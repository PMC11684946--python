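"""Tube-flow variant of the capillary network: a Poiseuille resistance graph.

The alternative concept of the capillary bed is a network of cylindrical
segments of uniform diameter and length.  Each edge carries Hagen-Poiseuille
conductance g = π d⁴/(128 µ L) and Kirchhoff conservation holds at the
junctions; arterioles inject flux, venules pin the outlet pressure.  The
tube model is retained for morphometric comparison with the sheet model and
for cross-validation of connectivity trends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConvergenceError, InvalidGeometryError, SingularSystemError
from .geometry import (AlveolarBase, ConnectivityConfig, MorphoParams,
                       place_ports)
from .sheetflow import UM, BoundaryConditions, FluidModel
from .units import pa_to_mmhg

__all__ = [
    "TubeNetwork",
    "NetworkSolution",
    "build_tube_network",
    "poiseuille_conductance",
    "solve_network",
]


@dataclass
class TubeNetwork:
    """Graph of cylindrical capillary segments on the alveolar surface."""

    nodes: np.ndarray                 # (n, 3) µm
    edges: np.ndarray                 # (m, 2) int
    diameters: np.ndarray             # (m,) µm
    lengths: np.ndarray               # (m,) µm
    port_nodes: dict                  # label -> {"kind", "diameter", "nodes"}
    seed: int | None = None

    def total_lumen_volume(self) -> float:
        """Σ π(d/2)²L over segments (µm³)."""
        return float((math.pi * (0.5 * self.diameters) ** 2 * self.lengths).sum())

    def to_networkx(self):
        import networkx as nx
        g = nx.Graph()
        for i, xyz in enumerate(self.nodes):
            g.add_node(i, pos=tuple(xyz))
        for (i, j), d, L in zip(self.edges, self.diameters, self.lengths):
            g.add_edge(int(i), int(j), diameter=float(d), length=float(L))
        return g


@dataclass
class NetworkSolution:
    pressures: np.ndarray             # Pa per node
    edge_flows: np.ndarray            # m³/s
    edge_speeds: np.ndarray           # m/s
    mean_capillary_speed: float       # m/s, lumen-volume weighted
    pressure_drop_pa: float
    pressure_drop_mmhg: float
    node_balance_residual: float      # max relative net flow at interior nodes
    iterations: int = 1

    @property
    def mean_capillary_speed_mm_s(self) -> float:
        return self.mean_capillary_speed * 1e3


def poiseuille_conductance(d: float, L: float, mu: float) -> float:
    """Hagen-Poiseuille conductance g = π d⁴ / (128 µ L) in m³/(s·Pa).

    ``d`` and ``L`` in µm, ``mu`` in Pa·s.
    """
    if d <= 0 or L <= 0 or mu <= 0:
        raise InvalidGeometryError("d, L and mu must be positive")
    d_m, L_m = d * UM, L * UM
    return math.pi * d_m ** 4 / (128.0 * mu * L_m)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation about the mouth axis (+z)."""
    a = rng.uniform(0.0, 2.0 * math.pi)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def build_tube_network(base: AlveolarBase, params: MorphoParams,
                       config: ConnectivityConfig, seed: int = 0) -> TubeNetwork:
    """Quasi-uniform tube network from triangulation edges on the closed surface.

    Target edge length = tube segment length; uniform diameter = tube
    capillary diameter.  Replicates differ by a random rotation of the
    triangulation about the mouth axis.  Ports attach to their three nearest
    nodes to avoid point-source artifacts.
    """
    import trimesh

    R = base.sphere_radius
    # nearest icosphere level to the target segment length (quasi-uniform)
    from .geometry import _ICO_EDGE_RAD
    n_sub = max(2, round(math.log2(_ICO_EDGE_RAD * R / params.tube_segment_length)))
    ico = trimesh.creation.icosphere(subdivisions=n_sub, radius=1.0)
    rng = np.random.default_rng(seed)
    dirs = np.asarray(ico.vertices) @ _random_rotation(rng).T
    faces = np.asarray(ico.faces)

    # keep faces entirely below the mouth rim
    below = dirs[:, 2] < math.cos(base.mouth_cap_angle)
    keep = below[faces].all(axis=1)
    faces = faces[keep]
    if len(faces) == 0:
        raise InvalidGeometryError("mouth removed the whole tube network")
    used = np.unique(faces)
    remap = -np.ones(len(dirs), dtype=np.int64)
    remap[used] = np.arange(len(used))
    dirs = dirs[used]
    faces = remap[faces]

    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    nodes = dirs * R
    lengths = np.linalg.norm(nodes[edges[:, 0]] - nodes[edges[:, 1]], axis=1)
    diameters = np.full(len(edges), params.tube_capillary_diameter)

    ports = place_ports(base, config, mid_surface_radius=R)
    port_nodes: dict[str, dict] = {}
    for p in ports:
        d2 = ((dirs - p.center) ** 2).sum(axis=1)
        nearest = np.argsort(d2)[:3]
        port_nodes[p.label] = {"kind": p.kind, "diameter": p.diameter,
                               "nodes": nearest.tolist()}
    return TubeNetwork(nodes=nodes, edges=edges, diameters=diameters,
                       lengths=lengths, port_nodes=port_nodes, seed=seed)


def _laplacian(net: TubeNetwork, mu_e: np.ndarray) -> tuple[sp.csr_matrix, np.ndarray]:
    g = np.array([poiseuille_conductance(d, L, m)
                  for d, L, m in zip(net.diameters, net.lengths, mu_e)])
    n = len(net.nodes)
    i, j = net.edges[:, 0], net.edges[:, 1]
    K = sp.coo_matrix(
        (np.concatenate([-g, -g, g, g]),
         (np.concatenate([i, j, i, j]), np.concatenate([j, i, i, j]))),
        shape=(n, n)).tocsr()
    return K, g


def solve_network(net: TubeNetwork, fluid: FluidModel,
                  bc: BoundaryConditions, picard_tol: float = 1e-6,
                  max_iter: int = 100,
                  stub_length_um: float = 100.0) -> NetworkSolution:
    """Kirchhoff solve G·p = q; Carreau rheology via Picard with γ = 8v/d."""
    n = len(net.nodes)
    inlet_nodes: dict[int, float] = {}
    dirichlet: list[int] = []
    q_per_port: dict[str, float] = {}
    art_ports, ven_ports = [], []
    for label, rec in net.port_nodes.items():
        if rec["kind"] == "arteriole":
            Q = bc.inlet_velocity * math.pi * (0.5 * rec["diameter"] * UM) ** 2
            q_per_port[label] = Q
            for nd in rec["nodes"]:
                inlet_nodes[nd] = inlet_nodes.get(nd, 0.0) + Q / len(rec["nodes"])
            art_ports.append((label, rec))
        else:
            dirichlet.extend(rec["nodes"])
            ven_ports.append((label, rec))
    if not dirichlet:
        raise SingularSystemError("no venule (Dirichlet) node")
    dirichlet = np.unique(dirichlet)
    b = np.zeros(n)
    for nd, q in inlet_nodes.items():
        b[nd] += q

    mu_e = np.full(len(net.edges),
                   fluid.mu if fluid.rheology == "newtonian" else fluid.eta0)
    free = np.setdiff1d(np.arange(n), dirichlet)
    speeds_old = None
    for it in range(1, max_iter + 1):
        K, g = _laplacian(net, mu_e)
        p = np.full(n, bc.outlet_pressure, dtype=float)
        rhs = b[free] - K[free][:, dirichlet] @ p[dirichlet]
        p[free] = spla.spsolve(K[free][:, free].tocsc(), rhs)
        flows = g * (p[net.edges[:, 0]] - p[net.edges[:, 1]])
        areas = math.pi * (0.5 * net.diameters * UM) ** 2
        speeds = np.abs(flows) / areas
        if fluid.rheology == "newtonian":
            break
        gamma = 8.0 * speeds / (net.diameters * UM)
        mu_new = np.asarray(fluid.viscosity(gamma))
        if speeds_old is not None:
            change = float(np.max(np.abs(speeds - speeds_old))
                           / max(speeds.max(), 1e-300))
            if change < picard_tol:
                break
        speeds_old = speeds
        mu_e = 0.5 * mu_e + 0.5 * mu_new
    else:
        raise ConvergenceError("tube-network Picard did not converge")

    # interior mass balance
    net_flow = np.zeros(n)
    np.add.at(net_flow, net.edges[:, 0], -flows)
    np.add.at(net_flow, net.edges[:, 1], flows)
    interior = np.ones(n, dtype=bool)
    interior[dirichlet] = False
    resid = net_flow.copy()
    for nd, q in inlet_nodes.items():
        resid[nd] += q
    q_tot = sum(q_per_port.values())
    balance = float(np.abs(resid[interior]).max() / q_tot) if q_tot > 0 else 0.0

    # lumen-volume weighted mean speed
    vol = areas * net.lengths * UM
    mean_speed = float((vol * speeds).sum() / vol.sum())

    # pressure drop with both vessel stubs, as in the sheet solver
    def stub(mu_loc, L_um, v, d_um):
        return 32.0 * mu_loc * (L_um * UM) * v / (d_um * UM) ** 2

    p_in, q_in = 0.0, 0.0
    for label, rec in art_ports:
        Q = q_per_port[label]
        v_tube = bc.inlet_velocity
        mu_t = (fluid.mu if fluid.rheology == "newtonian"
                else float(fluid.viscosity(8 * v_tube / (rec["diameter"] * UM))))
        rim_p = float(np.mean(p[rec["nodes"]]))
        p_in += Q * (rim_p + stub(mu_t, stub_length_um, v_tube, rec["diameter"]))
        q_in += Q
    p_in = p_in / q_in if q_in > 0 else bc.outlet_pressure
    p_out = bc.outlet_pressure
    if ven_ports and q_in > 0:
        q_share = q_in / len(ven_ports)
        corr = 0.0
        for label, rec in ven_ports:
            area = math.pi * (0.5 * rec["diameter"] * UM) ** 2
            v_tube = q_share / area
            mu_t = (fluid.mu if fluid.rheology == "newtonian"
                    else float(fluid.viscosity(8 * v_tube / (rec["diameter"] * UM))))
            corr += stub(mu_t, stub_length_um, v_tube, rec["diameter"])
        p_out -= corr / len(ven_ports)
    dp = p_in - p_out if q_in > 0 else 0.0
    return NetworkSolution(
        pressures=p, edge_flows=flows, edge_speeds=speeds,
        mean_capillary_speed=mean_speed, pressure_drop_pa=dp,
        pressure_drop_mmhg=pa_to_mmhg(dp), node_balance_residual=balance,
        iterations=it)
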