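"""Thin-film (Hele-Shaw) blood flow through the capillary sheet.

At the scale of an alveolus the flow is deep in the Stokes regime
(Re ≈ 0.008) and the sheet height h is two orders of magnitude smaller than
the alveolar radius, so the steady incompressible momentum balance reduces to
the lubrication closure on the curved mid-surface:

    ∇s·(T ∇s p) = 0,     T = h³(1−φ)/(12 µ f),     u = −h²/(12 µ f)·∇s p

where φ is the pillar plan-area fraction and f ≥ 1 a friction factor that
homogenizes the extra drag of the tissue pillars (calibrated against a
resolved unit-cell problem, :func:`estimate_friction_factor`).  Arterioles
impose a per-port volumetric influx Q = v_in·π(d/2)², venules a reference
pressure; the mouth, pores and sheet side walls are impermeable.  Blood is
either Newtonian (2 cP) or shear thinning via the Carreau law, solved by
Picard iteration on the apparent viscosity.

Discretization: piecewise-linear (P1) finite elements on the triangulated
mid-surface, symmetric positive-definite sparse system, direct factorization.
Geometry arrives in µm and is converted to SI internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import (ConvergenceError, EmptyBandError, InvalidGeometryError,
                     ResolutionError, SingularSystemError)
from .geometry import SheetDomain
from .units import pa_to_mmhg

__all__ = [
    "FluidModel",
    "BoundaryConditions",
    "SheetFlowProblem",
    "FlowSolution",
    "assemble_and_solve_newtonian",
    "solve_carreau",
    "solve_sheet",
    "mean_capillary_speed",
    "pressure_drop",
    "position_speeds",
    "estimate_friction_factor",
    "reynolds_number",
    "carreau_viscosity",
]

UM = 1e-6  # µm -> m


# ---------------------------------------------------------------------------
# fluid and boundary conditions
# ---------------------------------------------------------------------------

def carreau_viscosity(gamma, eta0: float = 0.056, eta_inf: float = 0.0035,
                      lam: float = 1.902, n_index: float = 0.3568):
    """Carreau apparent viscosity η(γ) in Pa·s.

    η = η∞ + (η0 − η∞)·[1 + (λγ)²]^((n−1)/2); bounded by η∞ and η0.
    """
    g = np.asarray(gamma, dtype=float)
    eta = eta_inf + (eta0 - eta_inf) * (1.0 + (lam * g) ** 2) ** ((n_index - 1.0) / 2.0)
    return eta if eta.shape else float(eta)


@dataclass(frozen=True)
class FluidModel:
    """Blood rheology: Newtonian (constant µ) or Carreau shear thinning."""

    density: float = 1050.0        # kg/m³
    rheology: str = "newtonian"    # {"newtonian", "carreau"}
    mu: float = 0.002              # Pa·s (Newtonian)
    eta0: float = 0.056            # Pa·s, zero-shear viscosity
    eta_inf: float = 0.0035        # Pa·s, infinite-shear viscosity
    lam: float = 1.902             # s, Carreau time constant
    n_index: float = 0.3568        # power-law index

    def __post_init__(self):
        if self.density <= 0:
            raise InvalidGeometryError("density must be positive")
        if self.rheology not in ("newtonian", "carreau"):
            raise InvalidGeometryError(f"unknown rheology {self.rheology!r}")
        if self.rheology == "newtonian" and self.mu <= 0:
            raise InvalidGeometryError("viscosity must be positive")
        if self.eta_inf > self.eta0:
            raise InvalidGeometryError("eta_inf must not exceed eta0")

    def viscosity(self, gamma):
        """Apparent viscosity at shear rate γ (1/s)."""
        if self.rheology == "newtonian":
            g = np.asarray(gamma, dtype=float)
            return np.full_like(g, self.mu) if g.shape else self.mu
        return carreau_viscosity(gamma, self.eta0, self.eta_inf,
                                 self.lam, self.n_index)

    @classmethod
    def newtonian(cls, mu: float = 0.002, density: float = 1050.0) -> "FluidModel":
        return cls(density=density, rheology="newtonian", mu=mu)

    @classmethod
    def carreau(cls, density: float = 1050.0, **kw) -> "FluidModel":
        return cls(density=density, rheology="carreau", **kw)


@dataclass(frozen=True)
class BoundaryConditions:
    """Velocity inlet at the arterioles, pressure outlet at the venules."""

    inlet_velocity: float = 0.0023   # m/s
    outlet_pressure: float = 1127.0  # Pa

    def __post_init__(self):
        if self.inlet_velocity < 0:
            raise InvalidGeometryError("inlet velocity must be >= 0")


@dataclass(frozen=True)
class SheetFlowProblem:
    """A sheet domain plus fluid model, boundary conditions and solver options.

    ``friction_factor_mode`` selects the pillar-drag closure: ``"unity"``
    (f = 1, pillars only reduce the open area), ``"calibrated"`` (unit-cell
    homogenization of the domain's lattice) or a numeric value used directly.
    Arterioles and venules continue as straight Poiseuille tube stubs of
    ``vessel_stub_length`` µm whose losses are added analytically.
    """

    domain: SheetDomain
    fluid: FluidModel = field(default_factory=FluidModel)
    bc: BoundaryConditions = field(default_factory=BoundaryConditions)
    friction_factor_mode: object = "calibrated"
    vessel_stub_length: float = 100.0     # µm
    inlet_flux_override: dict | None = None   # label -> Q (m³/s)
    linear_solver: str = "direct"         # {"direct", "iterative"}

    def friction_factor(self) -> float:
        mode = self.friction_factor_mode
        if isinstance(mode, (int, float)):
            return float(mode)
        if mode == "unity":
            return 1.0
        if mode == "calibrated":
            lat = self.domain.lattice
            if lat is None or lat.pillar_diameter <= 0:
                return 1.0
            return estimate_friction_factor(lat.pillar_diameter, lat.pitch)
        raise InvalidGeometryError(f"unknown friction factor mode {mode!r}")

    def open_fraction(self) -> float:
        lat = self.domain.lattice
        return 1.0 if lat is None else lat.open_fraction

    def inlet_fluxes(self) -> dict:
        """Per-arteriole volumetric influx Q_j (m³/s), keyed by port label."""
        fluxes = {}
        for p in self.domain.ports_by_kind("arteriole"):
            if self.inlet_flux_override and p.label in self.inlet_flux_override:
                fluxes[p.label] = float(self.inlet_flux_override[p.label])
            else:
                area = math.pi * (0.5 * p.diameter * UM) ** 2
                fluxes[p.label] = self.bc.inlet_velocity * area
        return fluxes


@dataclass
class FlowSolution:
    """Pressure/velocity fields and the scalar hemodynamic targets."""

    pressure: np.ndarray            # Pa, per vertex
    velocity: np.ndarray            # m/s, per face (3-vector, tangent)
    speed: np.ndarray               # m/s, per face
    shear_rate: np.ndarray          # 1/s, per face (γ = 6|u|/h)
    viscosity: np.ndarray           # Pa·s, per face (apparent)
    mean_capillary_speed: float     # m/s, mass-weighted over sheet elements
    pressure_drop_pa: float
    pressure_drop_mmhg: float
    position_speeds: dict           # {inlet, near_arteriole, center, near_venule, outlet}
    mass_balance_residual: float    # relative
    iterations: int
    friction_factor: float
    residual_history: list = field(default_factory=list)

    @property
    def mean_capillary_speed_mm_s(self) -> float:
        return self.mean_capillary_speed * 1e3


# ---------------------------------------------------------------------------
# P1 assembly on the triangulated surface
# ---------------------------------------------------------------------------

class _Discretization:
    """Per-domain FEM precomputation reused across solves."""

    def __init__(self, domain: SheetDomain):
        self.domain = domain
        v = domain.vertices * UM
        f = domain.faces
        self.nv = len(v)
        self.faces = f
        t0, t1, t2 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
        n = np.cross(t1 - t0, t2 - t0)
        nrm = np.linalg.norm(n, axis=1)
        if np.any(nrm <= 0):
            raise InvalidGeometryError("degenerate triangle in flow domain")
        self.area = 0.5 * nrm                       # m²
        nhat = n / nrm[:, None]
        inv2A = 1.0 / (2.0 * self.area)
        # ∇λ_i = n̂ × (x_k − x_j) / (2A), (i, j, k) cyclic
        self.grads = np.stack([
            np.cross(nhat, t2 - t1) * inv2A[:, None],
            np.cross(nhat, t0 - t2) * inv2A[:, None],
            np.cross(nhat, t1 - t0) * inv2A[:, None],
        ], axis=1)                                   # (nf, 3, 3)
        # stiffness sparsity pattern entries
        gg = np.einsum("fid,fjd->fij", self.grads, self.grads)  # (nf,3,3)
        self._gg_area = gg * self.area[:, None, None]
        self.rows = np.repeat(f, 3, axis=1).reshape(-1)          # i index
        self.cols = np.tile(f, (1, 3)).reshape(-1)               # j index

    def stiffness(self, T_e: np.ndarray) -> sp.csr_matrix:
        vals = (self._gg_area * T_e[:, None, None]).reshape(-1)
        K = sp.coo_matrix((vals, (self.rows, self.cols)),
                          shape=(self.nv, self.nv)).tocsr()
        return K

    def gradient(self, p: np.ndarray) -> np.ndarray:
        """Per-face surface gradient of a nodal field (units of p per m)."""
        pf = p[self.faces]                            # (nf, 3)
        return np.einsum("fi,fid->fd", pf, self.grads)


_DISC_CACHE: dict[int, _Discretization] = {}


def _discretize(domain: SheetDomain) -> _Discretization:
    key = id(domain)
    disc = _DISC_CACHE.get(key)
    if disc is None or disc.domain is not domain:
        disc = _Discretization(domain)
        _DISC_CACHE.clear()
        _DISC_CACHE[key] = disc
    return disc


def _rim_node_weights(domain: SheetDomain, label: str) -> tuple[np.ndarray, np.ndarray]:
    """Rim node indices and their tributary rim lengths (m)."""
    edges = domain.port_rim_edges(label)
    if len(edges) == 0:
        raise InvalidGeometryError(f"port {label} has no rim edges")
    v = domain.vertices * UM
    L = np.linalg.norm(v[edges[:, 0]] - v[edges[:, 1]], axis=1)
    w: dict[int, float] = {}
    for (i, j), le in zip(edges, L):
        w[int(i)] = w.get(int(i), 0.0) + 0.5 * le
        w[int(j)] = w.get(int(j), 0.0) + 0.5 * le
    nodes = np.array(sorted(w), dtype=np.int64)
    return nodes, np.array([w[int(i)] for i in nodes])


def _solve_linear(problem: SheetFlowProblem, disc: _Discretization,
                  T_e: np.ndarray) -> tuple[np.ndarray, float, dict]:
    """Solve K p = b with inlet fluxes and outlet Dirichlet pressure."""
    domain = problem.domain
    K = disc.stiffness(T_e)
    b = np.zeros(disc.nv)
    fluxes = problem.inlet_fluxes()
    for label, Q in fluxes.items():
        nodes, w = _rim_node_weights(domain, label)
        b[nodes] += Q * w / w.sum()

    venules = domain.ports_by_kind("venule")
    if not venules:
        raise SingularSystemError("no venule (pressure outlet) port")
    dir_nodes = np.unique(np.concatenate(
        [domain.boundary_loops[p.label] for p in venules]))
    p_out = problem.bc.outlet_pressure

    free = np.setdiff1d(np.arange(disc.nv), dir_nodes)
    p = np.full(disc.nv, p_out, dtype=float)
    rhs = b[free] - K[free][:, dir_nodes] @ np.full(len(dir_nodes), p_out)
    K_ff = K[free][:, free].tocsc()
    if problem.linear_solver == "iterative":
        sol, info = spla.cg(K_ff, rhs, rtol=1e-12, maxiter=20000)
        if info != 0:
            raise ConvergenceError("iterative linear solve failed", residual=float(info))
        p[free] = sol
    else:
        p[free] = spla.spsolve(K_ff, rhs)

    # mass balance: Dirichlet reactions are (negative) influx, so outflow = -Σr
    reactions = (K @ p - b)
    q_out = -float(reactions[dir_nodes].sum())
    q_in = float(sum(fluxes.values()))
    residual = abs(q_in - q_out) / q_in if q_in > 0 else abs(q_out)
    # per-venule outflow for stub losses / outlet speed
    out_flux = {}
    for pr in venules:
        nodes = domain.boundary_loops[pr.label]
        out_flux[pr.label] = -float(reactions[nodes].sum())
    return p, residual, out_flux


def _postprocess(problem: SheetFlowProblem, disc: _Discretization,
                 p: np.ndarray, mu_e: np.ndarray, f: float,
                 residual: float, out_flux: dict, iterations: int,
                 history: list | None = None) -> FlowSolution:
    domain = problem.domain
    h = domain.sheet_height * UM
    gp = disc.gradient(p)
    u = -(h * h / (12.0 * mu_e * f))[:, None] * gp
    speed = np.linalg.norm(u, axis=1)
    gamma = 6.0 * speed / h
    mean_speed = _mass_weighted_mean(speed, disc.area, problem)
    dp_pa = _pressure_drop_pa(problem, p, mu_e_hint=None, out_flux=out_flux)
    pos = _position_speeds(problem, disc, speed, out_flux)
    return FlowSolution(
        pressure=p, velocity=u, speed=speed, shear_rate=gamma,
        viscosity=mu_e.copy(), mean_capillary_speed=mean_speed,
        pressure_drop_pa=dp_pa, pressure_drop_mmhg=pa_to_mmhg(dp_pa),
        position_speeds=pos, mass_balance_residual=residual,
        iterations=iterations, friction_factor=f,
        residual_history=list(history or []))


def _mass_weighted_mean(speed: np.ndarray, area: np.ndarray,
                        problem: SheetFlowProblem) -> float:
    # mass per element ∝ ρ h (1−φ) A; h, φ, ρ uniform here but kept explicit
    w = (problem.fluid.density * problem.domain.sheet_height * UM
         * problem.open_fraction() * area)
    return float((w * speed).sum() / w.sum())


def _stub_loss_pa(problem: SheetFlowProblem, diameter_um: float,
                  v_tube: float) -> float:
    """Hagen–Poiseuille loss of one vessel stub, 32 µ L v / d²."""
    d = diameter_um * UM
    L = problem.vessel_stub_length * UM
    if problem.fluid.rheology == "carreau":
        mu = float(problem.fluid.viscosity(8.0 * abs(v_tube) / d))
    else:
        mu = problem.fluid.mu
    return 32.0 * mu * L * v_tube / (d * d)


def _pressure_drop_pa(problem: SheetFlowProblem, p: np.ndarray,
                      mu_e_hint, out_flux: dict) -> float:
    """Arteriole-to-venule pressure drop including both vessel-stub losses.

    Rim pressures are flux weighted; each vessel's Poiseuille stub loss moves
    the measurement point to the far (tube) end of the vessel, mirroring a
    pressure readout at the inlet and outlet surfaces.
    """
    domain = problem.domain
    fluxes = problem.inlet_fluxes()
    q_tot = sum(fluxes.values())
    if q_tot == 0:
        return 0.0
    p_in = 0.0
    for pr in domain.ports_by_kind("arteriole"):
        nodes, w = _rim_node_weights(domain, pr.label)
        rim_p = float((p[nodes] * w).sum() / w.sum())
        area = math.pi * (0.5 * pr.diameter * UM) ** 2
        v_tube = fluxes[pr.label] / area
        p_in += fluxes[pr.label] * (rim_p + _stub_loss_pa(problem, pr.diameter, v_tube))
    p_in /= q_tot

    p_out_eff = 0.0
    q_out_tot = 0.0
    for pr in domain.ports_by_kind("venule"):
        q = out_flux.get(pr.label, 0.0)
        area = math.pi * (0.5 * pr.diameter * UM) ** 2
        v_tube = q / area
        p_out_eff += q * (problem.bc.outlet_pressure
                          - _stub_loss_pa(problem, pr.diameter, v_tube))
        q_out_tot += q
    p_out_eff = p_out_eff / q_out_tot if q_out_tot != 0 else problem.bc.outlet_pressure
    return p_in - p_out_eff


def _position_speeds(problem: SheetFlowProblem, disc: _Discretization,
                     speed: np.ndarray, out_flux: dict) -> dict:
    """Speeds at the paper's five measurement positions."""
    domain = problem.domain
    result = {"inlet": problem.bc.inlet_velocity}
    venules = domain.ports_by_kind("venule")
    q_out = sum(out_flux.values())
    if q_out != 0:
        outlet = sum(out_flux[p.label] * (out_flux[p.label]
                     / (math.pi * (0.5 * p.diameter * UM) ** 2))
                     for p in venules) / q_out
    else:
        outlet = 0.0
    result["outlet"] = outlet

    if domain.mid_surface_radius is None:
        result.update(near_arteriole=float("nan"), center=float("nan"),
                      near_venule=float("nan"))
        return result

    cent = domain.face_centroids
    cent = cent / np.linalg.norm(cent, axis=1, keepdims=True)
    w = disc.area * problem.open_fraction()

    def band_mean(mask: np.ndarray, name: str) -> float:
        if not mask.any():
            raise EmptyBandError(f"no elements in the {name} band")
        return float((w[mask] * speed[mask]).sum() / w[mask].sum())

    far_all = np.ones(len(cent), dtype=bool)
    for kind in ("arteriole", "venule"):
        near = np.zeros(len(cent), dtype=bool)
        for pr in domain.ports_by_kind(kind):
            ang = np.arccos(np.clip(cent @ pr.center, -1, 1))
            near |= (ang > pr.angular_radius) & (ang <= 2.5 * pr.angular_radius)
        result[f"near_{kind}"] = band_mean(near, f"near_{kind}")
    for pr in domain.ports:
        ang = np.arccos(np.clip(cent @ pr.center, -1, 1))
        far_all &= ang > 4.0 * pr.angular_radius
    result["center"] = band_mean(far_all, "center")
    return result


# ---------------------------------------------------------------------------
# public solves
# ---------------------------------------------------------------------------

def assemble_and_solve_newtonian(problem: SheetFlowProblem) -> FlowSolution:
    """Solve the Newtonian thin-film problem (single sparse solve)."""
    if problem.fluid.rheology != "newtonian":
        raise InvalidGeometryError("Newtonian solve requires newtonian rheology")
    disc = _discretize(problem.domain)
    f = problem.friction_factor()
    h = problem.domain.sheet_height * UM
    mu_e = np.full(len(disc.faces), problem.fluid.mu)
    T_e = h ** 3 * problem.open_fraction() / (12.0 * mu_e * f)
    p, residual, out_flux = _solve_linear(problem, disc, T_e)
    return _postprocess(problem, disc, p, mu_e, f, residual, out_flux, 1)


def solve_carreau(problem: SheetFlowProblem, picard_tol: float = 1e-5,
                  max_iter: int = 100) -> FlowSolution:
    """Picard iteration on the Carreau apparent viscosity.

    Per element η_k = η(γ_k) with γ = 6|u|/h, under-relaxation 0.5 on η,
    until the maximum relative change of |u| falls below ``picard_tol``.
    """
    if problem.fluid.rheology != "carreau":
        raise InvalidGeometryError("Carreau solve requires carreau rheology")
    disc = _discretize(problem.domain)
    f = problem.friction_factor()
    h = problem.domain.sheet_height * UM
    open_frac = problem.open_fraction()
    mu_e = np.full(len(disc.faces), problem.fluid.eta0)
    speed_old = None
    history: list[float] = []
    for it in range(1, max_iter + 1):
        T_e = h ** 3 * open_frac / (12.0 * mu_e * f)
        p, residual, out_flux = _solve_linear(problem, disc, T_e)
        gp = disc.gradient(p)
        u = -(h * h / (12.0 * mu_e * f))[:, None] * gp
        speed = np.linalg.norm(u, axis=1)
        gamma = 6.0 * speed / h
        mu_new = np.asarray(problem.fluid.viscosity(gamma))
        if speed_old is not None:
            scale = max(speed.max(), 1e-300)
            change = float(np.max(np.abs(speed - speed_old)) / scale)
            history.append(change)
            if change < picard_tol:
                return _postprocess(problem, disc, p, mu_e, f, residual,
                                    out_flux, it, history)
        speed_old = speed
        mu_e = 0.5 * mu_e + 0.5 * mu_new
    raise ConvergenceError(
        f"Picard iteration did not converge in {max_iter} iterations",
        residual=history[-1] if history else None, history=history)


def solve_sheet(problem: SheetFlowProblem, **kw) -> FlowSolution:
    """Dispatch on the fluid rheology."""
    if problem.fluid.rheology == "carreau":
        return solve_carreau(problem, **kw)
    return assemble_and_solve_newtonian(problem)


# ---------------------------------------------------------------------------
# scalar measurements
# ---------------------------------------------------------------------------

def mean_capillary_speed(sol: FlowSolution, domain: SheetDomain,
                         open_fraction: float | None = None,
                         density: float = 1050.0) -> float:
    """Mass-weighted mean speed over sheet elements (m/s).

    Weights ∝ ρ h (1−φ) A per element; ports/stubs carry no elements.
    """
    phi_open = 1.0 if domain.lattice is None else domain.lattice.open_fraction
    if open_fraction is not None:
        phi_open = open_fraction
    w = density * domain.sheet_height * UM * phi_open * domain.face_areas * UM * UM
    return float((w * sol.speed).sum() / w.sum())


def pressure_drop(sol: FlowSolution, problem: SheetFlowProblem) -> float:
    """Arteriole-to-venule pressure drop in mmHg (see solver docstring)."""
    return sol.pressure_drop_mmhg


def position_speeds(sol: FlowSolution, domain: SheetDomain) -> dict:
    return dict(sol.position_speeds)


def reynolds_number(fluid: FluidModel, v: float, L: float) -> float:
    """Re = ρ v L / µ; Carreau fluids use the infinite-shear viscosity η∞."""
    if v <= 0 or L <= 0:
        if v == 0:
            return 0.0
        raise InvalidGeometryError("v and L must be positive")
    mu = fluid.mu if fluid.rheology == "newtonian" else fluid.eta_inf
    return fluid.density * v * L / mu


# ---------------------------------------------------------------------------
# pillar friction factor from a resolved unit cell
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def estimate_friction_factor(d_p: float, pitch: float,
                             h: float | None = None,
                             resolution: int = 161) -> float:
    """Friction factor of a square pillar array from a 2-D cell problem.

    Solves the thin-film pressure problem on one periodic square cell with
    the pillar disc as a zero-flux hole (finite volumes, harmonic face
    transmissivities), drives a unit pressure drop across the cell and
    measures the effective transmissivity T_eff.  The friction factor is the
    open-fraction-corrected obstruction ratio

        f = (1 − φ)·T0 / T_eff ≥ 1,

    so that T = h³(1−φ)/(12µf) reproduces the resolved cell flux.
    The sheet height drops out of the 2-D problem; ``h`` is accepted for
    interface symmetry.
    """
    if d_p <= 0:
        return 1.0
    if d_p >= pitch:
        raise InvalidGeometryError("pillar diameter must be below the pitch")
    N = int(resolution)
    dx = pitch / N
    if d_p / dx < 8:
        raise ResolutionError(
            f"fewer than 8 cells across the pillar (resolution={N})")
    xc = (np.arange(N) + 0.5) * dx
    X, Y = np.meshgrid(xc, xc, indexing="ij")
    r2 = (X - 0.5 * pitch) ** 2 + (Y - 0.5 * pitch) ** 2
    T = np.where(r2 <= (0.5 * d_p) ** 2, 0.0, 1.0)

    def harm(a, b):
        s = a + b
        return np.where(s > 0, 2.0 * a * b / np.where(s > 0, s, 1.0), 0.0)

    idx = np.arange(N * N).reshape(N, N)
    rows, cols, vals = [], [], []
    diag = np.zeros(N * N)

    def add_face(i1, i2, t):
        c = t / (dx * dx)  # conductance per unit cell area scale (uniform dx)
        rows.extend([i1, i2]); cols.extend([i2, i1]); vals.extend([-c, -c])
        diag[i1] += c; diag[i2] += c

    tx = harm(T[:-1, :], T[1:, :])
    for i in range(N - 1):
        for j in range(N):
            if tx[i, j] > 0:
                add_face(idx[i, j], idx[i + 1, j], tx[i, j])
    ty = harm(T[:, :-1], T[:, 1:])
    for i in range(N):
        for j in range(N - 1):
            if ty[i, j] > 0:
                add_face(idx[i, j], idx[i, j + 1], ty[i, j])
    # Dirichlet p=1 on the left face, p=0 on the right (half-cell spacing)
    b = np.zeros(N * N)
    for j in range(N):
        if T[0, j] > 0:
            c = 2.0 * T[0, j] / (dx * dx)
            diag[idx[0, j]] += c
            b[idx[0, j]] += c * 1.0
        if T[-1, j] > 0:
            c = 2.0 * T[-1, j] / (dx * dx)
            diag[idx[-1, j]] += c
    rows.extend(range(N * N)); cols.extend(range(N * N)); vals.extend(diag)
    # pin fully enclosed dead cells (inside the pillar) to keep K nonsingular
    dead = diag == 0
    K = sp.coo_matrix((vals, (rows, cols)), shape=(N * N, N * N)).tolil()
    for i in np.where(dead)[0]:
        K[i, i] = 1.0
    p = spla.spsolve(K.tocsc(), b)
    P = p.reshape(N, N)
    flux = 0.0
    for j in range(N):
        if T[0, j] > 0:
            flux += 2.0 * T[0, j] / dx * (1.0 - P[0, j]) * dx
    T_eff = flux * pitch / (1.0 * pitch)  # L/(Δp·W) with L = W = pitch
    phi = (math.pi / 4.0) * (d_p / pitch) ** 2
    return max(1.0, (1.0 - phi) / T_eff)
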