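"""Parametric geometry of an alveolus and its capillary sheet.

The alveolus is modeled as an open "3/4 spheroid": a sphere of radius ``R``
truncated by the plane of the alveolar mouth, a circular opening of radius
``a``.  The capillary bed wraps this base as a thin sheet (two endothelial
layers a height ``h`` apart, studded with tissue pillars); pores of Kohn
perforate the wall, and arterioles/venules attach as circular ports on the
equatorial band.  All lengths are micrometers; the mouth normal is +z and
azimuths are measured in the equatorial plane from the default arteriole
direction (+x).

The sheet itself is represented by its triangulated mid-surface (a sphere of
radius ``R + h/2`` by default) with the mouth, pores and ports carved out as
labeled holes.  Pillars are not meshed individually; they enter through the
lattice area fraction and a friction factor (see :mod:`alveoflow.sheetflow`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy.optimize import brentq

from .errors import InvalidGeometryError, MeshingError, NoSolutionError, PlacementError

__all__ = [
    "MorphoParams",
    "AlveolarBase",
    "PoreSet",
    "PillarLattice",
    "ConnectivityConfig",
    "PortRecord",
    "SheetDomain",
    "MorphometricReport",
    "solve_base_from_diameter",
    "solve_base_from_volume",
    "segment_morphometrics",
    "build_pillar_lattice",
    "place_pores",
    "place_ports",
    "build_sheet_midsurface",
    "acn_morphometrics",
    "mirror_domain",
    "make_strip_domain",
    "DEFAULT_PORT_DIAMETER_UM",
]

DEFAULT_PORT_DIAMETER_UM = 20.0

#: arc length of an icosahedron edge on the unit sphere (radians)
_ICO_EDGE_RAD = 1.1071487177940904


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MorphoParams:
    """Morphometric inputs of the alveolus + capillary-sheet model.

    Defaults are the human-scale literature values used throughout the
    package: a 225-µm alveolus (or 4.6e6 µm³ volume), a 181-µm mouth,
    17 pores of Kohn of 12.3 µm, a 6.34-µm sheet with 3.1-µm pillars
    6.17 µm apart, and 6.31-µm/5.75-µm tube capillaries.
    """

    base_mode: str = "diameter"  # {"diameter", "volume"}
    alveolus_diameter: float = 225.0
    alveolus_volume: float = 4.6e6
    mouth_diameter: float = 181.0
    n_pores: int = 17
    pore_diameter: float = 12.3
    sheet_height: float = 6.34
    interpillar_distance: float = 6.17
    pillar_diameter: float = 3.1
    tube_capillary_diameter: float = 6.31
    tube_segment_length: float = 5.75

    def __post_init__(self):
        lengths = (
            self.alveolus_diameter, self.mouth_diameter, self.pore_diameter,
            self.sheet_height, self.interpillar_distance,
            self.tube_capillary_diameter, self.tube_segment_length,
        )
        if any(x <= 0 for x in lengths) or self.alveolus_volume <= 0:
            raise InvalidGeometryError("all lengths must be positive")
        if self.pillar_diameter < 0:
            raise InvalidGeometryError("pillar diameter must be >= 0")
        if self.mouth_diameter >= self.alveolus_diameter:
            raise InvalidGeometryError("mouth must be narrower than the alveolus")
        if self.n_pores < 0:
            raise InvalidGeometryError("n_pores must be >= 0")
        if self.base_mode not in ("diameter", "volume"):
            raise InvalidGeometryError(f"unknown base_mode {self.base_mode!r}")

    def solve_base(self) -> "AlveolarBase":
        if self.base_mode == "diameter":
            return solve_base_from_diameter(self.alveolus_diameter, self.mouth_diameter)
        return solve_base_from_volume(self.alveolus_volume, self.mouth_diameter)


@dataclass(frozen=True)
class AlveolarBase:
    """Truncated-sphere alveolar base (all µm; mouth normal = +z).

    The sphere center is the origin; the mouth plane sits at ``z = z_m`` with
    ``z_m = sqrt(R² − a²)`` and the alveolus occupies the larger segment
    below it, of depth ``R + z_m``.
    """

    sphere_radius: float
    mouth_radius: float
    mouth_plane_offset: float
    depth: float

    @property
    def mouth_cap_angle(self) -> float:
        """Half-angle of the mouth cone as seen from the sphere center (rad)."""
        return math.acos(self.mouth_plane_offset / self.sphere_radius)

    def segment_volume(self) -> float:
        """Volume of the spherical segment below the mouth plane (µm³)."""
        R, d = self.sphere_radius, self.depth
        return (math.pi / 3.0) * d * d * (3.0 * R - d)

    def lateral_area(self) -> float:
        """Lateral (spherical) area of the segment, 2πR·depth (µm²)."""
        return 2.0 * math.pi * self.sphere_radius * self.depth

    def mouth_area(self) -> float:
        return math.pi * self.mouth_radius ** 2


@dataclass(frozen=True)
class PoreSet:
    """Pores of Kohn: circular holes in the alveolar wall."""

    centers: np.ndarray          # (n, 3) unit direction vectors
    pore_diameter: float         # µm
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.centers)

    def angular_radius(self, sphere_radius: float) -> float:
        return math.asin(min(1.0, 0.5 * self.pore_diameter / sphere_radius))


@dataclass(frozen=True)
class PillarLattice:
    """Homogenized description of the tissue-pillar array in the sheet."""

    lattice_type: str            # {"square", "hexagonal"}
    pitch: float                 # µm, pillar center-to-center spacing
    pillar_diameter: float       # µm
    area_fraction: float         # φ, plan-area fraction occupied by pillars
    pillar_count_estimate: float | None = None

    @property
    def open_fraction(self) -> float:
        return 1.0 - self.area_fraction


@dataclass(frozen=True)
class ConnectivityConfig:
    """Numbers, diameters and azimuths of the attached arterioles/venules.

    Arterioles sit on the equatorial band at azimuths equally spaced within
    [-60°, +60°], venules within [120°, 240°]; the default is a single
    20-µm arteriole at 0° opposite a single 20-µm venule at 180°.
    """

    n_arterioles: int = 1
    d_arteriole: float = DEFAULT_PORT_DIAMETER_UM
    n_venules: int = 1
    d_venule: float = DEFAULT_PORT_DIAMETER_UM
    arteriole_azimuths: tuple = (0.0,)    # degrees; one entry per cluster
    venule_azimuths: tuple = (180.0,)

    def __post_init__(self):
        if not (1 <= self.n_arterioles <= 5 and 1 <= self.n_venules <= 5):
            raise InvalidGeometryError("vessel counts must be in 1..5")
        if self.d_arteriole <= 0 or self.d_venule <= 0:
            raise InvalidGeometryError("vessel diameters must be positive")

    @property
    def arteriolar_area(self) -> float:
        """Total arteriolar lumen cross-sectional area A (µm²)."""
        return self.n_arterioles * math.pi * (0.5 * self.d_arteriole) ** 2


@dataclass(frozen=True)
class PortRecord:
    """One arteriole or venule attachment site on the sheet."""

    kind: str                    # {"arteriole", "venule"}
    diameter: float              # µm, lumen diameter
    center: np.ndarray           # unit direction of the port center
    angular_radius: float        # radians, hole half-angle on the mid-surface
    label: str

    @property
    def lumen_area_um2(self) -> float:
        return math.pi * (0.5 * self.diameter) ** 2


@dataclass
class MorphometricReport:
    """Derived morphometrics of the alveolus and its capillary sheet."""

    alveolus_volume: float | None = None           # µm³
    alveolus_depth: float | None = None            # µm
    mouth_area: float | None = None                # µm²
    lateral_area: float | None = None              # µm² (pore holes subtracted)
    capillary_volume: float | None = None          # µm³
    capillary_surface_total: float | None = None   # µm²
    capillary_surface_gas_exchange: float | None = None  # µm²

    def __post_init__(self):
        for name, v in vars(self).items():
            if v is not None and v < 0:
                raise InvalidGeometryError(f"{name} must be >= 0")
        if (self.capillary_surface_total is not None
                and self.capillary_surface_gas_exchange is not None
                and self.capillary_surface_gas_exchange
                > self.capillary_surface_total * (1 + 1e-12)):
            raise InvalidGeometryError(
                "gas-exchange surface cannot exceed total capillary surface")


# ---------------------------------------------------------------------------
# closed-form base construction
# ---------------------------------------------------------------------------

def solve_base_from_diameter(d_alv: float, d_mouth: float) -> AlveolarBase:
    """Truncate a sphere of diameter ``d_alv`` at a mouth of diameter ``d_mouth``."""
    if d_mouth > d_alv:
        raise InvalidGeometryError("mouth diameter must not exceed alveolus diameter")
    R = 0.5 * d_alv
    a = 0.5 * d_mouth
    z_m = math.sqrt(max(0.0, R * R - a * a))
    return AlveolarBase(sphere_radius=R, mouth_radius=a,
                        mouth_plane_offset=z_m, depth=R + z_m)


def solve_base_from_volume(V_alv: float, d_mouth: float,
                           rtol: float = 1e-10) -> AlveolarBase:
    """Find the sphere radius whose truncated segment has volume ``V_alv``.

    The segment volume V(R) = (π/3)·depth²·(3R − depth) with
    depth = R + sqrt(R² − a²) increases monotonically with R for fixed mouth
    radius a, so a bracketed scalar root solve applies.
    """
    a = 0.5 * d_mouth
    v_min = 2.0 * math.pi * a ** 3 / 3.0  # hemisphere of the mouth radius (R = a)
    if V_alv <= v_min:
        raise NoSolutionError(
            f"volume {V_alv:g} below the attainable minimum {v_min:g}")

    def f(R: float) -> float:
        return solve_base_from_diameter(2 * R, d_mouth).segment_volume() - V_alv

    R_hi = max(a * 2.0, (3.0 * V_alv / (4.0 * math.pi)) ** (1.0 / 3.0) * 2.0)
    while f(R_hi) < 0:
        R_hi *= 2.0
        if R_hi > 1e9:
            raise NoSolutionError("volume outside attainable range")
    R = brentq(f, a, R_hi, xtol=1e-12, rtol=rtol)
    return solve_base_from_diameter(2 * R, d_mouth)


def segment_morphometrics(base: AlveolarBase,
                          pores: PoreSet | None = None) -> MorphometricReport:
    """Analytic morphometrics of the truncated-sphere base.

    ``lateral_area`` subtracts the plan areas of the pores of Kohn.
    """
    pore_area = 0.0
    if pores is not None and len(pores) > 0:
        pore_area = len(pores) * math.pi * (0.5 * pores.pore_diameter) ** 2
    lateral = base.lateral_area() - pore_area
    if lateral <= 0:
        raise InvalidGeometryError("pores exceed the available lateral area")
    return MorphometricReport(
        alveolus_volume=base.segment_volume(),
        alveolus_depth=base.depth,
        mouth_area=base.mouth_area(),
        lateral_area=lateral,
    )


# ---------------------------------------------------------------------------
# pillar lattice
# ---------------------------------------------------------------------------

def build_pillar_lattice(params: MorphoParams, lattice_type: str = "square",
                         reference_area: float | None = None) -> PillarLattice:
    """Homogenize the pillar array into pitch + area fraction φ.

    The pitch is interpillar distance + pillar diameter (the literature
    reports the clear gap between pillars).  For a square lattice
    φ = (π/4)·d_p²/pitch²; hexagonal packing uses π/(2√3) instead.
    """
    if params.interpillar_distance <= 0:
        raise InvalidGeometryError("interpillar distance must be positive")
    pitch = params.interpillar_distance + params.pillar_diameter
    ratio = params.pillar_diameter / pitch
    if lattice_type == "square":
        phi = (math.pi / 4.0) * ratio ** 2
    elif lattice_type == "hexagonal":
        phi = (math.pi / (2.0 * math.sqrt(3.0))) * ratio ** 2
    else:
        raise InvalidGeometryError(f"unknown lattice type {lattice_type!r}")
    if phi >= 0.5:
        raise InvalidGeometryError(f"pillar area fraction {phi:.3f} >= 0.5")
    count = None
    if reference_area is not None and params.pillar_diameter > 0:
        count = phi * reference_area / (math.pi * (0.5 * params.pillar_diameter) ** 2)
    return PillarLattice(lattice_type=lattice_type, pitch=pitch,
                         pillar_diameter=params.pillar_diameter,
                         area_fraction=phi, pillar_count_estimate=count)


# ---------------------------------------------------------------------------
# random pore placement and port placement
# ---------------------------------------------------------------------------

def place_ports(base: AlveolarBase, config: ConnectivityConfig,
                mid_surface_radius: float | None = None) -> list[PortRecord]:
    """Place arteriole/venule ports on the equatorial band of the closed part.

    The default arteriole sits on the sphere equator at azimuth 0°, the
    default venule opposite at 180°.  Multiple vessels of one type form a
    compact cluster stacked along the meridian of their azimuth (polar
    offsets symmetric about the equator), so that every arteriole stays
    roughly antipodal to every venule and the inflow has to traverse the
    capillary sheet; spreading the vessels in azimuth instead lets adjacent
    arteriole-venule pairs short-circuit around the rim.
    """
    R_mid = mid_surface_radius if mid_surface_radius is not None else base.sphere_radius
    records: list[PortRecord] = []
    specs = ([("arteriole", config.d_arteriole, config.n_arterioles,
               config.arteriole_azimuths)]
             + [("venule", config.d_venule, config.n_venules,
                 config.venule_azimuths)])
    i = 0
    for kind, d, n, azimuths in specs:
        if d >= 2 * R_mid:
            raise InvalidGeometryError("port diameter exceeds the sphere")
        alpha = math.asin(0.5 * d / R_mid)
        if len(azimuths) == n:
            placements = [(math.radians(az), 0.5 * math.pi) for az in azimuths]
        elif len(azimuths) == 1:
            # meridional stack: polar offsets symmetric about the equator
            step = 2.8 * alpha
            polar = [0.5 * math.pi + (k - 0.5 * (n - 1)) * step for k in range(n)]
            placements = [(math.radians(azimuths[0]), th) for th in polar]
        else:
            raise InvalidGeometryError(
                f"{kind} azimuths must have length 1 or n_{kind}s")
        for phi, theta in placements:
            center = np.array([math.sin(theta) * math.cos(phi),
                               math.sin(theta) * math.sin(phi),
                               math.cos(theta)])
            records.append(PortRecord(kind=kind, diameter=d, center=center,
                                      angular_radius=alpha, label=f"port_{i}"))
            i += 1
    # pairwise disjoint discs
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            sep = _angle_between(records[i].center, records[j].center)
            if sep <= records[i].angular_radius + records[j].angular_radius:
                raise InvalidGeometryError(
                    f"ports {records[i].label} and {records[j].label} overlap")
    # ports must stay clear of the mouth rim
    for r in records:
        polar = _angle_between(r.center, np.array([0.0, 0.0, 1.0]))
        if polar - r.angular_radius <= base.mouth_cap_angle:
            raise InvalidGeometryError(f"port {r.label} intersects the mouth rim")
    return records


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    return math.acos(float(np.clip(np.dot(u, v), -1.0, 1.0)))


def place_pores(base: AlveolarBase, n: int, d: float, seed: int,
                exclusions: list[PortRecord] | None = None,
                max_attempts_per_pore: int = 2000) -> PoreSet:
    """Rejection-sample ``n`` non-overlapping pore discs on the closed surface.

    Pores avoid the mouth rim and a buffer of one port radius around every
    port.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    alpha = math.asin(min(1.0, 0.5 * d / base.sphere_radius))
    theta_rim = base.mouth_cap_angle
    # pore disc fully below the mouth rim, small extra margin for clean meshing
    margin = 0.15 * alpha
    z_max = math.cos(theta_rim + alpha + margin)
    excl: list[tuple[np.ndarray, float]] = []
    for p in (exclusions or []):
        # buffer of one extra port radius between vessel and pore rims
        excl.append((p.center, 2.0 * p.angular_radius + alpha + margin))
    centers: list[np.ndarray] = []
    attempts = 0
    budget = max(1, n) * max_attempts_per_pore
    while len(centers) < n:
        attempts += 1
        if attempts > budget:
            raise PlacementError(
                f"placed {len(centers)}/{n} pores in {budget} attempts")
        z = rng.uniform(-1.0, z_max)
        phi = rng.uniform(0.0, 2.0 * math.pi)
        s = math.sqrt(1.0 - z * z)
        c = np.array([s * math.cos(phi), s * math.sin(phi), z])
        if any(_angle_between(c, e) <= r for e, r in excl):
            continue
        if any(_angle_between(c, o) <= 2.0 * alpha + margin for o in centers):
            continue
        centers.append(c)
    arr = np.array(centers) if centers else np.zeros((0, 3))
    return PoreSet(centers=arr, pore_diameter=d, seed=seed)


# ---------------------------------------------------------------------------
# triangulated mid-surface
# ---------------------------------------------------------------------------

@dataclass
class SheetDomain:
    """Triangulated capillary mid-surface with labeled holes.

    Vertices are in µm.  ``boundary_loops`` maps hole labels
    ({"mouth", "pore_i", "port_j"}) to the vertex indices on that rim.
    """

    vertices: np.ndarray                 # (nv, 3) µm
    faces: np.ndarray                    # (nf, 3) int
    base: AlveolarBase | None
    sheet_height: float                  # µm
    mid_surface_radius: float | None     # µm (None for planar domains)
    ports: list[PortRecord]
    pores: PoreSet | None
    lattice: PillarLattice | None
    boundary_loops: dict[str, np.ndarray]
    boundary_edges: np.ndarray           # (ne, 2) int
    mesh_stats: dict = field(default_factory=dict)

    # -- derived quantities ------------------------------------------------
    @property
    def face_areas(self) -> np.ndarray:
        """Per-triangle area (µm²)."""
        v = self.vertices
        f = self.faces
        cr = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.sqrt((cr * cr).sum(axis=1))

    @property
    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def total_area(self) -> float:
        return float(self.face_areas.sum())

    def analytic_area(self) -> float:
        """Spherical-cap oracle for the carved mid-surface area (µm²)."""
        if self.base is None or self.mid_surface_radius is None:
            raise InvalidGeometryError("analytic area requires a spherical base")
        R = self.mid_surface_radius
        area = 2.0 * math.pi * R * R * (1.0 + math.cos(self.base.mouth_cap_angle))
        alphas = [p.angular_radius for p in self.ports]
        if self.pores is not None and len(self.pores) > 0:
            alphas += [self.pores.angular_radius(self.base.sphere_radius)] * len(self.pores)
        for al in alphas:
            area -= 2.0 * math.pi * R * R * (1.0 - math.cos(al))
        return area

    def port_rim_edges(self, label: str) -> np.ndarray:
        """Boundary edges whose endpoints both lie on the given rim."""
        rim = set(int(i) for i in self.boundary_loops[label])
        mask = [(int(e[0]) in rim and int(e[1]) in rim) for e in self.boundary_edges]
        return self.boundary_edges[np.array(mask, dtype=bool)]

    def ports_by_kind(self, kind: str) -> list[PortRecord]:
        return [p for p in self.ports if p.kind == kind]


def _subdivisions_for_edge(radius: float, target_edge: float) -> int:
    # small slack so a target sitting exactly on a subdivision level does not
    # round up to the next (4x denser) level
    n = math.ceil(math.log2(_ICO_EDGE_RAD * radius / (1.001 * target_edge)))
    return max(2, n)


def _boundary_edges_of(faces: np.ndarray) -> np.ndarray:
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges_sorted = np.sort(edges, axis=1)
    uniq, counts = np.unique(edges_sorted, axis=0, return_counts=True)
    return uniq[counts == 1]


def build_sheet_midsurface(base: AlveolarBase,
                           pores: PoreSet | None,
                           ports: list[PortRecord],
                           target_edge_length: float,
                           sheet_height: float,
                           lattice: PillarLattice | None = None,
                           offset: float | None = None,
                           smooth_iters: int = 8) -> SheetDomain:
    """Triangulate the capillary mid-surface with mouth/pore/port holes.

    The mid-surface is a sphere offset outward from the alveolar base by
    ``offset`` (default h/2).  An icosphere at the requested resolution is
    carved: vertices near each hole rim are snapped onto the rim circle and
    triangles inside the hole are removed, then interior vertices are
    relaxed by a few rounds of Laplacian smoothing (rim vertices fixed).
    """
    if target_edge_length <= 0:
        raise MeshingError("target edge length must be positive")
    if pores is not None and len(pores) > 0 and target_edge_length > pores.pore_diameter / 3.0:
        raise MeshingError(
            "target edge length must be <= pore_diameter/3 to resolve the pores")
    off = 0.5 * sheet_height if offset is None else offset
    R_mid = base.sphere_radius + off

    n_sub = _subdivisions_for_edge(R_mid, target_edge_length)
    ico = trimesh.creation.icosphere(subdivisions=n_sub, radius=1.0)
    verts = np.asarray(ico.vertices, dtype=float).copy()
    faces = np.asarray(ico.faces, dtype=np.int64).copy()
    edge_ang = _ICO_EDGE_RAD / (2 ** n_sub)

    caps: list[tuple[np.ndarray, float, str]] = [
        (np.array([0.0, 0.0, 1.0]), base.mouth_cap_angle, "mouth")]
    if pores is not None and len(pores) > 0:
        al = pores.angular_radius(base.sphere_radius)
        for i, c in enumerate(pores.centers):
            caps.append((np.asarray(c, dtype=float), al, f"pore_{i}"))
    for p in ports:
        caps.append((np.asarray(p.center, dtype=float), p.angular_radius, p.label))

    # a hole needs roughly three edges across its diameter to be carved
    for _, alpha, label in caps:
        if alpha < 1.45 * edge_ang and label != "mouth":
            raise MeshingError(
                f"hole {label} too small for the requested resolution")

    snap_band = 0.45 * edge_ang
    vertex_cap = np.full(len(verts), -1, dtype=np.int64)
    for k, (center, alpha, _) in enumerate(caps):
        cosang = np.clip(verts @ center, -1.0, 1.0)
        ang = np.arccos(cosang)
        band = np.abs(ang - alpha) < snap_band
        if not band.any():
            continue
        v = verts[band]
        ca = cosang[band][:, None]
        sa = np.sin(ang[band])[:, None]
        tangent = (v - ca * center) / np.where(sa < 1e-15, 1.0, sa)
        verts[band] = math.cos(alpha) * center + math.sin(alpha) * tangent
        vertex_cap[band] = k

    # remove faces inside any cap
    keep = np.ones(len(faces), dtype=bool)
    centroids = verts[faces].mean(axis=1)
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    for k, (center, alpha, _) in enumerate(caps):
        ang_v = np.arccos(np.clip(verts @ center, -1.0, 1.0))
        deep_v = ang_v < alpha - 1e-9
        ang_c = np.arccos(np.clip(centroids @ center, -1.0, 1.0))
        inside = deep_v[faces].any(axis=1) | (ang_c < alpha - 1e-9)
        keep &= ~inside
    faces = faces[keep]
    if len(faces) == 0:
        raise MeshingError("carving removed the entire surface")

    # drop unreferenced vertices
    used = np.unique(faces)
    remap = -np.ones(len(verts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    verts = verts[used]
    vertex_cap = vertex_cap[used]
    faces = remap[faces]

    bedges = _boundary_edges_of(faces)
    boundary_vertices = np.unique(bedges)

    # Laplacian relaxation of interior vertices on the unit sphere
    if smooth_iters > 0 and len(verts) > 0:
        import scipy.sparse as sp
        e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
        e = np.unique(np.sort(e, axis=1), axis=0)
        nv = len(verts)
        adj = sp.coo_matrix(
            (np.ones(2 * len(e)),
             (np.concatenate([e[:, 0], e[:, 1]]), np.concatenate([e[:, 1], e[:, 0]]))),
            shape=(nv, nv)).tocsr()
        deg = np.asarray(adj.sum(axis=1)).ravel()
        deg[deg == 0] = 1.0
        interior = np.ones(nv, dtype=bool)
        interior[boundary_vertices] = False
        for _ in range(smooth_iters):
            mean_nb = adj @ verts / deg[:, None]
            upd = 0.5 * verts + 0.5 * mean_nb
            upd /= np.linalg.norm(upd, axis=1, keepdims=True)
            verts[interior] = upd[interior]

    # group boundary vertices into labeled rims via their snapped cap
    loops: dict[str, np.ndarray] = {}
    for k, (_, _, label) in enumerate(caps):
        members = np.where(vertex_cap == k)[0]
        members = members[np.isin(members, boundary_vertices)]
        if len(members) > 0:
            loops[label] = members
    # any boundary vertex not snapped (should not happen) -> nearest cap rim
    unlabeled = boundary_vertices[vertex_cap[boundary_vertices] < 0]
    if len(unlabeled) > 0:
        cap_centers = np.array([c for c, _, _ in caps])
        cap_alpha = np.array([a for _, a, _ in caps])
        ang = np.arccos(np.clip(verts[unlabeled] @ cap_centers.T, -1, 1))
        nearest = np.argmin(np.abs(ang - cap_alpha[None, :]), axis=1)
        for k in np.unique(nearest):
            label = caps[k][2]
            extra = unlabeled[nearest == k]
            loops[label] = (np.concatenate([loops[label], extra])
                            if label in loops else extra)

    missing = [lbl for _, _, lbl in caps if lbl not in loops]
    if missing:
        raise MeshingError(f"holes not realized in the mesh: {missing}")

    verts_um = verts * R_mid
    areas = _triangle_areas(verts_um, faces)
    stats = _mesh_quality(verts_um, faces)
    stats.update(n_vertices=len(verts_um), n_faces=len(faces),
                 subdivisions=n_sub, target_edge_length=target_edge_length)
    domain = SheetDomain(
        vertices=verts_um, faces=faces, base=base, sheet_height=sheet_height,
        mid_surface_radius=R_mid, ports=list(ports), pores=pores,
        lattice=lattice, boundary_loops=loops, boundary_edges=bedges,
        mesh_stats=stats)
    if areas.min() <= 0:
        raise MeshingError("degenerate triangle produced during carving")
    return domain


def _triangle_areas(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    cr = np.cross(verts[faces[:, 1]] - verts[faces[:, 0]],
                  verts[faces[:, 2]] - verts[faces[:, 0]])
    return 0.5 * np.sqrt((cr * cr).sum(axis=1))


def _mesh_quality(verts: np.ndarray, faces: np.ndarray) -> dict:
    p0, p1, p2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    e0 = np.linalg.norm(p1 - p0, axis=1)
    e1 = np.linalg.norm(p2 - p1, axis=1)
    e2 = np.linalg.norm(p0 - p2, axis=1)
    lengths = np.stack([e0, e1, e2], axis=1)
    areas = _triangle_areas(verts, faces)
    with np.errstate(invalid="ignore"):
        # min angle per face from the law of cosines
        def ang(a, b, c):
            return np.arccos(np.clip((a * a + b * b - c * c) / (2 * a * b), -1, 1))
        angles = np.stack([ang(e0, e2, e1), ang(e0, e1, e2), ang(e1, e2, e0)], axis=1)
    aspect = lengths.max(axis=1) * lengths.sum(axis=1) / (4.0 * np.sqrt(3.0) * areas + 1e-300)
    return {
        "min_angle_deg": float(np.degrees(angles.min())),
        "max_aspect": float(aspect.max()),
        "median_edge_um": float(np.median(lengths)),
    }


def acn_morphometrics(domain: SheetDomain, lattice: PillarLattice,
                      h: float | None = None) -> MorphometricReport:
    """Table-style morphometrics of the capillary sheet.

    ``open_area`` is the analytic lateral area of the base with the pore
    discs subtracted; the sheet volume is open_area·h·(1−φ), the total
    endothelial surface counts both layers plus the pillar walls, and the
    gas-exchange surface is the inner layer alone.
    """
    if domain.base is None:
        raise InvalidGeometryError("morphometrics require a spherical base")
    h = domain.sheet_height if h is None else h
    seg = segment_morphometrics(domain.base, domain.pores)
    open_area = seg.lateral_area
    phi = lattice.area_fraction
    n_pillars = lattice.pillar_count_estimate
    if n_pillars is None:
        if lattice.pillar_diameter > 0:
            n_pillars = phi * open_area / (math.pi * (0.5 * lattice.pillar_diameter) ** 2)
        else:
            n_pillars = 0.0
    pillar_wall = n_pillars * math.pi * lattice.pillar_diameter * h
    return MorphometricReport(
        alveolus_volume=seg.alveolus_volume,
        alveolus_depth=seg.alveolus_depth,
        mouth_area=seg.mouth_area,
        lateral_area=open_area,
        capillary_volume=open_area * h * (1.0 - phi),
        capillary_surface_total=2.0 * open_area * (1.0 - phi) + pillar_wall,
        capillary_surface_gas_exchange=open_area * (1.0 - phi),
    )


# ---------------------------------------------------------------------------
# mirroring and planar benchmark domain
# ---------------------------------------------------------------------------

def mirror_pores(pores: PoreSet) -> PoreSet:
    """Reflect the pore pattern through the x-z plane."""
    centers = pores.centers.copy()
    if len(centers):
        centers[:, 1] = -centers[:, 1]
    return replace(pores, centers=centers)


def mirror_domain(domain: SheetDomain) -> SheetDomain:
    """Exact mirror image of a sheet domain (reflection y -> -y).

    Face winding is flipped so outward orientation is preserved; triangle
    areas are bitwise identical to the original's.
    """
    verts = domain.vertices.copy()
    verts[:, 1] = -verts[:, 1]
    faces = domain.faces[:, [0, 2, 1]].copy()
    ports = [replace(p, center=np.array([p.center[0], -p.center[1], p.center[2]]))
             for p in domain.ports]
    pores = mirror_pores(domain.pores) if domain.pores is not None else None
    bedges = _boundary_edges_of(faces)
    return SheetDomain(
        vertices=verts, faces=faces, base=domain.base,
        sheet_height=domain.sheet_height,
        mid_surface_radius=domain.mid_surface_radius, ports=ports, pores=pores,
        lattice=domain.lattice,
        boundary_loops={k: v.copy() for k, v in domain.boundary_loops.items()},
        boundary_edges=bedges, mesh_stats=dict(domain.mesh_stats))


def make_strip_domain(width: float, length: float, sheet_height: float,
                      target_edge_length: float) -> SheetDomain:
    """Flat rectangular strip with an inlet edge (x=0) and outlet edge (x=L).

    Benchmark domain for the plane-Poiseuille closed form.  The inlet edge is
    labeled ``port_0`` (arteriole) and the outlet edge ``port_1`` (venule).
    """
    nx = max(2, int(round(length / target_edge_length)) + 1)
    ny = max(2, int(round(width / target_edge_length)) + 1)
    x = np.linspace(0.0, length, nx)
    y = np.linspace(0.0, width, ny)
    X, Y = np.meshgrid(x, y, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(nx * ny)])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            v00 = i * ny + j
            v01 = v00 + 1
            v10 = v00 + ny
            v11 = v10 + 1
            faces.append([v00, v10, v11])
            faces.append([v00, v11, v01])
    faces = np.array(faces, dtype=np.int64)
    inlet = np.arange(ny)
    outlet = np.arange((nx - 1) * ny, nx * ny)
    ports = [
        PortRecord(kind="arteriole", diameter=width, center=np.array([1.0, 0, 0]),
                   angular_radius=0.0, label="port_0"),
        PortRecord(kind="venule", diameter=width, center=np.array([-1.0, 0, 0]),
                   angular_radius=0.0, label="port_1"),
    ]
    bedges = _boundary_edges_of(faces)
    return SheetDomain(
        vertices=verts, faces=faces, base=None, sheet_height=sheet_height,
        mid_surface_radius=None, ports=ports, pores=None, lattice=None,
        boundary_loops={"port_0": inlet, "port_1": outlet},
        boundary_edges=bedges,
        mesh_stats={"n_vertices": len(verts), "n_faces": len(faces)})
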