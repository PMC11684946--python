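"""Artifact export: STL / legacy VTK / JSON results and run manifests.

STL is unitless; all geometry exports are in micrometers, which the run
manifest records alongside checksums of every written artifact.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .geometry import SheetDomain


def export_stl(domain: SheetDomain, path) -> Path:
    """Binary STL of the mid-surface (coordinates in µm)."""
    import trimesh
    mesh = trimesh.Trimesh(vertices=domain.vertices, faces=domain.faces,
                           process=False)
    path = Path(path)
    mesh.export(path)
    return path


def export_shell_stl(domain: SheetDomain, path) -> Path:
    """Two-layer shell (inner/outer endothelial surfaces) for visualization."""
    import trimesh
    if domain.mid_surface_radius is None:
        raise ValueError("shell export requires a spherical domain")
    h2 = 0.5 * domain.sheet_height
    r = np.linalg.norm(domain.vertices, axis=1, keepdims=True)
    dirs = domain.vertices / r
    inner = domain.vertices - dirs * h2
    outer = domain.vertices + dirs * h2
    nv = len(domain.vertices)
    verts = np.vstack([inner, outer])
    faces = np.vstack([domain.faces[:, ::-1], domain.faces + nv])
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    path = Path(path)
    mesh.export(path)
    return path


def write_vtk(domain: SheetDomain, path, point_data: dict | None = None,
              cell_data: dict | None = None, comment: str = "alveoflow field output") -> Path:
    """Legacy ASCII VTK (POLYDATA) writer for the triangulated surface."""
    path = Path(path)
    v = domain.vertices
    f = domain.faces
    lines = ["# vtk DataFile Version 3.0", comment, "ASCII", "DATASET POLYDATA",
             f"POINTS {len(v)} double"]
    lines += [f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in v]
    lines.append(f"POLYGONS {len(f)} {4 * len(f)}")
    lines += [f"3 {a} {b} {c}" for a, b, c in f]

    def emit(data: dict, head: str, count: int):
        lines.append(f"{head} {count}")
        for name, arr in data.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{x:.9g}" for x in arr)
            else:
                lines.append(f"VECTORS {name} double")
                lines.extend(f"{a:.9g} {b:.9g} {c:.9g}" for a, b, c in arr)

    if point_data:
        emit(point_data, "POINT_DATA", len(v))
    if cell_data:
        emit(cell_data, "CELL_DATA", len(f))
    path.write_text("\n".join(lines) + "\n")
    return path


def write_flow_vtk(domain: SheetDomain, solution, path) -> Path:
    """Pressure / velocity / shear-rate fields in legacy VTK."""
    return write_vtk(
        domain, path,
        point_data={"pressure_Pa": solution.pressure},
        cell_data={"velocity_m_s": solution.velocity,
                   "shear_rate_1_s": solution.shear_rate})


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path, config: dict, artifacts: list, seeds: dict | None = None) -> Path:
    """Run manifest: config snapshot, package version, seeds, checksums."""
    from . import __version__
    path = Path(path)
    manifest = {
        "package": "alveoflow",
        "version": __version__,
        "units": {"length": "um", "velocity_report": "mm/s",
                  "pressure_report": "mmHg", "internal": "SI"},
        "config": config,
        "seeds": seeds or {},
        "artifacts": [{"path": str(Path(a).name), "sha256": sha256_of(a)}
                      for a in artifacts],
    }
    path.write_text(json.dumps(manifest, indent=2, default=_json_default) + "\n")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
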