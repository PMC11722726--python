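"""Mesh export/import, manifest writing and YAML config parsing.

Writers are deterministic: fixed field ordering, fixed float formatting and
no timestamps, so identical inputs give byte-identical files.  Supported
formats: binary little-endian STL, OBJ, ASCII PLY and legacy VTK polydata.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import EllipseSection, TriMesh
from .lv import LVProfile

FORMATS = ("stl", "obj", "ply", "vtk")

_STL_HEADER = b"cardiosynth binary STL".ljust(80, b"\0")


def export_mesh(mesh: TriMesh, path, fmt: str | None = None) -> Path:
    """Write a mesh to ``path``; the format defaults to the file suffix."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in FORMATS:
        raise ValueError(f"unknown mesh format {fmt!r}; expected one of {FORMATS}")
    if mesh.n_faces == 0 or mesh.n_vertices == 0:
        raise ValueError("refusing to export an empty mesh")
    writer = {"stl": _write_stl, "obj": _write_obj, "ply": _write_ply, "vtk": _write_vtk}[fmt]
    writer(mesh, path)
    return path


def _write_stl(mesh: TriMesh, path: Path) -> None:
    tri = mesh.vertices[mesh.faces].astype("<f4")
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]).astype("<f8")
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    normals = (normals / norms).astype("<f4")
    with open(path, "wb") as fh:
        fh.write(_STL_HEADER)
        fh.write(struct.pack("<I", mesh.n_faces))
        record = np.zeros(mesh.n_faces, dtype=[("n", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")])
        record["n"] = normals
        record["v"] = tri
        fh.write(record.tobytes())


def _write_obj(mesh: TriMesh, path: Path) -> None:
    lines = [f"v {x:.9g} {y:.9g} {z:.9g}" for x, y, z in mesh.vertices]
    lines += [f"f {a + 1} {b + 1} {c + 1}" for a, b, c in mesh.faces]
    path.write_text("\n".join(lines) + "\n")


def _write_ply(mesh: TriMesh, path: Path) -> None:
    header = [
        "ply",
        "format ascii 1.0",
        f"element vertex {mesh.n_vertices}",
        "property double x",
        "property double y",
        "property double z",
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    body = [f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in mesh.vertices]
    body += [f"3 {a} {b} {c}" for a, b, c in mesh.faces]
    path.write_text("\n".join(header + body) + "\n")


def _write_vtk(mesh: TriMesh, path: Path) -> None:
    lines = [
        "# vtk DataFile Version 3.0",
        "cardiosynth surface mesh",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {mesh.n_vertices} double",
    ]
    lines += [f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in mesh.vertices]
    lines.append(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}")
    lines += [f"3 {a} {b} {c}" for a, b, c in mesh.faces]
    path.write_text("\n".join(lines) + "\n")


def load_mesh(path) -> TriMesh:
    """Read a mesh back into a TriMesh (our VTK writer's layout, or any
    trimesh-supported format for STL/OBJ/PLY)."""
    path = Path(path)
    if path.suffix.lower() == ".vtk":
        return _read_vtk(path)
    import trimesh  # deferred: only needed when importing foreign meshes

    tm = trimesh.load(str(path), force="mesh", process=True)
    return TriMesh(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces, dtype=np.int64))


def _read_vtk(path: Path) -> TriMesh:
    tokens = path.read_text().split()
    i = tokens.index("POINTS")
    n = int(tokens[i + 1])
    coords = np.array(tokens[i + 3 : i + 3 + 3 * n], dtype=float).reshape(n, 3)
    j = tokens.index("POLYGONS")
    m = int(tokens[j + 1])
    body = np.array(tokens[j + 3 : j + 3 + 4 * m], dtype=np.int64).reshape(m, 4)
    return TriMesh(coords, body[:, 1:])


def write_manifest(manifest: pd.DataFrame, path) -> Path:
    """Write a cohort manifest CSV deterministically (fixed column order,
    '%.6g' floats, LF line endings)."""
    if len(manifest) == 0:
        raise ValueError("refusing to write an empty manifest")
    path = Path(path)
    manifest.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")
    return path


def profile_from_yaml(path) -> LVProfile:
    """Load an LVProfile from YAML: ``height``, ``wall_offset`` and a
    ``sections`` list of {z, cx, cy, ax, ay} mappings."""
    data = yaml.safe_load(Path(path).read_text())
    sections = [
        EllipseSection(
            z=float(s["z"]),
            cx=float(s.get("cx", 0.0)),
            cy=float(s.get("cy", 0.0)),
            ax=float(s["ax"]),
            ay=float(s.get("ay", s["ax"])),
        )
        for s in data["sections"]
    ]
    return LVProfile(sections=sections, height=float(data["height"]), wall_offset=float(data.get("wall_offset", 10.0)))


def profile_to_yaml(profile: LVProfile, path) -> Path:
    data = {
        "height": float(profile.height),
        "wall_offset": float(profile.wall_offset),
        "sections": [
            {"z": float(s.z), "cx": float(s.cx), "cy": float(s.cy), "ax": float(s.ax), "ay": float(s.ay)}
            for s in profile.sections
        ],
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path


def write_run_manifest(path, config: dict) -> Path:
    """Record the full run configuration (command, parameters, seed, package
    version) next to the generated artifacts."""
    from . import __version__

    payload = {"package": "cardiosynth", "version": __version__, **config}
    path = Path(path)
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path
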