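"""Left-ventricle construction by lofting control ellipses.

The ventricle is defined by an ordered stack of control ellipses along the
long axis (+Z, base at z = 0, apex at z = height).  Lofting the stack gives
the inner (endocardial) shell; offsetting every section radially by the wall
offset and lofting again gives the outer shell; the wall is the region
between them and the inner shell encloses the fluid cavity.

The shipped default profile uses circular sections at 10 mm spacing with
inner radii chosen so that, with the 10 mm wall offset, the outer shell
spans radii 21-37.5 mm at a height of 80 mm and the cavity volume lies in
the physiological 108-140 mL window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    EllipseSection,
    MeshMetrics,
    TriMesh,
    loft_ellipses,
    mesh_metrics,
    mesh_volume,
    points_to_surface_distance,
)

DEFAULT_WALL_OFFSET = 10.0  # mm, radial offset of the outer shell
DEFAULT_INNER_RADII = (11.0, 19.0, 24.0, 27.0, 27.5, 25.5, 22.0, 17.0, 11.0)
DEFAULT_HEIGHT = 80.0  # mm


@dataclass
class LVProfile:
    """Ordered control-ellipse stack (base -> apex) plus the wall-offset rule."""

    sections: list
    height: float
    wall_offset: float = DEFAULT_WALL_OFFSET

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("height must be positive")
        if self.wall_offset <= 0:
            raise ValueError("wall_offset must be positive")
        z = np.array([s.z for s in self.sections], dtype=float)
        if len(z) < 2 or np.any(np.diff(z) <= 0):
            raise ValueError("sections must be strictly increasing in z")
        if abs(z[0]) > 1e-9 or abs(z[-1] - self.height) > 1e-9:
            raise ValueError("sections must span [0, height]")

    def with_height(self, height: float) -> "LVProfile":
        """Affine z-rescale to a new height; radii unchanged."""
        if height <= 0:
            raise ValueError("height must be positive")
        sections = [replace(s, z=(s.z / self.height) * height) for s in self.sections]
        return LVProfile(sections=sections, height=height, wall_offset=self.wall_offset)

    def with_wall_offset(self, offset: float) -> "LVProfile":
        return LVProfile(sections=[replace(s) for s in self.sections], height=self.height, wall_offset=offset)

    def edited(self, edits: dict) -> "LVProfile":
        """Apply per-section edits ``{index: (cx_shift_mm, radius_scale)}``."""
        sections = [replace(s) for s in self.sections]
        for idx, (shift, scale) in edits.items():
            s = sections[idx]
            if scale <= 0:
                raise ValueError("radius scale must be positive")
            sections[idx] = replace(s, cx=s.cx + shift, ax=s.ax * scale, ay=s.ay * scale)
        return LVProfile(sections=sections, height=self.height, wall_offset=self.wall_offset)

    def resampled(self, n_rings: int) -> "LVProfile":
        """Linearly interpolate the section parameters onto ``n_rings`` evenly
        spaced z-stations (the original knots stay on piecewise-linear paths)."""
        z_old = np.array([s.z for s in self.sections])
        z_new = np.linspace(0.0, self.height, n_rings)
        interp = {
            name: np.interp(z_new, z_old, np.array([getattr(s, name) for s in self.sections]))
            for name in ("cx", "cy", "ax", "ay")
        }
        sections = [
            EllipseSection(z=z_new[i], cx=interp["cx"][i], cy=interp["cy"][i], ax=interp["ax"][i], ay=interp["ay"][i])
            for i in range(n_rings)
        ]
        return LVProfile(sections=sections, height=self.height, wall_offset=self.wall_offset)

    def outer_sections(self) -> list:
        return [replace(s, ax=s.ax + self.wall_offset, ay=s.ay + self.wall_offset) for s in self.sections]


def default_profile() -> LVProfile:
    """Default (model 0) profile: circular sections every 10 mm, height 80 mm,
    inner radii 11..27.5..11 mm, wall offset 10 mm -> outer radii 21..37.5 mm."""
    z = np.arange(0.0, 81.0, 10.0)
    sections = [EllipseSection(z=zi, ax=r, ay=r) for zi, r in zip(z, DEFAULT_INNER_RADII)]
    return LVProfile(sections=sections, height=DEFAULT_HEIGHT, wall_offset=DEFAULT_WALL_OFFSET)


@dataclass
class LVModel:
    """Inner and outer shells of one left-ventricle geometry."""

    inner: TriMesh
    outer: TriMesh
    profile: LVProfile
    model_id: str = "lv"


@dataclass
class LVMeasurements:
    """Per-model measured dimensions (mm / mL), mirroring the manifest columns."""

    height: float
    thickness_min: float
    thickness_max: float
    thickness_avg: float
    radius_min: float
    radius_max: float
    radius_avg: float
    cavity_volume_ml: float

    def as_dict(self) -> dict:
        return {
            "height_mm": self.height,
            "thickness_min_mm": self.thickness_min,
            "thickness_max_mm": self.thickness_max,
            "thickness_avg_mm": self.thickness_avg,
            "radius_min_mm": self.radius_min,
            "radius_max_mm": self.radius_max,
            "radius_avg_mm": self.radius_avg,
            "cavity_volume_ml": self.cavity_volume_ml,
        }


def build_lv(profile: LVProfile, n_theta: int = 96, n_z: int = 65, model_id: str = "lv") -> LVModel:
    """Loft the inner and radially offset outer shells (both capped).

    The profile is resampled to ``n_z`` evenly spaced rings so thickness and
    radius statistics are not starved near the apex.  An offset that would
    collapse a section (non-positive outer radius, or inner radius larger
    than outer anywhere) is rejected.
    """
    dense = profile.resampled(n_z) if n_z and n_z > len(profile.sections) else profile
    inner = loft_ellipses(dense.sections, n_theta=n_theta, cap_ends=True)
    outer = loft_ellipses(dense.outer_sections(), n_theta=n_theta, cap_ends=True)
    return LVModel(inner=inner, outer=outer, profile=profile, model_id=model_id)


def _lateral_vertex_mask(mesh: TriMesh) -> np.ndarray:
    """Builder mask if present, else the cap-exclusion heuristic (needed for
    meshes re-imported from files, which lose the builder metadata)."""
    if mesh.lateral_mask is not None:
        return mesh.lateral_mask
    from .geometry import _infer_lateral_mask

    t = mesh.vertices[:, 2]
    r = np.hypot(mesh.vertices[:, 0], mesh.vertices[:, 1])
    return _infer_lateral_mask(t, r)


def measure_lv(model: LVModel, apex_exclusion: float = 2.0) -> LVMeasurements:
    """Measure one LV model.

    Height and radius statistics come from the OUTER shell via
    :func:`mesh_metrics`; wall thickness is the nearest-point distance from
    each inner-shell lateral vertex to the outer lateral surface (so sloped
    apex/base regions measure below the radial wall offset); cavity volume
    is the inner-shell enclosed volume in mL.
    """
    outer_stats: MeshMetrics = mesh_metrics(model.outer, apex_exclusion=apex_exclusion)
    inner_lat = _lateral_vertex_mask(model.inner)
    pts = model.inner.vertices[inner_lat]
    outer_face_lateral = _lateral_vertex_mask(model.outer)[model.outer.faces].all(axis=1)
    thickness = points_to_surface_distance(pts, model.outer, face_mask=outer_face_lateral)
    volume = mesh_volume(model.inner) / 1000.0
    return LVMeasurements(
        height=outer_stats.height,
        thickness_min=float(thickness.min()),
        thickness_max=float(thickness.max()),
        thickness_avg=float(thickness.mean()),
        radius_min=outer_stats.radius_min,
        radius_max=outer_stats.radius_max,
        radius_avg=outer_stats.radius_avg,
        cavity_volume_ml=volume,
    )
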