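"""Parameterized aortic-valve construction.

The valve is built from three leaflets attached inside an aortic root.  Each
leaflet is swept from a logarithmic generating curve defined in a radial
plane: with aortic radius ``R``, leaflet height ``H`` and curvature modifier
``a``,

    z(x) = H * ln(1 + a*(1 - x/R)) / ln(1 + a),     x in [0, R],

so the curve descends from the free-edge midpoint (x=0, z=H) to the wall
attachment (x=R, z=0); ``a -> 0`` degenerates continuously to the straight
line ``H*(1 - x/R)``.  Sweeping the plane over a 120-degree sector, the free
edge exponent ``k`` shapes the effective height ``H * (1 - (|theta|/60)^k)``
so the leaflet vanishes at the commissures.  The aortic root is a surface of
revolution with three sinus-of-Valsalva pockets bulging outward behind the
leaflets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import TriMesh, mesh_metrics, revolve_with_bulge

HALF_SECTOR = np.pi / 3.0  # three equal sectors -> 60 degree half-angle

#: physiological parameter ranges (mm) by population
ROOT_RANGES = {
    "adult": {
        "aortic_diameter": (15.0, 30.0),
        "bulb_height": (17.0, 25.0),
        "sinus_height": (17.0, 20.0),
        "sinus_depth": (1.5, 3.0),
    },
    "child": {
        "aortic_diameter": (6.0, 20.0),
        "bulb_height": (6.0, 14.0),
        "sinus_height": (6.0, 14.0),
        "sinus_depth": (1.5, 3.0),
    },
}

#: commonly observed sub-ranges (same units) for the mixture sampler
ROOT_COMMON_RANGES = {
    "adult": {"aortic_diameter": (20.0, 23.0)},
    "child": {"aortic_diameter": (7.0, 13.0)},
}


@dataclass(frozen=True)
class LeafletParams:
    """Leaflet control parameters: radius R, height H, curvature a, edge k."""

    R: float
    H: float
    a: float = 1.0
    k: float = 2.0

    def __post_init__(self) -> None:
        if self.R <= 0 or self.H <= 0:
            raise ValueError("R and H must be positive")
        if self.a < 0:
            raise ValueError("a must be >= 0 (a = 0 is the linear limit)")
        if self.k <= 0:
            raise ValueError("k must be positive")


@dataclass(frozen=True)
class RootParams:
    """Aortic-root parameters (mm): annulus radius, bulb/sinus heights, sinus depth."""

    annulus_radius: float
    bulb_height: float
    sinus_height: float
    sinus_depth: float
    population: str = "adult"

    def range_violations(self) -> list[str]:
        rng = ROOT_RANGES[self.population]
        checks = {
            "aortic_diameter": 2.0 * self.annulus_radius,
            "bulb_height": self.bulb_height,
            "sinus_height": self.sinus_height,
            "sinus_depth": self.sinus_depth,
        }
        out = []
        for name, value in checks.items():
            lo, hi = rng[name]
            if not (lo <= value <= hi):
                out.append(f"{name}={value:g} outside [{lo:g}, {hi:g}] for {self.population}")
        return out


def default_adult_root() -> RootParams:
    """Range midpoints of the adult physiological intervals."""
    return RootParams(annulus_radius=11.25, bulb_height=21.0, sinus_height=18.5, sinus_depth=2.25)


def generating_curve(params: LeafletParams, n_samples: int = 64) -> np.ndarray:
    """Sample the leaflet generating curve as an ``(n, 2)`` array of (x, z).

    Monotone decreasing from (0, H) to (R, 0); for ``a`` below 1e-8 the
    linear limit is used to avoid 0/0.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    x = np.linspace(0.0, params.R, n_samples)
    z = _curve_z(x, params)
    return np.column_stack([x, z])


def _curve_z(x: np.ndarray, params: LeafletParams) -> np.ndarray:
    u = 1.0 - np.asarray(x, dtype=float) / params.R
    if params.a < 1e-8:
        return params.H * u
    return params.H * np.log1p(params.a * u) / np.log1p(params.a)


def free_edge_profile(theta, k: float, half_sector: float = HALF_SECTOR):
    """Height scale f(theta) = 1 - (|theta|/half_sector)**k in [0, 1].

    f(0) = 1 at the leaflet midline, f(+-half_sector) = 0 at the commissures;
    larger ``k`` flattens the free edge.
    """
    theta = np.asarray(theta, dtype=float)
    if k <= 0:
        raise ValueError("k must be positive")
    if np.any(np.abs(theta) > half_sector + 1e-12):
        raise ValueError("theta outside the leaflet sector")
    return 1.0 - (np.abs(theta) / half_sector) ** k


def build_leaflet(
    params: LeafletParams,
    n_theta: int = 48,
    n_radial: int = 24,
    sector_rotation: float = 0.0,
) -> TriMesh:
    """Open leaflet surface swept over theta in [-60, 60] degrees.

    At each sweep angle the generating curve is evaluated with effective
    height ``H * f(theta)``; the attachment edge (x = R) lies on the annulus
    cylinder at z = 0 and the free edge is the locus x = 0.
    ``sector_rotation`` rotates the whole sector about the valve axis.
    """
    if n_theta < 8 or n_radial < 8:
        raise ValueError("resolutions must be >= 8")
    theta = np.linspace(-HALF_SECTOR, HALF_SECTOR, n_theta) + sector_rotation
    x = np.linspace(params.R, 0.0, n_radial)
    f = free_edge_profile(theta - sector_rotation, params.k)
    base_z = _curve_z(x, params) / params.H  # unit-height curve shape
    # grid: rows over theta, columns over x
    zz = np.outer(f * params.H, base_z)
    xx = np.outer(np.cos(theta), x)
    yy = np.outer(np.sin(theta), x)
    verts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    faces = []
    for i in range(n_theta - 1):
        for j in range(n_radial - 1):
            a = i * n_radial + j
            b = a + 1
            c = a + n_radial + 1
            d = a + n_radial
            faces.append((a, b, c))
            faces.append((a, c, d))
    return TriMesh(verts, np.array(faces, dtype=np.int64))


def build_aortic_root(
    params: RootParams,
    n_theta: int = 96,
    n_z: int = 48,
    sharpness: float = 2.0,
    allow_out_of_range: bool = False,
) -> TriMesh:
    """Aortic root: a cylinder of radius ``annulus_radius`` and height
    ``bulb_height`` with three sinus-of-Valsalva pockets.

    The bulge is ``sinus_depth * g(z) * max(0, cos(3*theta))**sharpness``
    with the smooth axial window ``g(z) = sin^2(pi*z/sinus_height)`` on
    ``[0, sinus_height]``, so the maximal radial coordinate is exactly
    ``annulus_radius + sinus_depth`` (the peak height is inserted into the
    axial grid).
    """
    violations = params.range_violations()
    if violations and not allow_out_of_range:
        raise ValueError("root parameters out of physiological range: " + "; ".join(violations))
    z = np.linspace(0.0, params.bulb_height, n_z + 1)
    peak = params.sinus_height / 2.0
    if 0.0 < peak < params.bulb_height:
        z = np.unique(np.concatenate([z, [peak]]))
    profile = np.column_stack([np.full(z.shape, params.annulus_radius), z])

    def bulge(zi: float, theta: np.ndarray) -> np.ndarray:
        if params.sinus_depth == 0.0 or not (0.0 <= zi <= params.sinus_height):
            return np.zeros_like(theta)
        g = np.sin(np.pi * zi / params.sinus_height) ** 2
        azi = np.maximum(0.0, np.cos(3.0 * theta)) ** sharpness
        return params.sinus_depth * g * azi

    return revolve_with_bulge(profile, n_theta=n_theta, bulge=bulge, cap_ends=False)


@dataclass
class ValveAssembly:
    """Aortic root plus three leaflets at 120-degree spacing."""

    root: TriMesh
    leaflets: list
    leaflet_params: LeafletParams
    root_params: RootParams

    def meshes(self) -> dict:
        out = {"root": self.root}
        for i, m in enumerate(self.leaflets):
            out[f"leaflet_{i}"] = m
        return out


def assemble_valve(
    leaflet: LeafletParams,
    root: RootParams,
    n_theta: int = 48,
    n_radial: int = 24,
    root_resolution: tuple = (96, 48),
    rescale: bool = False,
    allow_out_of_range: bool = False,
) -> ValveAssembly:
    """Build the root and three leaflets.

    The leaflet radius must equal the root annulus radius; with
    ``rescale=True`` the leaflet R is snapped to the annulus instead of
    raising.
    """
    if abs(leaflet.R - root.annulus_radius) > 1e-9:
        if not rescale:
            raise ValueError(
                f"leaflet R={leaflet.R:g} mm does not match annulus radius "
                f"{root.annulus_radius:g} mm (pass rescale=True to snap)"
            )
        leaflet = replace(leaflet, R=root.annulus_radius)
    leaflets = [
        build_leaflet(leaflet, n_theta=n_theta, n_radial=n_radial, sector_rotation=rot)
        for rot in (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0)
    ]
    root_mesh = build_aortic_root(
        root,
        n_theta=root_resolution[0],
        n_z=root_resolution[1],
        allow_out_of_range=allow_out_of_range,
    )
    return ValveAssembly(root=root_mesh, leaflets=leaflets, leaflet_params=leaflet, root_params=root)


def valve_dimensions(assembly: ValveAssembly) -> dict:
    """Report leaflet/root dimensions used by validation and manifests."""
    root_metrics = mesh_metrics(assembly.root, apex_exclusion=0.0)
    return {
        "leaflet_radius_mm": assembly.leaflet_params.R,
        "leaflet_height_mm": assembly.leaflet_params.H,
        "root_height_mm": root_metrics.height,
        "root_radius_max_mm": root_metrics.radius_max,
    }
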