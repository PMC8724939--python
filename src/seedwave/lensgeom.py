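"""Axisymmetric lens-shaped seed geometry and triangulation.

A lentil seed is idealised as a biconvex lens: two identical spherical
caps joined at their circular base (no cylindrical rim).  With overall
diameter ``d`` and thickness ``t`` the cap base radius is ``a = d/2``,
the cap height ``hcap = t/2`` and the circumscribing sphere radius
``Rs = (a^2 + hcap^2) / (2*hcap)``.

The computational domain is the half cross-section in the (r, z) plane
(r >= 0, z the rotation axis, seed centred at the origin); revolving it
about the z axis recovers the full seed.  That cross-section is convex,
so a Delaunay triangulation of well-spaced boundary + interior points is
a valid conforming mesh of it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

_AXIS_TOL = 1e-12


@dataclass(frozen=True)
class LensGeometry:
    """Biconvex lens (two spherical caps) with SI dimensions."""

    diameter: float = 4.4e-3
    thickness: float = 2.2e-3

    def __post_init__(self):
        if not (0.0 < self.thickness <= self.diameter):
            raise ValueError("need 0 < thickness <= diameter")

    @property
    def a(self) -> float:
        """Cap base radius (m)."""
        return self.diameter / 2.0

    @property
    def hcap(self) -> float:
        """Cap height (m)."""
        return self.thickness / 2.0

    @property
    def Rs(self) -> float:
        """Radius of the circumscribing sphere of each cap (m)."""
        return (self.a**2 + self.hcap**2) / (2.0 * self.hcap)

    def profile(self, r) -> np.ndarray:
        """Upper cap surface z(r) for r in [0, a]."""
        r = np.asarray(r, dtype=float)
        return np.sqrt(self.Rs**2 - r**2) - (self.Rs - self.hcap)

    def cross_section_area(self) -> float:
        """Analytic area of the half-lens (r, z) cross-section (m^2)."""
        a, h, Rs = self.a, self.hcap, self.Rs
        return Rs**2 * math.asin(a / Rs) - a * (Rs - h)


def lens_volume_area(geom: LensGeometry) -> tuple[float, float]:
    """Exact volume (m^3) and outer surface area (m^2) of the lens.

    Two spherical caps joined at the equator with no exposed rim:
    V = 2 * pi*h^2*(3R - h)/3 and A = 2 * 2*pi*R*h.
    """
    h, Rs = geom.hcap, geom.Rs
    volume = 2.0 * math.pi * h**2 * (3.0 * Rs - h) / 3.0
    area = 2.0 * 2.0 * math.pi * Rs * h
    return volume, area


def characteristic_length(geom: LensGeometry) -> float:
    """Volume-to-surface-area ratio L = V/A (m)."""
    v, a = lens_volume_area(geom)
    return v / a


@dataclass
class Mesh:
    """Conforming triangulation of the half-lens cross-section.

    nodes : (n, 2) float array of (r, z) coordinates, r >= 0
    triangles : (m, 3) int array, counter-clockwise node triples
    boundary_edges : (b, 2) int array, edges on the curved (convective) surface
    axis_edges : (k, 2) int array, edges on the symmetry axis r = 0
    """

    nodes: np.ndarray
    triangles: np.ndarray
    boundary_edges: np.ndarray
    axis_edges: np.ndarray
    geom: LensGeometry | None = None

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def triangle_areas(self) -> np.ndarray:
        """Signed (r, z)-plane triangle areas; positive for CCW ordering."""
        p = self.nodes[self.triangles]
        return 0.5 * (
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    def validate(self) -> None:
        """Raise on orientation, radius-sign, connectivity or tag defects."""
        if np.any(self.nodes[:, 0] < -_AXIS_TOL):
            raise ValueError("mesh has nodes with negative radius")
        areas = self.triangle_areas()
        if np.any(areas <= 0):
            raise ValueError("mesh has non-CCW or degenerate triangles")
        edge_count: dict[tuple[int, int], int] = {}
        for tri in self.triangles:
            for i in range(3):
                e = tuple(sorted((int(tri[i]), int(tri[(i + 1) % 3]))))
                edge_count[e] = edge_count.get(e, 0) + 1
        hull = {e for e, c in edge_count.items() if c == 1}
        if any(c > 2 for c in edge_count.values()):
            raise ValueError("non-manifold edge in mesh")
        tagged = {tuple(sorted(map(int, e))) for e in self.boundary_edges}
        tagged |= {tuple(sorted(map(int, e))) for e in self.axis_edges}
        if tagged != hull:
            raise ValueError("boundary/axis edge tags do not cover the mesh hull")
        for e in self.axis_edges:
            if np.any(np.abs(self.nodes[list(e), 0]) > _AXIS_TOL):
                raise ValueError("axis-tagged edge off the symmetry axis")


def _arc_points(geom: LensGeometry, target_h: float, upper: bool) -> np.ndarray:
    """Points along one cap arc from the pole to the equator (inclusive)."""
    Rs, a, h = geom.Rs, geom.a, geom.hcap
    theta_max = math.asin(min(1.0, a / Rs))
    n_seg = max(8, int(math.ceil(Rs * theta_max / target_h)))
    theta = np.linspace(0.0, theta_max, n_seg + 1)
    r = Rs * np.sin(theta)
    z = Rs * np.cos(theta) - (Rs - h)
    if not upper:
        z = -z
    return np.column_stack([r, z])


def generate_mesh(geom: LensGeometry, target_h: float = 9e-5) -> Mesh:
    """Triangulate the half-lens cross-section with edge length ~ target_h.

    The curved cap surfaces are tagged ``convective`` (boundary_edges),
    the r = 0 segment ``symmetry`` (axis_edges).  The default target_h
    yields a mesh of a few hundred nodes and on the order of a thousand
    triangles for the default seed dimensions.
    """
    if not (0.0 < target_h <= geom.thickness / 2.0):
        raise ValueError("target_h must be in (0, thickness/2]")
    up = _arc_points(geom, target_h, upper=True)
    lo = _arc_points(geom, target_h, upper=False)
    # axis segment between the two poles, endpoints already on the arcs
    n_ax = max(2, int(math.ceil(geom.thickness / target_h)))
    z_ax = np.linspace(-geom.hcap, geom.hcap, n_ax + 1)[1:-1]
    axis_pts = np.column_stack([np.zeros_like(z_ax), z_ax])

    pts = [up, lo[1:], axis_pts]
    # interior grid, kept clear of the boundary to avoid sliver triangles
    margin = 0.45 * target_h
    r_grid = np.arange(target_h, geom.a, target_h)
    if r_grid.size:
        z_top = geom.profile(r_grid) - margin
        for r_i, zt in zip(r_grid, z_top):
            if zt <= 0:
                continue
            n_z = int(math.floor(2.0 * zt / target_h))
            if n_z < 1:
                zs = np.array([0.0])
            else:
                zs = np.linspace(-zt, zt, n_z + 1)
            pts.append(np.column_stack([np.full_like(zs, r_i), zs]))
    nodes = np.vstack(pts)
    # dedupe (equator point appears on both arcs)
    _, keep = np.unique(np.round(nodes / (1e-6 * target_h)).astype(np.int64), axis=0, return_index=True)
    nodes = nodes[np.sort(keep)]
    nodes[np.abs(nodes[:, 0]) < _AXIS_TOL, 0] = 0.0

    tri = Delaunay(nodes)
    triangles = tri.simplices.copy()
    p = nodes[triangles]
    areas = 0.5 * (
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )
    flip = areas < 0
    triangles[flip] = triangles[flip][:, [0, 2, 1]]
    keep_tri = np.abs(areas) > 1e-6 * target_h**2
    triangles = triangles[keep_tri]
    if triangles.size == 0:
        raise RuntimeError(
            f"meshing failed for geometry {geom}: no non-degenerate triangles "
            f"(target_h={target_h})"
        )

    edge_count: dict[tuple[int, int], int] = {}
    for t in triangles:
        for i in range(3):
            e = tuple(sorted((int(t[i]), int(t[(i + 1) % 3]))))
            edge_count[e] = edge_count.get(e, 0) + 1
    hull_edges = [e for e, c in edge_count.items() if c == 1]
    axis_edges, conv_edges = [], []
    for e in hull_edges:
        if np.all(np.abs(nodes[list(e), 0]) <= _AXIS_TOL):
            axis_edges.append(e)
        else:
            conv_edges.append(e)

    mesh = Mesh(
        nodes=nodes,
        triangles=triangles,
        boundary_edges=np.asarray(conv_edges, dtype=int).reshape(-1, 2),
        axis_edges=np.asarray(axis_edges, dtype=int).reshape(-1, 2),
        geom=geom,
    )
    mesh.validate()
    return mesh


def axisymmetric_measures(mesh: Mesh) -> tuple[np.ndarray, np.ndarray]:
    """Revolved per-triangle volumes and per-convective-edge areas.

    Volume of a triangle revolved about the z axis: 2*pi*rbar*area with
    rbar the centroid radius (Pappus).  Revolved area of a boundary edge:
    2*pi*rbar_edge*length.  Sums converge to the analytic lens volume and
    surface area under refinement.
    """
    p = mesh.nodes[mesh.triangles]
    areas = mesh.triangle_areas()
    rbar = p[:, :, 0].mean(axis=1)
    volumes = 2.0 * math.pi * rbar * areas

    e = mesh.nodes[mesh.boundary_edges]
    lengths = np.linalg.norm(e[:, 1] - e[:, 0], axis=1)
    rbar_e = e[:, :, 0].mean(axis=1)
    areas_b = 2.0 * math.pi * rbar_e * lengths
    return volumes, areas_b


def write_vtk(mesh: Mesh, path: str, point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the mesh (and optional nodal fields) as legacy ASCII VTK."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nseedwave lens mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for r, z in mesh.nodes:
            fh.write(f"{r:.9e} {z:.9e} 0.0\n")
        fh.write(f"CELLS {mesh.n_triangles} {4 * mesh.n_triangles}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        fh.write(f"CELL_TYPES {mesh.n_triangles}\n")
        fh.write("5\n" * mesh.n_triangles)
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, vals in point_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for v in np.asarray(vals, dtype=float):
                    fh.write(f"{v:.9e}\n")
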