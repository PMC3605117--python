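"""Internal structured mesh generator for cables, annuli and spherical shells.

The generator is deliberately deterministic (no randomness): meshes are built
from an icosahedral triangulation of the sphere extruded along radial layers,
with prisms split into tetrahedra by a global-index diagonal rule that makes
the split conforming across neighbouring prisms and layers.  Interfaces
between compartments coincide exactly with mesh layers, so no element
straddles a compartment boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .geometry import Boundary, Compartment, SphericalGeometry
from .params import GeometryConfig

__all__ = [
    "Mesh",
    "MeshingError",
    "interval_mesh",
    "annulus_mesh",
    "icosphere",
    "ball_mesh",
    "spherical_shell_mesh",
    "four_compartment_mesh",
    "generate_mesh",
    "tag_boundaries",
]


class MeshingError(RuntimeError):
    pass


@dataclass
class Mesh:
    """A conforming simplicial mesh with compartment and boundary tags.

    ``points``: (n, dim) coordinates in meters.
    ``cells``: (m, dim+1) node indices of simplices.
    ``cell_labels``: (m,) compartment label per element (Compartment.*).
    ``facets``: (nf, dim) node indices of tagged interface/boundary facets.
    ``facet_labels``: (nf,) Boundary.* label per tagged facet.
    """

    dim: int
    points: np.ndarray
    cells: np.ndarray
    cell_labels: np.ndarray
    facets: np.ndarray = field(default_factory=lambda: np.zeros((0, 1), dtype=int))
    facet_labels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim == 1:
            self.points = self.points[:, None]
        self.cells = np.asarray(self.cells, dtype=int)
        self.cell_labels = np.asarray(self.cell_labels, dtype=int)
        self._orient()

    # -- basic queries -------------------------------------------------
    @property
    def num_nodes(self) -> int:
        return self.points.shape[0]

    @property
    def num_cells(self) -> int:
        return self.cells.shape[0]

    def cell_points(self) -> np.ndarray:
        return self.points[self.cells]  # (m, dim+1, dim)

    def cell_volumes(self) -> np.ndarray:
        x = self.cell_points()
        if self.dim == 1:
            return np.abs(x[:, 1, 0] - x[:, 0, 0])
        edges = x[:, 1:, :] - x[:, :1, :]
        det = np.linalg.det(edges)
        return np.abs(det) / float(math.factorial(self.dim))

    def cell_centroids(self) -> np.ndarray:
        return self.cell_points().mean(axis=1)

    def facet_centroids(self) -> np.ndarray:
        return self.points[self.facets].mean(axis=1)

    def facet_areas(self) -> np.ndarray:
        x = self.points[self.facets]
        if self.dim == 1:
            return np.ones(len(self.facets))
        if self.dim == 2:
            return np.linalg.norm(x[:, 1] - x[:, 0], axis=-1)
        c = np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])
        return 0.5 * np.linalg.norm(c, axis=-1)

    def compartment_volume(self, label: int) -> float:
        return float(self.cell_volumes()[self.cell_labels == label].sum())

    def compartment_nodes(self, label: int) -> np.ndarray:
        return np.unique(self.cells[self.cell_labels == label])

    def submesh(self, label: int, with_nodes: bool = False):
        """Extract the single-compartment mesh (node indices renumbered).

        With ``with_nodes=True`` also returns the parent-mesh node indices
        of the submesh nodes (for mapping fields back)."""
        keep = self.cell_labels == label
        cells = self.cells[keep]
        nodes = np.unique(cells)
        remap = -np.ones(self.num_nodes, dtype=int)
        remap[nodes] = np.arange(nodes.size)
        sub = Mesh(
            dim=self.dim,
            points=self.points[nodes],
            cells=remap[cells],
            cell_labels=self.cell_labels[keep],
        )
        return (sub, nodes) if with_nodes else sub

    # -- internal ------------------------------------------------------
    def _orient(self) -> None:
        """Flip element orientation so all simplex volumes are positive."""
        if self.dim == 1:
            bad = self.points[self.cells[:, 1], 0] < self.points[self.cells[:, 0], 0]
        else:
            x = self.cell_points()
            edges = x[:, 1:, :] - x[:, :1, :]
            bad = np.linalg.det(edges) < 0
        if np.any(bad):
            self.cells[bad, -2], self.cells[bad, -1] = (
                self.cells[bad, -1].copy(),
                self.cells[bad, -2].copy(),
            )
        vols = self.cell_volumes()
        if np.any(vols <= 0):
            raise MeshingError("degenerate element (zero volume)")


# ---------------------------------------------------------------------------
# 1D
# ---------------------------------------------------------------------------


def interval_mesh(length: float, h: float, x0: float = 0.0) -> Mesh:
    """Uniform 1D cable of ``length`` meters with target edge ``h``."""
    if length <= 0 or h <= 0:
        raise MeshingError("length and resolution must be positive")
    n = max(1, int(round(length / h)))
    x = x0 + np.linspace(0.0, length, n + 1)
    cells = np.column_stack([np.arange(n), np.arange(1, n + 1)])
    labels = np.full(n, Compartment.M)
    facets = np.array([[0], [n]])
    facet_labels = np.array([Boundary.dU, Boundary.dM])
    return Mesh(1, x, cells, labels, facets, facet_labels)


# ---------------------------------------------------------------------------
# 2D annulus
# ---------------------------------------------------------------------------


def annulus_mesh(
    r_inner: float, r_outer: float, n_radial: int, n_theta: int
) -> Mesh:
    """Triangulated annulus (a 2D cross-section of the uterine wall)."""
    if not 0 < r_inner < r_outer:
        raise MeshingError("require 0 < r_inner < r_outer")
    if n_radial < 1 or n_theta < 3:
        raise MeshingError("need n_radial >= 1 and n_theta >= 3")
    radii = np.linspace(r_inner, r_outer, n_radial + 1)
    theta = 2 * np.pi * np.arange(n_theta) / n_theta
    ring = np.column_stack([np.cos(theta), np.sin(theta)])
    points = (radii[:, None, None] * ring[None, :, :]).reshape(-1, 2)

    def node(k, j):
        return k * n_theta + (j % n_theta)

    tris = []
    for k in range(n_radial):
        for j in range(n_theta):
            a, b = node(k, j), node(k, j + 1)
            c, d = node(k + 1, j), node(k + 1, j + 1)
            # split quad (a,b,d,c) along the diagonal through its min index
            if min(a, d) < min(b, c):
                tris.append([a, b, d])
                tris.append([a, d, c])
            else:
                tris.append([a, b, c])
                tris.append([b, d, c])
    cells = np.array(tris)
    labels = np.full(len(cells), Compartment.M)
    inner = np.array([[node(0, j), node(0, j + 1)] for j in range(n_theta)])
    outer = np.array(
        [[node(n_radial, j), node(n_radial, j + 1)] for j in range(n_theta)]
    )
    facets = np.vstack([inner, outer])
    facet_labels = np.concatenate(
        [np.full(n_theta, Boundary.dU), np.full(n_theta, Boundary.dM)]
    )
    return Mesh(2, points, cells, labels, facets, facet_labels)


# ---------------------------------------------------------------------------
# icosphere surface
# ---------------------------------------------------------------------------


def icosphere(subdiv: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit-sphere triangulation: subdivided icosahedron (verts, faces)."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ]
    )
    for _ in range(subdiv):
        verts_list = list(verts)
        cache: Dict[tuple, int] = {}

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = verts_list[i] + verts_list[j]
                m = m / np.linalg.norm(m)
                cache[key] = len(verts_list)
                verts_list.append(m)
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(verts_list)
        faces = np.array(new_faces)
    return verts, faces


# ---------------------------------------------------------------------------
# layered radial extrusion -> tetrahedra
# ---------------------------------------------------------------------------


def _prism_split(cols: tuple[int, int, int], bot: np.ndarray, top: np.ndarray):
    """Split a triangular prism into 3 tets, conforming across prisms.

    ``cols`` are the global surface-vertex indices of the three columns (the
    tie-break key); ``bot``/``top`` the six node indices.  Diagonal choice
    follows the min-index rule (Dompierre et al.), which guarantees that the
    two prisms sharing a quad face pick the same diagonal.
    """
    order = np.argsort(cols)
    i0, i1, i2 = order[0], order[1], order[2]
    # rotate so the smallest column is first, preserving cyclic orientation
    if (i0, i1, i2) in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        rot = {0: (0, 1, 2), 1: (1, 2, 0), 2: (2, 0, 1)}[i0]
    else:
        rot = {0: (0, 2, 1), 1: (1, 0, 2), 2: (2, 1, 0)}[i0]
    V1, V2, V3 = (bot[r] for r in rot)
    V4, V5, V6 = (top[r] for r in rot)
    c2, c3 = cols[rot[1]], cols[rot[2]]
    if c2 < c3:
        return [[V1, V2, V3, V6], [V1, V2, V6, V5], [V1, V5, V6, V4]]
    return [[V1, V2, V3, V5], [V1, V5, V3, V6], [V1, V5, V6, V4]]


def _extrude_layers(
    verts: np.ndarray,
    faces: np.ndarray,
    layer_radii: np.ndarray,
    band_labels: np.ndarray,
    include_center: bool,
    center_label: int = Compartment.F,
):
    """Build tetrahedra between successive radial layers.

    ``layer_radii``: (n_layers, n_verts) radius of each surface vertex per
    layer (layers may be warped, e.g. toward an offset abdominal sphere).
    ``band_labels``: (n_layers-1,) compartment label of each radial band.
    """
    n_layers, nv = layer_radii.shape
    points = (layer_radii[:, :, None] * verts[None, :, :]).reshape(-1, 3)
    offset = 0
    cells = []
    labels = []
    if include_center:
        points = np.vstack([[[0.0, 0.0, 0.0]], points])
        offset = 1
        for a, b, c in faces:
            cells.append([0, a + offset, b + offset, c + offset])
            labels.append(center_label)

    def node(layer, v):
        return offset + layer * nv + v

    for k in range(n_layers - 1):
        lab = band_labels[k]
        for a, b, c in faces:
            bot = np.array([node(k, a), node(k, b), node(k, c)])
            top = np.array([node(k + 1, a), node(k + 1, b), node(k + 1, c)])
            for tet in _prism_split((a, b, c), bot, top):
                cells.append(tet)
                labels.append(lab)
    return points, np.array(cells), np.array(labels), offset, nv


def _layer_facets(faces: np.ndarray, layer: int, nv: int, offset: int) -> np.ndarray:
    return offset + layer * nv + faces


def spherical_shell_mesh(
    r_inner: float, r_outer: float, subdiv: int = 2, n_layers: int = 2
) -> Mesh:
    """Tetrahedral mesh of the myometrial shell alone (all elements M)."""
    if not 0 < r_inner < r_outer:
        raise MeshingError("require 0 < r_inner < r_outer")
    if n_layers < 1:
        raise MeshingError("need at least one radial layer")
    verts, faces = icosphere(subdiv)
    radii = np.linspace(r_inner, r_outer, n_layers + 1)
    layer_radii = np.repeat(radii[:, None], verts.shape[0], axis=1)
    band = np.full(n_layers, Compartment.M)
    pts, cells, labels, offset, nv = _extrude_layers(
        verts, faces, layer_radii, band, include_center=False
    )
    inner = _layer_facets(faces, 0, nv, offset)
    outer = _layer_facets(faces, n_layers, nv, offset)
    facets = np.vstack([inner, outer])
    flabels = np.concatenate(
        [np.full(len(faces), Boundary.dU), np.full(len(faces), Boundary.dM)]
    )
    return Mesh(3, pts, cells, labels, facets, flabels)


def ball_mesh(
    radius: float,
    subdiv: int = 2,
    n_layers: int = 4,
    label: int = Compartment.A,
) -> Mesh:
    """Homogeneous tetrahedral ball (validation geometry); outer surface
    tagged dA."""
    if radius <= 0 or n_layers < 1:
        raise MeshingError("radius and n_layers must be positive")
    verts, faces = icosphere(subdiv)
    radii = np.linspace(0.0, radius, n_layers + 1)[1:]
    layer_radii = np.repeat(radii[:, None], verts.shape[0], axis=1)
    band = np.full(n_layers - 1, label)
    pts, cells, labels, offset, nv = _extrude_layers(
        verts, faces, layer_radii, band, include_center=True, center_label=label
    )
    facets = _layer_facets(faces, n_layers - 1, nv, offset)
    flabels = np.full(len(faces), Boundary.dA)
    return Mesh(3, pts, cells, labels, facets, flabels)


def four_compartment_mesh(
    geometry: SphericalGeometry,
    subdiv: int = 2,
    layers: tuple[int, int, int, int] = (3, 2, 2, 3),
) -> Mesh:
    """Conforming tetrahedral mesh of fetus, cavity, wall and abdomen.

    ``layers`` = radial element layers in (F, U, M, A).  The three inner
    interfaces are exact spheres; the outer abdominal layers are warped along
    each ray toward the (possibly offset) abdominal surface so that the mesh
    boundary lies exactly on it.
    """
    cfg = geometry.config
    nF, nU, nM, nA = layers
    if min(layers) < 1:
        raise MeshingError("need at least one layer per compartment")
    verts, faces = icosphere(subdiv)
    nv = verts.shape[0]

    rF = np.linspace(0.0, cfg.r_fetus, nF + 1)[1:]  # center handled separately
    rU = np.linspace(cfg.r_fetus, cfg.r_myo_inner, nU + 1)[1:]
    rM = np.linspace(cfg.r_myo_inner, cfg.r_myo_outer, nM + 1)[1:]
    iso = np.concatenate([rF, rU, rM])
    layer_radii = np.repeat(iso[:, None], nv, axis=1)
    # abdominal band: interpolate between the uterine surface and the ray
    # intersection with the offset abdominal sphere
    t_out = geometry.abdomen_ray_radius(verts)  # (nv,)
    frac = np.linspace(0.0, 1.0, nA + 1)[1:]
    warped = cfg.r_myo_outer + frac[:, None] * (t_out[None, :] - cfg.r_myo_outer)
    layer_radii = np.vstack([layer_radii, warped])

    band = np.concatenate(
        [
            np.full(nF - 1, Compartment.F),
            np.full(nU, Compartment.U),
            np.full(nM, Compartment.M),
            np.full(nA, Compartment.A),
        ]
    )
    pts, cells, labels, offset, nv = _extrude_layers(
        verts, faces, layer_radii, band, include_center=True,
        center_label=Compartment.F,
    )
    # tagged facets at the four interfaces (layer indices into layer_radii)
    iF = nF - 1
    iU = nF - 1 + nU
    iM = nF - 1 + nU + nM
    iA = nF - 1 + nU + nM + nA
    facets = np.vstack(
        [_layer_facets(faces, i, nv, offset) for i in (iF, iU, iM, iA)]
    )
    flabels = np.concatenate(
        [
            np.full(len(faces), Boundary.dF),
            np.full(len(faces), Boundary.dU),
            np.full(len(faces), Boundary.dM),
            np.full(len(faces), Boundary.dA),
        ]
    )
    return Mesh(3, pts, cells, labels, facets, flabels)


def generate_mesh(
    geometry: SphericalGeometry,
    resolution: float,
    dimension: int = 3,
    kind: str = "full",
    length: Optional[float] = None,
) -> Mesh:
    """Generate a conforming mesh of the requested dimension.

    ``resolution`` is a target edge length in meters.  ``kind`` for 3D is
    ``"full"`` (four compartments) or ``"shell"`` (myometrium only).  For 1D a
    cable of ``length`` (default: the fundus-to-cervix arc length of the
    mid-wall sphere) is produced; for 2D a mid-wall annulus cross-section.
    """
    if resolution <= 0:
        raise MeshingError("resolution must be positive")
    cfg = geometry.config
    wall = cfg.wall_thickness
    if resolution > 2 * wall:
        raise MeshingError(
            f"resolution {resolution} too coarse to resolve the {wall} m wall"
        )
    if dimension == 1:
        L = length if length is not None else np.pi * (cfg.r_myo_outer - wall / 2)
        return interval_mesh(L, resolution)
    if dimension == 2:
        n_rad = max(2, int(round(wall / resolution)))
        n_theta = max(8, int(round(2 * np.pi * cfg.r_myo_outer / resolution)))
        return annulus_mesh(cfg.r_myo_inner, cfg.r_myo_outer, n_rad, n_theta)
    if dimension != 3:
        raise MeshingError("dimension must be 1, 2 or 3")
    edge0 = 1.0515  # icosahedron chord length on the unit sphere
    subdiv = max(0, int(np.ceil(np.log2(edge0 * cfg.r_myo_outer / resolution))))
    n_wall = max(2, int(round(wall / resolution)))
    if kind == "shell":
        return spherical_shell_mesh(cfg.r_myo_inner, cfg.r_myo_outer, subdiv, n_wall)
    if kind != "full":
        raise MeshingError(f"unknown mesh kind {kind!r}")
    nF = max(2, int(round(cfg.r_fetus / resolution / 4)))
    nU = max(1, int(round((cfg.r_myo_inner - cfg.r_fetus) / resolution)))
    nA = max(2, int(round((cfg.r_abdomen - cfg.r_myo_outer) / resolution / 4)))
    return four_compartment_mesh(geometry, subdiv, (nF, nU, n_wall, nA))


def tag_boundaries(mesh: Mesh, geometry: SphericalGeometry, rtol: float = 0.02) -> Mesh:
    """(Re)label tagged facets from their centroid position.

    A facet whose centroid radius matches one of the concentric interface
    radii (within ``rtol`` relative tolerance) gets that tag; a facet on the
    offset abdominal sphere gets dA.  An untaggable facet raises with its id.
    """
    cfg = geometry.config
    cent = mesh.facet_centroids()
    if mesh.dim == 1:
        r = np.abs(cent[:, 0])
    else:
        r = np.linalg.norm(cent, axis=-1)
    labels = np.full(len(cent), Boundary.NONE, dtype=int)
    targets = [
        (cfg.r_fetus, Boundary.dF),
        (cfg.r_myo_inner, Boundary.dU),
        (cfg.r_myo_outer, Boundary.dM),
    ]
    for radius, lab in targets:
        hit = np.abs(r - radius) <= rtol * radius
        labels[hit] = lab
    if mesh.dim == 3:
        ra = geometry.abdomen_distance(cent)
        hit = np.abs(ra - cfg.r_abdomen) <= rtol * cfg.r_abdomen
        labels[(labels == Boundary.NONE) & hit] = Boundary.dA
    bad = np.where(labels == Boundary.NONE)[0]
    if bad.size:
        raise MeshingError(
            f"facet {bad[0]} (centroid radius {r[bad[0]]:.4g}) matches no interface"
        )
    mesh.facet_labels = labels
    return mesh
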