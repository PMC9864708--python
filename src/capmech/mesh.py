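"""Structured triangulation of an annular vessel cross-section.

The wall between the lumen and outer contours is meshed transfinitely: the
lumen is resampled at equal arc length, matched outer points are found by
casting rays from the lumen centroid, and radial layers interpolate between
the two rings.  Each quad cell is split into two triangles along alternating
diagonals.  The construction gives the circumferential fiber direction per
element directly (the tangent of the interpolated layer), which the
anisotropic vessel model needs.

Lipid and calcification pools are labelled per element by a point-in-polygon
test at the element centroid; the interface is therefore resolved to one
element, which sharpens under mesh refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely import contains_xy
from shapely.geometry import LineString, Polygon

from .contours import SliceContours, polygon_centroid, resample_even

__all__ = ["Mesh", "build_mesh"]

TISSUE_CODES = {"vessel": 0, "lipid": 1, "calcification": 2}
TISSUE_NAMES = {v: k for k, v in TISSUE_CODES.items()}


@dataclass
class Mesh:
    """Triangle mesh of the vessel wall.

    nodes are reference (zero-load) coordinates in mm; ``tissue`` holds an
    integer code per element (0 vessel, 1 lipid, 2 calcification); ``nc`` is
    the unit circumferential direction per element; boundary edge lists are
    ordered counter-clockwise.
    """

    nodes: np.ndarray  # (N, 2)
    elements: np.ndarray  # (M, 3) int
    tissue: np.ndarray  # (M,) int
    nc: np.ndarray  # (M, 2) unit vectors
    lumen_edges: np.ndarray  # (n_theta, 2) int node pairs, CCW
    outer_edges: np.ndarray  # (n_theta, 2)
    element_size: float

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_areas(self) -> np.ndarray:
        p = self.nodes[self.elements]
        v1 = p[:, 1] - p[:, 0]
        v2 = p[:, 2] - p[:, 0]
        return 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])

    def min_angle_deg(self) -> float:
        p = self.nodes[self.elements]
        angles = []
        for k in range(3):
            a = p[:, (k + 1) % 3] - p[:, k]
            b = p[:, (k + 2) % 3] - p[:, k]
            cosang = np.einsum("ij,ij->i", a, b) / (
                np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
            )
            angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
        return float(np.min(angles))


def _ray_hits(centroid: np.ndarray, directions: np.ndarray, contour: np.ndarray) -> np.ndarray:
    """Farthest intersection of centroid rays with a closed contour."""
    ring = LineString(np.vstack([contour, contour[:1]]))
    reach = 10.0 * np.max(np.linalg.norm(contour - centroid, axis=1))
    hits = np.empty_like(directions)
    for i, d in enumerate(directions):
        ray = LineString([centroid, centroid + d * reach])
        inter = ray.intersection(ring)
        if inter.is_empty:
            raise ValueError("outer contour not star-shaped about lumen centroid")
        pts = (
            [inter]
            if inter.geom_type == "Point"
            else list(getattr(inter, "geoms", []))
        )
        coords = []
        for g in pts:
            coords.extend(np.asarray(g.coords))
        coords = np.asarray(coords)
        far = np.argmax(np.linalg.norm(coords - centroid, axis=1))
        hits[i] = coords[far]
    return hits


def _radial_stations(mean_thickness: float, element_size: float,
                     boundary_layer: bool) -> np.ndarray:
    """Normalized radial layer positions 0..1, optionally graded at the lumen.

    The loaded vessel develops a steep stress boundary layer at the lumen
    (exponential stiffening); graded layers start at ~element_size/12 there
    and grow geometrically to the target size at the outer wall.
    """
    if not boundary_layer:
        n_r = max(3, int(round(mean_thickness / element_size)))
        return np.linspace(0.0, 1.0, n_r + 1)
    h0 = element_size / 12.0
    ratio = 1.3
    steps = [h0]
    while sum(steps) < mean_thickness:
        steps.append(min(steps[-1] * ratio, element_size))
    t = np.concatenate([[0.0], np.cumsum(steps)]) / sum(steps)
    return t


def build_mesh(
    slc: SliceContours, element_size: float, boundary_layer: bool = False
) -> Mesh:
    """Triangulate the wall of a (zero-load) slice at a target element size."""
    if element_size <= 0:
        raise ValueError("element_size must be positive")
    centroid = polygon_centroid(slc.lumen)
    lumen_closed = np.vstack([slc.lumen, slc.lumen[:1]])
    perim = float(np.sum(np.linalg.norm(np.diff(lumen_closed, axis=0), axis=1)))
    n_theta = max(16, int(round(perim / element_size)))
    n_theta += n_theta % 2  # even count so the alternating diagonals wrap cleanly
    lumen_pts = resample_even(slc.lumen, n_theta)
    dirs = lumen_pts - centroid
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    outer_pts = _ray_hits(centroid, dirs, slc.outer)

    thickness = np.linalg.norm(outer_pts - lumen_pts, axis=1)
    stations = _radial_stations(float(np.mean(thickness)), element_size, boundary_layer)
    n_r = len(stations) - 1

    # transfinite grid: rows j = 0..n_r from lumen to outer
    t = stations[:, None, None]
    grid = (1 - t) * lumen_pts[None] + t * outer_pts[None]  # (n_r+1, n_theta, 2)
    nodes = grid.reshape(-1, 2)

    def nid(j: int | np.ndarray, i: int | np.ndarray) -> np.ndarray:
        return j * n_theta + np.mod(i, n_theta)

    elements = []
    for j in range(n_r):
        for i in range(n_theta):
            a, b = nid(j, i), nid(j, i + 1)
            c, d = nid(j + 1, i + 1), nid(j + 1, i)
            # CCW corner order is a -> d -> c -> b (radial out, then back)
            if (i + j) % 2 == 0:  # alternate diagonals for isotropy
                elements.append((a, d, c))
                elements.append((a, c, b))
            else:
                elements.append((a, d, b))
                elements.append((b, d, c))
    elements = np.asarray(elements, dtype=int)

    # circumferential direction: layer tangent at the element centroid
    cen = nodes[elements].mean(axis=1)
    rel = cen - centroid
    radial = rel / np.linalg.norm(rel, axis=1, keepdims=True)
    nc = np.stack([-radial[:, 1], radial[:, 0]], axis=1)  # CCW tangent

    tissue = np.zeros(len(elements), dtype=int)
    for polys, code in ((slc.lipids, 1), (slc.calcifications, 2)):
        for p in polys:
            inside = contains_xy(Polygon(p), cen[:, 0], cen[:, 1])
            tissue[inside] = code

    idx = np.arange(n_theta)
    lumen_edges = np.stack([nid(0, idx), nid(0, idx + 1)], axis=1)
    outer_edges = np.stack([nid(n_r, idx), nid(n_r, idx + 1)], axis=1)

    mesh = Mesh(nodes, elements, tissue, nc, lumen_edges, outer_edges, element_size)
    if np.any(mesh.element_areas() <= 0):
        raise ValueError("mesh has inverted elements; contours too distorted")
    return mesh
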