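"""Contour processing, polar quad meshing, and scattered-field transfer.

Tumor outlines are treated as star-shaped polygons about their centroid,
which gives a deterministic angular correspondence for averaging several
outlines, interpolating an outline between two time points, and laying a
transfinite polar mesh (quad rings plus a central triangle fan) over the
domain.  Field transfer between point sets uses inverse-distance
weighting (IDW).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Mesh",
    "polygon_area",
    "polygon_centroid",
    "star_radii",
    "resample_star",
    "average_contours",
    "interpolate_contours",
    "mesh_polygon",
    "mesh_rectangle",
    "idw_interpolate",
    "transfer_fields",
]

_SQRT3INV = 1.0 / np.sqrt(3.0)
# 2x2 Gauss points/weights on [-1,1]^2
QUAD_GAUSS = [(-_SQRT3INV, -_SQRT3INV), (_SQRT3INV, -_SQRT3INV),
              (_SQRT3INV, _SQRT3INV), (-_SQRT3INV, _SQRT3INV)]


def quad_shape(xi: float, eta: float) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear shape functions and parent-space gradients.

    Local node order is counter-clockwise: (-1,-1), (1,-1), (1,1), (-1,1).
    Returns (N, dN) with N shape (4,), dN shape (4, 2).
    """
    N = 0.25 * np.array([(1 - xi) * (1 - eta), (1 + xi) * (1 - eta),
                         (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)])
    dN = 0.25 * np.array([
        [-(1 - eta), -(1 - xi)],
        [(1 - eta), -(1 + xi)],
        [(1 + eta), (1 + xi)],
        [-(1 + eta), (1 - xi)],
    ])
    return N, dN


def polygon_area(pts: np.ndarray) -> float:
    """Signed shoelace area (positive for counter-clockwise orientation)."""
    pts = np.asarray(pts, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_centroid(pts: np.ndarray) -> np.ndarray:
    """Area centroid of a simple polygon."""
    pts = np.asarray(pts, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    xr, yr = np.roll(x, -1), np.roll(y, -1)
    cross = x * yr - xr * y
    a = 0.5 * cross.sum()
    if abs(a) < 1e-300:
        return pts.mean(axis=0)
    cx = np.sum((x + xr) * cross) / (6.0 * a)
    cy = np.sum((y + yr) * cross) / (6.0 * a)
    return np.array([cx, cy])


def star_radii(contour: np.ndarray, angles: np.ndarray,
               center: np.ndarray | None = None) -> np.ndarray:
    """Radius of a star-shaped polygon along each ray angle from the center.

    Raises ValueError when a ray crosses the boundary more than once
    (the polygon is not star-shaped about the chosen center).
    """
    contour = np.asarray(contour, dtype=float)
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if center is None:
        center = polygon_centroid(contour)
    a = contour - center                    # edge starts
    b = np.roll(contour, -1, axis=0) - center  # edge ends
    d = b - a                               # (m, 2)
    u = np.column_stack([np.cos(angles), np.sin(angles)])  # (n, 2)

    # ray c + t u vs segment a + s d:  t = cross(a, d) / cross(u, d)
    cross_ud = u[:, 0:1] * d[None, :, 1] - u[:, 1:2] * d[None, :, 0]  # (n, m)
    cross_ad = a[None, :, 0] * d[None, :, 1] - a[None, :, 1] * d[None, :, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(np.abs(cross_ud) > 1e-300, cross_ad / cross_ud, np.nan)
        # s along the segment:  t u = a + s d  crossed with u gives
        # 0 = cross(a, u) + s cross(d, u), i.e. s = cross(a, u)/cross(u, d)
        cross_au = a[None, :, 0] * u[:, 1:2] - a[None, :, 1] * u[:, 0:1]
        s = np.where(np.abs(cross_ud) > 1e-300, cross_au / cross_ud, np.nan)
    # generous s-window: a ray through a shared vertex must register on at
    # least one of the two adjacent edges; duplicates collapse below
    hit = (t > 1e-12) & (s >= -1e-9) & (s <= 1.0 + 1e-9)
    radii = np.empty(len(angles))
    for i in range(len(angles)):
        ts = t[i, hit[i]]
        if ts.size == 0:
            raise ValueError("ray misses the contour; center outside polygon?")
        # A ray grazing a vertex reports both adjacent edges, and a polygon
        # that is star-shaped about a nearby point (e.g. a blended outline
        # whose area centroid moved slightly off the resampling center) can
        # produce crossings a fraction of a percent apart.  Take the outer
        # one; only a genuinely folded boundary is an error.
        if ts.max() - ts.min() > 0.02 * ts.max():
            raise ValueError(
                "contour is not star-shaped about its centroid "
                f"(ray at angle {angles[i]:.4f} crosses the boundary "
                f"{ts.size} times)")
        radii[i] = ts.max()
    return radii


def resample_star(contour: np.ndarray, n_angles: int,
                  preserve_area: bool = True) -> np.ndarray:
    """Resample a star-shaped contour at equal polar angles about its centroid.

    With ``preserve_area`` (default) the resampled polygon is scaled
    radially about the centroid so its area equals the input polygon's
    area; the chord polygon of a smooth outline otherwise loses
    O(n_angles^-2) of the area.  With ``preserve_area=False`` vertices lie
    exactly on the input boundary.
    """
    contour = np.asarray(contour, dtype=float)
    center = polygon_centroid(contour)
    angles = 2.0 * np.pi * np.arange(n_angles) / n_angles
    r = star_radii(contour, angles, center)
    pts = center + r[:, None] * np.column_stack([np.cos(angles), np.sin(angles)])
    if preserve_area:
        a_in = abs(polygon_area(contour))
        a_out = abs(polygon_area(pts))
        pts = center + (pts - center) * np.sqrt(a_in / a_out)
    return pts


def _check_star_vertices(contour: np.ndarray) -> np.ndarray:
    """Vertex polar angles about the centroid; error if not monotone."""
    center = polygon_centroid(contour)
    rel = contour - center
    ang = np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
    d = np.diff(ang)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("contour vertices are not angularly monotone "
                         "(radius is multivalued; not star-shaped)")
    return ang


def average_contours(contours: list, n_angles: int = 128,
                     normalize_scale: bool = False) -> np.ndarray:
    """Average several star-shaped outlines into one.

    Centroids are aligned at the origin, each outline is resampled at
    ``n_angles`` equal polar angles, and the per-angle mean radius taken.
    ``normalize_scale`` first rescales every outline to the mean area, so
    shapes are averaged independently of size (how sizes of replicate
    tumor sections should be normalized before averaging is a modelling
    choice, not a measured fact).
    """
    if len(contours) == 0:
        raise ValueError("need at least one contour")
    angles = 2.0 * np.pi * np.arange(n_angles) / n_angles
    radii = []
    areas = np.array([abs(polygon_area(np.asarray(c, float)))
                      for c in contours])
    for c, a in zip(contours, areas):
        c = np.asarray(c, dtype=float)
        r = star_radii(c, angles, polygon_centroid(c))
        if normalize_scale:
            r = r * np.sqrt(areas.mean() / a)
        radii.append(r)
    r_mean = np.mean(radii, axis=0)
    return r_mean[:, None] * np.column_stack([np.cos(angles), np.sin(angles)])


def interpolate_contours(cA: np.ndarray, cB: np.ndarray,
                         alpha: float) -> np.ndarray:
    """Linear blend of two outlines resampled to matching angular nodes.

    Per-angle radius (and centroid position) interpolate linearly;
    alpha = 0 returns ``cA`` exactly, alpha = 1 returns ``cB`` exactly.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    cA = np.asarray(cA, dtype=float)
    cB = np.asarray(cB, dtype=float)
    if cA.shape != cB.shape:
        raise ValueError("contours must be resampled to matching angular "
                         "nodes (same vertex count) before interpolation")
    _check_star_vertices(cA)
    _check_star_vertices(cB)
    if alpha == 0.0:
        return cA.copy()
    if alpha == 1.0:
        return cB.copy()
    return (1.0 - alpha) * cA + alpha * cB


# ---------------------------------------------------------------------------
# Meshing


@dataclass
class Mesh:
    """2D mesh of 4-node quads plus 3-node triangles, unit thickness.

    ``nodes`` are (x, y) in micrometres; ``quads``/``tris`` index into
    nodes counter-clockwise; ``boundary_nodes`` lists the node indices on
    the domain contour; ``h_z`` is the out-of-plane thickness in um.
    """

    nodes: np.ndarray
    quads: np.ndarray
    tris: np.ndarray
    boundary_nodes: np.ndarray
    h_z: float = 1.0

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.quads = (np.asarray(self.quads, dtype=int)
                      if len(self.quads) else np.empty((0, 4), int))
        self.tris = (np.asarray(self.tris, dtype=int)
                     if len(self.tris) else np.empty((0, 3), int))
        self.boundary_nodes = np.asarray(self.boundary_nodes, dtype=int)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.quads) + len(self.tris)

    def element_nodes(self):
        """Yield the connectivity of every element (quads then triangles)."""
        for q in self.quads:
            yield q
        for t in self.tris:
            yield t

    def element_areas(self) -> np.ndarray:
        out = np.empty(self.n_elements)
        for e, conn in enumerate(self.element_nodes()):
            out[e] = abs(polygon_area(self.nodes[conn]))
        return out

    def element_centers(self) -> np.ndarray:
        out = np.empty((self.n_elements, 2))
        for e, conn in enumerate(self.element_nodes()):
            out[e] = self.nodes[conn].mean(axis=0)
        return out

    @property
    def area(self) -> float:
        return float(self.element_areas().sum())

    def node_tributary_volumes(self) -> np.ndarray:
        """V_J = sum_e integral of N_J over e, times thickness h_z.

        Partitions the mesh volume exactly: sum_J V_J = area * h_z.
        """
        V = np.zeros(self.n_nodes)
        for q in self.quads:
            coords = self.nodes[q]
            for xi, eta in QUAD_GAUSS:
                N, dN = quad_shape(xi, eta)
                J = dN.T @ coords
                V[q] += N * abs(np.linalg.det(J))
        for t in self.tris:
            a = abs(polygon_area(self.nodes[t]))
            V[t] += a / 3.0
        return V * self.h_z

    def check_jacobians(self) -> None:
        """Raise if any quad has a non-positive Jacobian at a Gauss point."""
        for q in self.quads:
            coords = self.nodes[q]
            for xi, eta in QUAD_GAUSS:
                _, dN = quad_shape(xi, eta)
                if np.linalg.det(dN.T @ coords) <= 0:
                    raise ValueError(f"non-positive Jacobian in quad {q}")
        for t in self.tris:
            if polygon_area(self.nodes[t]) <= 0:
                raise ValueError(f"inverted triangle {t}")


def mesh_polygon(contour: np.ndarray, n_rings: int = 16, n_sectors: int = 32,
                 h_z: float = 1.0, preserve_area: bool = True) -> Mesh:
    """Polar transfinite mesh of a star-shaped polygon.

    ``n_rings`` x ``n_sectors`` quads fill the annular region between the
    first ring and the boundary; a fan of ``n_sectors`` triangles closes
    the centroid.  Node radii grow linearly from the centroid to the
    (resampled) boundary along each sector angle.
    """
    if n_rings < 2:
        raise ValueError("n_rings must be >= 2")
    if n_sectors < 6:
        raise ValueError("n_sectors must be >= 6")
    contour = np.asarray(contour, dtype=float)
    if abs(polygon_area(contour)) <= 0:
        raise ValueError("degenerate contour")
    boundary = resample_star(contour, n_sectors, preserve_area=preserve_area)
    center = polygon_centroid(boundary)

    nodes = [center]
    for i in range(1, n_rings + 1):
        f = i / n_rings
        ring = center + f * (boundary - center)
        nodes.extend(ring)
    nodes = np.asarray(nodes)

    def nid(i, j):
        # ring i in 1..n_rings, sector j modulo n_sectors
        return 1 + (i - 1) * n_sectors + (j % n_sectors)

    tris = [[0, nid(1, j), nid(1, j + 1)] for j in range(n_sectors)]
    quads = [
        [nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)]
        for i in range(1, n_rings)
        for j in range(n_sectors)
    ]
    boundary_nodes = np.array([nid(n_rings, j) for j in range(n_sectors)])
    mesh = Mesh(nodes=nodes, quads=np.array(quads), tris=np.array(tris),
                boundary_nodes=boundary_nodes, h_z=h_z)
    mesh.check_jacobians()
    return mesh


def mesh_rectangle(length: float, height: float, nx: int, ny: int,
                   origin: tuple[float, float] = (0.0, 0.0),
                   h_z: float = 1.0) -> Mesh:
    """Structured quad mesh of an axis-aligned rectangle (benchmark helper)."""
    if nx < 1 or ny < 1:
        raise ValueError("need at least one element per direction")
    xs = origin[0] + np.linspace(0.0, length, nx + 1)
    ys = origin[1] + np.linspace(0.0, height, ny + 1)
    xx, yy = np.meshgrid(xs, ys)
    nodes = np.column_stack([xx.ravel(), yy.ravel()])

    def nid(i, j):  # row i (y), col j (x)
        return i * (nx + 1) + j

    quads = [
        [nid(i, j), nid(i, j + 1), nid(i + 1, j + 1), nid(i + 1, j)]
        for i in range(ny)
        for j in range(nx)
    ]
    border = sorted(
        {nid(i, j) for i in (0, ny) for j in range(nx + 1)}
        | {nid(i, j) for i in range(ny + 1) for j in (0, nx)}
    )
    return Mesh(nodes=nodes, quads=np.array(quads),
                tris=np.empty((0, 3), int),
                boundary_nodes=np.array(border), h_z=h_z)


# ---------------------------------------------------------------------------
# Inverse-distance weighting


def idw_interpolate(points: np.ndarray, values: np.ndarray,
                    queries: np.ndarray, power: float = 2.0,
                    k: int | None = None) -> np.ndarray:
    """Shepard inverse-distance interpolation.

    value(q) = sum_i w_i v_i / sum_i w_i with w_i = |q - x_i|^(-power),
    over all samples or the ``k`` nearest.  Exact at sample locations
    (limit convention), bounded by the sample extrema, and reproduces
    constants.  Conflicting values at duplicate sample points are an
    error.
    """
    if power <= 0:
        raise ValueError("power must be positive")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    values = np.asarray(values, dtype=float)
    flat = values.ndim == 1
    vals = values[:, None] if flat else values
    if len(points) == 0:
        raise ValueError("need at least one sample point")
    if len(points) != len(vals):
        raise ValueError("points and values length mismatch")

    # duplicate detection
    order = np.lexsort(points.T)
    ps, vs = points[order], vals[order]
    same = np.all(np.isclose(ps[1:], ps[:-1], rtol=0, atol=0), axis=1)
    if np.any(same & ~np.all(np.isclose(vs[1:], vs[:-1]), axis=1)):
        raise ValueError("duplicate sample points with conflicting values")

    scale = max(np.ptp(points, axis=0).max(), 1.0)
    tol = 1e-12 * scale
    if k is not None and k < len(points):
        tree = cKDTree(points)
        dist, idx = tree.query(queries, k=k)
        dist = np.atleast_2d(dist)
        idx = np.atleast_2d(idx)
        neigh_vals = vals[idx]                      # (nq, k, m)
    else:
        diff = queries[:, None, :] - points[None, :, :]
        dist = np.sqrt(np.sum(diff**2, axis=-1))    # (nq, n)
        idx = None
        neigh_vals = np.broadcast_to(vals[None], (len(queries),) + vals.shape)

    out = np.empty((len(queries), vals.shape[1]))
    exact = dist.min(axis=1) <= tol
    with np.errstate(divide="ignore"):
        w = dist ** (-power)
    w[~np.isfinite(w)] = 0.0
    denom = w.sum(axis=1)
    ok = ~exact
    out[ok] = (w[ok, :, None] * neigh_vals[ok]).sum(axis=1) / denom[ok, None]
    for qi in np.nonzero(exact)[0]:
        j = int(dist[qi].argmin())
        out[qi] = neigh_vals[qi, j]
    return out[:, 0] if flat else out


def transfer_fields(old_mesh: Mesh, fields: np.ndarray, new_mesh: Mesh,
                    power: float = 2.0, k: int = 4) -> np.ndarray:
    """IDW transfer of nodal fields from one mesh to another.

    Uses the ``k`` nearest old nodes (default 4); constants transfer
    exactly and identical meshes give an identity transfer.
    """
    if old_mesh.n_nodes == 0:
        raise ValueError("empty source mesh")
    return idw_interpolate(old_mesh.nodes, fields, new_mesh.nodes,
                           power=power, k=k)
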