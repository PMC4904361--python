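"""Convex-polyhedron geometry: face recovery from vertex coordinates.

A convex polyhedron is stored as a bare set of vertex coordinates; its
combinatorics (edges and polygonal faces) are recovered from the convex
hull.  Qhull returns a simplicial (triangulated) hull, so hull facets that
lie in a common supporting plane are merged back into polygonal faces.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull


class GeometryError(ValueError):
    """Degenerate or non-convex input geometry."""


#: facets whose outward normals differ by less than this angle (radians)
#: are candidates for merging into one planar face
NORMAL_TOL = 1e-6
#: and whose plane offsets agree within this distance (model units)
OFFSET_TOL = 1e-8


def _merge_coplanar_facets(hull: ConvexHull, normal_tol: float, offset_tol: float):
    """Union-find merge of adjacent hull simplices sharing a supporting plane."""
    nfac = len(hull.simplices)
    parent = list(range(nfac))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    eq = hull.equations  # (nfac, 4): outward normal, offset
    cos_tol = np.cos(normal_tol)
    for i in range(nfac):
        for j in hull.neighbors[i]:
            if j < i:
                continue
            if eq[i, :3] @ eq[j, :3] >= cos_tol and abs(eq[i, 3] - eq[j, 3]) <= offset_tol:
                ri, rj = find(i), find(int(j))
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[int]] = {}
    for i in range(nfac):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def _boundary_cycle(simplices: np.ndarray, group: list[int], normal: np.ndarray,
                    points: np.ndarray) -> list[int]:
    """Ordered boundary vertex cycle of a union of coplanar triangles.

    The cycle is oriented counter-clockwise when viewed from outside
    (against the outward face normal).
    """
    # count directed edges; boundary edges appear exactly once as undirected.
    # qhull simplices are not consistently oriented, so orient each triangle
    # CCW w.r.t. the outward normal first.
    edge_count: dict[tuple[int, int], int] = {}
    directed: dict[tuple[int, int], tuple[int, int]] = {}
    for fi in group:
        tri = [int(v) for v in simplices[fi]]
        p0, p1, p2 = points[tri]
        if np.cross(p1 - p0, p2 - p0) @ normal < 0:
            tri = [tri[0], tri[2], tri[1]]
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            key = (min(a, b), max(a, b))
            edge_count[key] = edge_count.get(key, 0) + 1
            directed[key] = (a, b)
    boundary = [directed[k] for k, c in edge_count.items() if c == 1]
    if not boundary:
        raise GeometryError("facet group has no boundary; degenerate hull")
    nxt = {a: b for a, b in boundary}
    if len(nxt) != len(boundary):
        raise GeometryError("non-simple face boundary (pinched face)")
    start = boundary[0][0]
    cycle = [start]
    cur = nxt[start]
    while cur != start:
        cycle.append(cur)
        cur = nxt[cur]
        if len(cycle) > len(boundary):
            raise GeometryError("face boundary does not close into a single cycle")
    if len(cycle) != len(boundary):
        raise GeometryError("face boundary is not a single cycle")
    # orientation: qhull simplices are already consistently oriented w.r.t.
    # outward normals, so the walk above is CCW from outside; verify.
    pts = points[cycle]
    area_vec = np.zeros(3)
    for i in range(len(cycle)):
        area_vec += np.cross(pts[i], pts[(i + 1) % len(cycle)])
    if area_vec @ normal < 0:
        cycle.reverse()
    return [int(v) for v in cycle]


def derive_faces(vertices, normal_tol: float = NORMAL_TOL,
                 offset_tol: float = OFFSET_TOL):
    """Recover edges and polygonal faces of a convex polyhedron.

    Parameters
    ----------
    vertices : (m, 3) array_like
        Coordinates of the vertices of a convex polyhedron.  All points
        must be extreme points of their own convex hull.

    Returns
    -------
    edges : list of (i, j) tuples, i < j
    faces : list of vertex-index cycles, each oriented CCW from outside

    Raises
    ------
    GeometryError
        If the input is degenerate (rank < 3) or some point is interior.
    """
    pts = np.asarray(vertices, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise GeometryError("need at least 4 three-dimensional points")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10 * max(1.0, np.abs(pts).max())) < 3:
        raise GeometryError("points are coplanar or collinear")
    hull = ConvexHull(pts)
    if len(hull.vertices) != len(pts):
        missing = sorted(set(range(len(pts))) - set(hull.vertices.tolist()))
        raise GeometryError(f"points {missing} are not extreme (interior or duplicate)")

    groups = _merge_coplanar_facets(hull, normal_tol, offset_tol)
    faces = []
    for group in groups:
        normal = hull.equations[group[0], :3]
        faces.append(_boundary_cycle(hull.simplices, group, normal, pts))

    edge_set = set()
    for cyc in faces:
        for i in range(len(cyc)):
            a, b = cyc[i], cyc[(i + 1) % len(cyc)]
            edge_set.add((min(a, b), max(a, b)))
    edges = sorted(edge_set)

    V, E, F = len(pts), len(edges), len(faces)
    if V - E + F != 2:
        raise GeometryError(
            f"derived face set violates Euler's relation: V={V} E={E} F={F}")
    return edges, faces


def face_plane(points) -> tuple[np.ndarray, float]:
    """Best-fit plane (unit normal, offset) through a set of points."""
    pts = np.asarray(points, dtype=float)
    c = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - c)
    n = vt[2]
    return n, float(n @ c)


def polar_dual_vertices(vertices, faces) -> np.ndarray:
    """Vertices of the polar dual polyhedron (one per face).

    The dual vertex of a face with supporting plane {x : n.x = h} (outward
    unit normal n, h > 0 with the centroid at the origin) is n / h.  Polar
    duality guarantees exactly planar dual faces, so the combinatorial
    structure of the dual is recovered exactly by `derive_faces`.
    """
    pts = np.asarray(vertices, dtype=float)
    pts = pts - pts.mean(axis=0)
    duals = []
    for cyc in faces:
        n, h = face_plane(pts[cyc])
        if h < 0:
            n, h = -n, -h
        if h < 1e-9:
            raise GeometryError("face plane passes through the centroid")
        duals.append(n / h)
    return np.array(duals)
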