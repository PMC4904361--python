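"""Constructions of the 123 reference solids (vertex coordinates only).

The reference library consists of the 5 Platonic, 13 Archimedean,
13 Catalan and 92 Johnson solids.  Every construction here produces bare
vertex coordinates; edges and faces are always recovered afterwards from
the convex hull (`geometry.derive_faces`), since only the combinatorial
structure matters for topological-profile classification.

Construction routes
-------------------
* Platonic and most Archimedean solids: classical closed-form coordinates
  (golden ratio / silver ratio / tribonacci constant recipes).
* Snub cube: closed form; snub dodecahedron: numerical realization of the
  chiral 60-point orbit seeded by alternating the great rhombicosidodecahedron.
* Catalan solids: polar duals of the Archimedean solids (polar duality
  about the centroid yields exactly planar dual faces).
* Johnson solids: assembled from unit-edge rings, pyramids, cupolas and
  rotundas, by augmentation/diminishment/gyration of Platonic and
  Archimedean solids, or (for the eight "elementary" coronas and snubs
  J84-J92 without such a decomposition) by numerically solving for the
  unique convex unit-edge realization with regular faces from a symmetry
  ansatz.

All outputs are validated: convexity, Euler's relation, and (except for
the Catalans, whose faces are non-regular by design) planar regular faces
with equal edge lengths to ~1e-9 relative accuracy.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import ConvexHull, QhullError

from .geometry import GeometryError, derive_faces, polar_dual_vertices

PHI = (1.0 + math.sqrt(5.0)) / 2.0
#: tribonacci constant, the real root of t^3 = t^2 + t + 1
TRIBONACCI = np.roots([1.0, -1.0, -1.0, -1.0]).real.max()


# --------------------------------------------------------------------------
# small helpers

def _dedupe(points, tol=1e-9):
    pts = np.asarray(points, dtype=float)
    out = []
    for p in pts:
        if not any(np.linalg.norm(p - q) < tol for q in out):
            out.append(p)
    return np.array(out)


def _signed_perms(values, even_perms_only=False, sign_rule=None):
    """All coordinate permutations of `values` with sign choices.

    sign_rule(n_minus, perm_parity) -> bool selects which combinations
    are kept; by default all are kept.  Zeros never receive a sign.
    """
    base = list(values)
    perms = itertools.permutations(range(3))
    out = []
    for perm in perms:
        parity = _perm_parity(perm)
        if even_perms_only and parity != 0:
            continue
        vec = [base[perm[0]], base[perm[1]], base[perm[2]]]
        nz = [i for i, v in enumerate(vec) if v != 0]
        for signs in itertools.product([1, -1], repeat=len(nz)):
            n_minus = sum(1 for s in signs if s < 0)
            if sign_rule is not None and not sign_rule(n_minus, parity):
                continue
            w = list(vec)
            for i, s in zip(nz, signs):
                w[i] = s * w[i]
            out.append(w)
    return _dedupe(out)


def _perm_parity(perm):
    inv = sum(1 for i in range(3) for j in range(i + 1, 3) if perm[i] > perm[j])
    return inv % 2


def circumradius(n: int) -> float:
    """Circumradius of a regular n-gon with unit edge."""
    return 0.5 / math.sin(math.pi / n)


def ring(n: int, z: float, phase: float = 0.0, radius: float | None = None):
    """Vertices of a regular n-gon with unit edge in the plane at height z."""
    R = circumradius(n) if radius is None else radius
    ang = phase + 2.0 * math.pi * np.arange(n) / n
    return np.column_stack([R * np.cos(ang), R * np.sin(ang), np.full(n, float(z))])


def pyramid_height(n: int) -> float:
    """Apex height of a unit-edge right pyramid over a regular n-gon (n<6)."""
    h2 = 1.0 - circumradius(n) ** 2
    if h2 <= 0:
        raise GeometryError(f"no unit-edge pyramid over an {n}-gon")
    return math.sqrt(h2)


def cupola_height(n: int) -> float:
    """Height of a unit-edge n-cupola (n-gon over 2n-gon)."""
    rn, r2n = circumradius(n), circumradius(2 * n)
    d2 = rn * rn + r2n * r2n - 2.0 * rn * r2n * math.cos(math.pi / (2 * n))
    return math.sqrt(1.0 - d2)


def antiprism_height(n: int) -> float:
    """Height between the two n-gon rings of a unit-edge n-antiprism."""
    R = circumradius(n)
    c = 2.0 * R * math.sin(math.pi / (2 * n))
    return math.sqrt(1.0 - c * c)


def _rotz(points, angle):
    c, s = math.cos(angle), math.sin(angle)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return points @ R.T


def edge_length(points) -> float:
    """Shortest inter-vertex distance = edge length for unit-edge solids."""
    pts = np.asarray(points)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    d[np.diag_indices(len(pts))] = np.inf
    return float(d.min())


def normalize_edge(points) -> np.ndarray:
    """Rescale so the minimum inter-vertex distance (the edge) is 1."""
    pts = np.asarray(points, dtype=float)
    return pts / edge_length(pts)


# --------------------------------------------------------------------------
# Platonic solids

def tetrahedron():
    return np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / math.sqrt(8.0)


def cube():
    return 0.5 * np.array(list(itertools.product([-1.0, 1.0], repeat=3)))


def octahedron():
    return _signed_perms([1.0, 0.0, 0.0]) / math.sqrt(2.0)


def dodecahedron():
    a = np.array(list(itertools.product([-1.0, 1.0], repeat=3)))
    b = _signed_perms([0.0, 1.0 / PHI, PHI], even_perms_only=True)
    return np.vstack([a, b]) * (PHI / 2.0)  # edge 2/phi before scaling


def icosahedron():
    return _signed_perms([0.0, 1.0, PHI], even_perms_only=True) / 2.0


# --------------------------------------------------------------------------
# Archimedean solids

def truncated_tetrahedron():
    pts = _signed_perms([1.0, 1.0, 3.0], sign_rule=lambda m, p: m % 2 == 0)
    return pts / math.sqrt(8.0)


def cuboctahedron():
    return _signed_perms([1.0, 1.0, 0.0]) / math.sqrt(2.0)


def truncated_cube():
    xi = math.sqrt(2.0) - 1.0
    return _signed_perms([xi, 1.0, 1.0]) / (2.0 * xi)


def truncated_octahedron():
    return _signed_perms([0.0, 1.0, 2.0]) / math.sqrt(2.0)


def rhombicuboctahedron():
    return _signed_perms([1.0, 1.0, 1.0 + math.sqrt(2.0)]) / 2.0


def truncated_cuboctahedron():
    s = math.sqrt(2.0)
    return _signed_perms([1.0, 1.0 + s, 1.0 + 2.0 * s]) / 2.0


def snub_cube():
    t = TRIBONACCI
    # one enantiomorph: even permutations with an even number of minus
    # signs together with odd permutations with an odd number
    pts = _signed_perms([1.0, 1.0 / t, t],
                        sign_rule=lambda m, p: (m % 2) == p)
    return normalize_edge(pts)


def icosidodecahedron():
    a = _signed_perms([0.0, 0.0, PHI], even_perms_only=True)
    b = _signed_perms([0.5, PHI / 2.0, PHI * PHI / 2.0], even_perms_only=True)
    return normalize_edge(np.vstack([a, b]))


def truncated_dodecahedron():
    a = _signed_perms([0.0, 1.0 / PHI, 2.0 + PHI], even_perms_only=True)
    b = _signed_perms([1.0 / PHI, PHI, 2.0 * PHI], even_perms_only=True)
    c = _signed_perms([PHI, 2.0, PHI + 1.0], even_perms_only=True)
    return normalize_edge(np.vstack([a, b, c]))


def truncated_icosahedron():
    a = _signed_perms([0.0, 1.0, 3.0 * PHI], even_perms_only=True)
    b = _signed_perms([1.0, 2.0 + PHI, 2.0 * PHI], even_perms_only=True)
    c = _signed_perms([PHI, 2.0, 2.0 * PHI + 1.0], even_perms_only=True)
    return normalize_edge(np.vstack([a, b, c]))


def rhombicosidodecahedron():
    a = _signed_perms([1.0, 1.0, PHI ** 3], even_perms_only=True)
    b = _signed_perms([PHI ** 2, PHI, 2.0 * PHI], even_perms_only=True)
    c = _signed_perms([2.0 + PHI, 0.0, PHI ** 2], even_perms_only=True)
    return normalize_edge(np.vstack([a, b, c]))


def truncated_icosidodecahedron():
    f = PHI
    blocks = [
        [1.0 / f, 1.0 / f, 3.0 + f],
        [2.0 / f, f, 1.0 + 2.0 * f],
        [1.0 / f, f * f, 3.0 * f - 1.0],
        [2.0 * f - 1.0, 2.0, 2.0 + f],
        [f, 3.0, 2.0 * f],
    ]
    pts = np.vstack([_signed_perms(b, even_perms_only=True) for b in blocks])
    return normalize_edge(pts)


# --------------------------------------------------------------------------
# numerical realization of unit-edge solids with regular faces

def _merged_hull_faces(pts, angle_tol):
    """Polygonal faces of the hull, merging facets within angle_tol (rad)."""
    hull = ConvexHull(pts)
    nfac = len(hull.simplices)
    parent = list(range(nfac))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    cos_tol = math.cos(angle_tol)
    for i in range(nfac):
        for j in hull.neighbors[i]:
            if j < i:
                continue
            if hull.equations[i, :3] @ hull.equations[j, :3] >= cos_tol:
                ri, rj = find(i), find(int(j))
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[int]] = {}
    for i in range(nfac):
        groups.setdefault(find(i), []).append(i)
    faces = []
    for group in groups.values():
        vs = sorted({int(v) for gi in group for v in hull.simplices[gi]})
        faces.append(vs)
    return faces, hull


def _face_cycles(pts, faces):
    """Order each merged face's vertices into a ring (by angle in its plane)."""
    cycles = []
    for vs in faces:
        P = pts[vs]
        c = P.mean(axis=0)
        Q = P - c
        _, _, vt = np.linalg.svd(Q)
        u, v = vt[0], vt[1]
        ang = np.arctan2(Q @ v, Q @ u)
        order = np.argsort(ang)
        cycles.append([vs[i] for i in order])
    return cycles


def _face_residuals(pts, cycles):
    """Residuals forcing every face cycle to be a planar regular unit polygon."""
    res = []
    for cyc in cycles:
        P = pts[cyc]
        n = len(cyc)
        c = P.mean(axis=0)
        Q = P - c
        sv = np.linalg.svd(Q, compute_uv=False)
        res.append(sv[2])  # planarity
        R = circumradius(n) if n >= 3 else 0.5
        res.extend(np.linalg.norm(Q, axis=1) - R)  # regular circumradius
        d = np.linalg.norm(P - np.roll(P, -1, axis=0), axis=1)
        res.extend(d - 1.0)  # unit edges
    return np.array(res)


def realize(param_to_points, x0, merge_angle=0.25, max_outer=8, verbose=False):
    """Solve for unit-edge regular-face coordinates from a symmetry ansatz.

    `param_to_points(x)` maps the free parameters to the full vertex set;
    the residual demands that every merged hull face be a planar regular
    polygon with unit edges.  The face combinatorics is frozen within each
    least-squares solve (hull recomputation between evaluations would make
    finite-difference jacobians meaningless) and refreshed between outer
    iterations until it stabilizes.  Returns the realized coordinates.
    """
    x = np.asarray(x0, dtype=float)
    prev_faces = None
    for _ in range(max_outer):
        pts = param_to_points(x)
        faces, _ = _merged_hull_faces(pts, merge_angle)
        key = sorted(tuple(f) for f in faces)
        cycles = _face_cycles(pts, faces)

        def fun(xx, cycles=cycles):
            pts = param_to_points(np.asarray(xx, float))
            if not np.isfinite(pts).all() or np.abs(pts).max() > 1e6:
                raise GeometryError("parameters diverged")
            return _face_residuals(pts, cycles)

        sol = least_squares(fun, x, xtol=1e-15, ftol=1e-15, gtol=1e-15)
        x = sol.x
        if verbose:
            print("realize outer: residual max", np.abs(sol.fun).max())
        if prev_faces == key:
            break
        prev_faces = key
    pts = param_to_points(x)
    # the objective is translation invariant; remove any gauge drift
    return pts - pts.mean(axis=0)


# --------------------------------------------------------------------------
# icosahedral rotation group (for the snub dodecahedron orbit)

def _rotation_matrix(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = math.cos(angle / 2.0)
    b, c, d = -axis * math.sin(angle / 2.0)
    return np.array([
        [a * a + b * b - c * c - d * d, 2 * (b * c + a * d), 2 * (b * d - a * c)],
        [2 * (b * c - a * d), a * a + c * c - b * b - d * d, 2 * (c * d + a * b)],
        [2 * (b * d + a * c), 2 * (c * d - a * b), a * a + d * d - b * b - c * c],
    ])


def icosahedral_rotations():
    """The 60 rotation matrices of the icosahedral rotation group I."""
    g1 = _rotation_matrix([0.0, 1.0, PHI], 2.0 * math.pi / 5.0)
    g2 = _rotation_matrix([1.0, 1.0, 1.0], 2.0 * math.pi / 3.0)
    mats = [np.eye(3)]

    def known(M):
        return any(np.allclose(M, K, atol=1e-9) for K in mats)

    frontier = [np.eye(3)]
    while frontier:
        nxt = []
        for M in frontier:
            for g in (g1, g2):
                P = g @ M
                if not known(P):
                    mats.append(P)
                    nxt.append(P)
        frontier = nxt
        if len(mats) > 60:
            raise GeometryError("icosahedral group closure failed")
    if len(mats) != 60:
        raise GeometryError(f"expected 60 rotations, got {len(mats)}")
    return mats


def snub_dodecahedron():
    """Chiral 60-vertex orbit solved from an alternation seed."""
    tid = truncated_icosidodecahedron()
    edges, _ = derive_faces(tid)
    # 2-colour the (bipartite) vertex graph and keep one colour class
    n = len(tid)
    colour = -np.ones(n, dtype=int)
    colour[0] = 0
    stack = [0]
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    while stack:
        v = stack.pop()
        for w in adj[v]:
            if colour[w] < 0:
                colour[w] = 1 - colour[v]
                stack.append(w)
    seed0 = tid[np.flatnonzero(colour == 0)[0]]
    rots = icosahedral_rotations()

    def orbit(x):
        return np.array([R @ x for R in rots])

    pts = realize(orbit, seed0, merge_angle=0.2)
    return normalize_edge(pts)


# --------------------------------------------------------------------------
# Catalan solids (polar duals)

_ARCHIMEDEAN = [
    ("truncated tetrahedron", truncated_tetrahedron),
    ("cuboctahedron", cuboctahedron),
    ("truncated cube", truncated_cube),
    ("truncated octahedron", truncated_octahedron),
    ("rhombicuboctahedron", rhombicuboctahedron),
    ("truncated cuboctahedron", truncated_cuboctahedron),
    ("snub cube", snub_cube),
    ("icosidodecahedron", icosidodecahedron),
    ("truncated dodecahedron", truncated_dodecahedron),
    ("truncated icosahedron", truncated_icosahedron),
    ("rhombicosidodecahedron", rhombicosidodecahedron),
    ("truncated icosidodecahedron", truncated_icosidodecahedron),
    ("snub dodecahedron", snub_dodecahedron),
]

#: dual Catalan solid of each Archimedean solid, in the same order
_CATALAN_NAMES = [
    "triakis tetrahedron",
    "rhombic dodecahedron",
    "triakis octahedron",
    "tetrakis hexahedron",
    "deltoidal icositetrahedron",
    "disdyakis dodecahedron",
    "pentagonal icositetrahedron",
    "rhombic triacontahedron",
    "triakis icosahedron",
    "pentakis dodecahedron",
    "deltoidal hexecontahedron",
    "disdyakis triacontahedron",
    "pentagonal hexecontahedron",
]


def catalan_from(archimedean_vertices) -> np.ndarray:
    _, faces = derive_faces(archimedean_vertices)
    return polar_dual_vertices(archimedean_vertices, faces)


# --------------------------------------------------------------------------
# solid validation (used to select augmentation sites/alignments)

def validate_regular_solid(pts, tol=1e-7):
    """Check convex unit-edge regular-faced realization; return face vector.

    Returns (V, E, face_count_by_size) if valid, else raises GeometryError.
    """
    pts = np.asarray(pts, dtype=float)
    edges, faces = derive_faces(pts)
    for cyc in faces:
        P = pts[cyc]
        c = P.mean(axis=0)
        Q = P - c
        sv = np.linalg.svd(Q, compute_uv=False)
        if sv[2] > tol:
            raise GeometryError("non-planar face after merge")
        R = circumradius(len(cyc))
        if np.abs(np.linalg.norm(Q, axis=1) - R).max() > tol:
            raise GeometryError("face is not a regular polygon")
        d = np.linalg.norm(P - np.roll(P, -1, axis=0), axis=1)
        if np.abs(d - 1.0).max() > tol:
            raise GeometryError("face edges are not unit length")
    fv: dict[int, int] = {}
    for f in faces:
        fv[len(f)] = fv.get(len(f), 0) + 1
    return len(pts), len(edges), fv


def _face_centroid_normal(pts, cyc):
    P = pts[cyc]
    c = P.mean(axis=0)
    _, _, vt = np.linalg.svd(P - c)
    n = vt[2]
    if n @ (c - pts.mean(axis=0)) < 0:
        n = -n
    return c, n


def augment_pyramid(pts, cyc):
    """Glue a unit-edge right pyramid onto the given face cycle."""
    pts = np.asarray(pts, dtype=float)
    c, n = _face_centroid_normal(pts, cyc)
    apex = c + pyramid_height(len(cyc)) * n
    return np.vstack([pts, apex])


def augment_cupola(pts, cyc, twist=0):
    """Glue a unit-edge n-cupola onto a 2n-gon face cycle.

    twist selects which alternating edge-midpoint family the top ring sits
    above (the two choices generally give different solids; exactly one is
    a valid convex regular-faced augmentation).
    """
    pts = np.asarray(pts, dtype=float)
    m = len(cyc)
    if m % 2:
        raise GeometryError("cupola augmentation needs an even face")
    n = m // 2
    c, nrm = _face_centroid_normal(pts, cyc)
    P = pts[cyc]
    # in-plane frame
    u = P[0] - c
    u = u - (u @ nrm) * nrm
    u /= np.linalg.norm(u)
    v = np.cross(nrm, u)
    ang = np.arctan2((P - c) @ v, (P - c) @ u)
    order = np.argsort(ang)
    angs = ang[order]
    # top-ring angles: midpoints of alternate boundary pairs
    tops = []
    h = cupola_height(n)
    Rn = circumradius(n)
    for j in range(n):
        k = (2 * j + twist) % m
        a1, a2 = angs[k], angs[(k + 1) % m]
        if (k + 1) % m == 0:
            a2 += 2 * math.pi
        mid = (a1 + a2) / 2.0
        tops.append(c + h * nrm + Rn * (math.cos(mid) * u + math.sin(mid) * v))
    return np.vstack([pts, np.array(tops)])


def _faces_of_size(pts, k):
    _, faces = derive_faces(pts)
    return [f for f in faces if len(f) == k]


def _axis(pts, cyc):
    c, n = _face_centroid_normal(np.asarray(pts, float), cyc)
    return n


def dots_expand(dots, k):
    """Expand a pairwise dot-product spec to one value per pair of k sites."""
    npairs = k * (k - 1) // 2
    if len(dots) == npairs:
        return list(dots)
    if len(dots) == 1:
        return [dots[0]] * npairs
    raise ValueError("bad dots spec")


def _pick_faces_by_axis(pts, faces, k, dots):
    """Pick k faces whose pairwise axis dot-products match `dots`."""
    axes = [_axis(pts, f) for f in faces]
    want = sorted(dots_expand(dots, k))
    for combo in itertools.combinations(range(len(faces)), k):
        pair_dots = sorted(
            axes[i] @ axes[j] for i, j in itertools.combinations(combo, 2))
        if all(abs(a - b) < 1e-6 for a, b in zip(pair_dots, want)):
            return [faces[i] for i in combo]
    raise GeometryError("no face combination with requested axis geometry")


# --------------------------------------------------------------------------
# Johnson solids: stacked-ring components

def _cupola_rings(n, z0=0.0, up=1.0, bottom_phase=None, top_shift=0.0):
    """Bottom 2n-ring and top n-ring of a unit-edge cupola.

    The bottom ring sits at height z0 with phase pi/(2n) (+bottom_phase
    override); the top ring sits at z0 + up*h with vertices above alternate
    bottom-edge midpoints, rotated additionally by top_shift.
    """
    q = math.pi / (2 * n) if bottom_phase is None else bottom_phase
    bot = ring(2 * n, z0, q)
    top = ring(n, z0 + up * cupola_height(n), q - math.pi / (2 * n) + top_shift)
    return bot, top


def pyramid(n):
    return np.vstack([ring(n, 0.0), [[0.0, 0.0, pyramid_height(n)]]])


def cupola(n):
    bot, top = _cupola_rings(n)
    return np.vstack([bot, top])


def rotunda(gyr: int = 0):
    """Pentagonal rotunda: decagon at z=0 (phase pi/10), body above.

    gyr=1 rotates the body (not the decagon) by pi/5; since the decagon is
    invariant under that rotation, this yields the alternative attachment
    used for ortho/gyro pairings.
    """
    ico = icosidodecahedron()
    _, faces = derive_faces(ico)
    pent = next(f for f in faces if len(f) == 5)
    c, n = _face_centroid_normal(ico, pent)
    axis = c / np.linalg.norm(c)
    # rotate axis to +z
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s, cth = np.linalg.norm(v), axis @ z
    if s < 1e-12:
        R = np.eye(3) if cth > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - cth) / (s * s))
    pts = ico @ R.T
    keep = pts[pts[:, 2] > -1e-9]
    # decagon ring is at z ~ 0; normalize its phase to pi/10
    eq = keep[np.abs(keep[:, 2]) < 1e-9]
    ang = math.atan2(eq[0, 1], eq[0, 0])
    pts = _rotz(keep, math.pi / 10.0 - ang)
    # snap phase: decagon vertices sit at pi/10 + k*pi/5
    if gyr:
        body = pts[np.abs(pts[:, 2]) > 1e-9]
        deca = pts[np.abs(pts[:, 2]) < 1e-9]
        pts = np.vstack([deca, _rotz(body, math.pi / 5.0)])
    return pts


def prism(n, z0=0.0, phase=0.0):
    return np.vstack([ring(n, z0, phase), ring(n, z0 - 1.0, phase)])


def antiprism(n, z0=0.0, phase=0.0):
    return np.vstack([ring(n, z0, phase),
                      ring(n, z0 - antiprism_height(n), phase + math.pi / n)])


def _mirror_z(pts):
    out = np.array(pts, dtype=float)
    out[:, 2] *= -1.0
    return out


# ---- J1-J26 ----

def j1():  # square pyramid
    return pyramid(4)


def j2():  # pentagonal pyramid
    return pyramid(5)


def j3():
    return cupola(3)


def j4():
    return cupola(4)


def j5():
    return cupola(5)


def j6():
    return rotunda()


def _elongated_pyramid(n):
    return np.vstack([prism(n), [[0.0, 0.0, pyramid_height(n)]]])


def j7():
    return _elongated_pyramid(3)


def j8():
    return _elongated_pyramid(4)


def j9():
    return _elongated_pyramid(5)


def _gyroelongated_pyramid(n):
    return np.vstack([antiprism(n), [[0.0, 0.0, pyramid_height(n)]]])


def j10():
    return _gyroelongated_pyramid(4)


def j11():
    return _gyroelongated_pyramid(5)


def _bipyramid(n):
    h = pyramid_height(n)
    return np.vstack([ring(n, 0.0), [[0, 0, h], [0, 0, -h]]])


def j12():
    return _bipyramid(3)


def j13():
    return _bipyramid(5)


def _elongated_bipyramid(n):
    h = pyramid_height(n)
    return np.vstack([prism(n), [[0, 0, h], [0, 0, -1.0 - h]]])


def j14():
    return _elongated_bipyramid(3)


def j15():
    return _elongated_bipyramid(4)


def j16():
    return _elongated_bipyramid(5)


def j17():  # gyroelongated square bipyramid
    ha = antiprism_height(4)
    hp = pyramid_height(4)
    return np.vstack([antiprism(4), [[0, 0, hp], [0, 0, -ha - hp]]])


def _elongated_cupola(n):
    bot, top = _cupola_rings(n)
    return np.vstack([top, prism(2 * n, 0.0, math.pi / (2 * n))])


def j18():
    return _elongated_cupola(3)


def j19():
    return _elongated_cupola(4)


def j20():
    return _elongated_cupola(5)


def j21():  # elongated pentagonal rotunda
    rot = rotunda()
    return np.vstack([rot[np.abs(rot[:, 2]) > 1e-9],
                      prism(10, 0.0, math.pi / 10.0)])


def _gyroelongated_cupola(n):
    bot, top = _cupola_rings(n)
    return np.vstack([top, antiprism(2 * n, 0.0, math.pi / (2 * n))])


def j22():
    return _gyroelongated_cupola(3)


def j23():
    return _gyroelongated_cupola(4)


def j24():
    return _gyroelongated_cupola(5)


def j25():  # gyroelongated pentagonal rotunda
    rot = rotunda()
    return np.vstack([rot[np.abs(rot[:, 2]) > 1e-9],
                      antiprism(10, 0.0, math.pi / 10.0)])


def j26():  # gyrobifastigium
    h = math.sqrt(3.0) / 2.0
    return np.array([
        [0.5, 0.5, 0.0], [0.5, -0.5, 0.0], [-0.5, 0.5, 0.0], [-0.5, -0.5, 0.0],
        [0.5, 0.0, h], [-0.5, 0.0, h],
        [0.0, 0.5, -h], [0.0, -0.5, -h],
    ])


# ---- bicupolas, cupolarotundas, birotundas (J27-J48) ----

def _bicupola(n, gyro: bool):
    bot, top = _cupola_rings(n)
    shift = math.pi / n if gyro else 0.0
    top2 = _rotz(_mirror_z(top), shift)
    return np.vstack([bot, top, top2])


def j27():
    return _bicupola(3, gyro=False)


def j28():
    return _bicupola(4, gyro=False)


def j29():
    return _bicupola(4, gyro=True)


def j30():
    return _bicupola(5, gyro=False)


def j31():
    return _bicupola(5, gyro=True)


def _cupolarotunda(gyro: bool):
    # cupola above the shared decagon (phase pi/10), rotunda mirrored below
    _, top = _cupola_rings(5)
    rot = _mirror_z(rotunda(gyr=1 if gyro else 0))
    return np.vstack([top, rot])


def j32():  # orthocupolarotunda (see calibration in the build script)
    return _cupolarotunda(gyro=False)


def j33():
    return _cupolarotunda(gyro=True)


def _birotunda(gyro: bool):
    rot = rotunda()
    rot2 = _mirror_z(rotunda(gyr=1 if gyro else 0))
    return np.vstack([rot, rot2[np.abs(rot2[:, 2]) > 1e-9]])


def j34():  # pentagonal orthobirotunda (the gyro form is the icosidodecahedron)
    return _birotunda(gyro=False)


def _elongated_bicupola(n, gyro: bool):
    bot, top = _cupola_rings(n)
    pr = prism(2 * n, 0.0, math.pi / (2 * n))
    shift = math.pi / n if gyro else 0.0
    _, top2 = _cupola_rings(n, z0=-1.0, up=-1.0, top_shift=shift)
    return np.vstack([top, pr, top2])


def j35():
    return _elongated_bicupola(3, gyro=False)


def j36():
    return _elongated_bicupola(3, gyro=True)


def j37():  # elongated square gyrobicupola (pseudo-rhombicuboctahedron)
    return _elongated_bicupola(4, gyro=True)


def j38():
    return _elongated_bicupola(5, gyro=False)


def j39():
    return _elongated_bicupola(5, gyro=True)


def _elongated_cupolarotunda(gyro: bool):
    _, top = _cupola_rings(5)
    pr = prism(10, 0.0, math.pi / 10.0)
    rot = _mirror_z(rotunda(gyr=1 if gyro else 0))
    rot = rot[np.abs(rot[:, 2]) > 1e-9]
    rot[:, 2] -= 1.0
    return np.vstack([top, pr, rot])


def j40():
    return _elongated_cupolarotunda(gyro=False)


def j41():
    return _elongated_cupolarotunda(gyro=True)


def _elongated_birotunda(gyro: bool):
    rot = rotunda()
    pr = prism(10, 0.0, math.pi / 10.0)
    rot2 = _mirror_z(rotunda(gyr=1 if gyro else 0))
    rot2 = rot2[np.abs(rot2[:, 2]) > 1e-9]
    rot2[:, 2] -= 1.0
    return np.vstack([rot[np.abs(rot[:, 2]) > 1e-9], pr, rot2])


def j42():
    return _elongated_birotunda(gyro=False)


def j43():
    return _elongated_birotunda(gyro=True)


def _gyroelongated_bicupola(n):
    bot, top = _cupola_rings(n)
    ap = antiprism(2 * n, 0.0, math.pi / (2 * n))
    z2 = -antiprism_height(2 * n)
    _, top2 = _cupola_rings(n, z0=z2, up=-1.0,
                            bottom_phase=math.pi / (2 * n) + math.pi / (2 * n))
    return np.vstack([top, ap, top2])


def j44():
    return _gyroelongated_bicupola(3)


def j45():
    return _gyroelongated_bicupola(4)


def j46():
    return _gyroelongated_bicupola(5)


def j47():  # gyroelongated pentagonal cupolarotunda
    _, top = _cupola_rings(5)
    ap = antiprism(10, 0.0, math.pi / 10.0)
    z2 = -antiprism_height(10)
    rot = _mirror_z(rotunda())
    rot = rot[np.abs(rot[:, 2]) > 1e-9]
    rot[:, 2] += z2
    rot = _rotz(rot, math.pi / 10.0)
    return np.vstack([top, ap, rot])


def j48():  # gyroelongated pentagonal birotunda
    rot = rotunda()
    ap = antiprism(10, 0.0, math.pi / 10.0)
    z2 = -antiprism_height(10)
    rot2 = _mirror_z(rotunda())
    rot2 = rot2[np.abs(rot2[:, 2]) > 1e-9]
    rot2[:, 2] += z2
    rot2 = _rotz(rot2, math.pi / 10.0)
    return np.vstack([rot[np.abs(rot[:, 2]) > 1e-9], ap, rot2])


# ---- augmented prisms (J49-J57) ----

def _aug_prism(n, which):
    pts = prism(n, 0.5)
    sq = [f for f in _faces_of_size(pts, 4)]
    # order square side faces by centroid angle
    def cang(f):
        c, _ = _face_centroid_normal(pts, f)
        return math.atan2(c[1], c[0]) % (2 * math.pi)
    sq.sort(key=cang)
    for k in which:
        pts = augment_pyramid(pts, [int(v) for v in sq[k]])
    return pts


def j49():
    return _aug_prism(3, [0])


def j50():
    return _aug_prism(3, [0, 1])


def j51():
    return _aug_prism(3, [0, 1, 2])


def j52():
    return _aug_prism(5, [0])


def j53():
    return _aug_prism(5, [0, 2])


def j54():
    return _aug_prism(6, [0])


def j55():
    return _aug_prism(6, [0, 3])


def j56():
    return _aug_prism(6, [0, 2])


def j57():
    return _aug_prism(6, [0, 2, 4])


# ---- augmented dodecahedra / diminished icosahedra (J58-J64) ----

_META = -1.0 / math.sqrt(5.0)


def _aug_dodeca(k, dots):
    pts = normalize_edge(dodecahedron())
    faces = _faces_of_size(pts, 5)
    if k == 1:
        chosen = [faces[0]]
    else:
        chosen = _pick_faces_by_axis(pts, faces, k, dots)
    for f in chosen:
        pts = augment_pyramid(pts, f)
    return pts


def j58():
    return _aug_dodeca(1, [])


def j59():
    return _aug_dodeca(2, [-1.0])


def j60():
    return _aug_dodeca(2, [_META])


def j61():
    return _aug_dodeca(3, [_META])


def _diminished_icosahedron(k, dots):
    pts = normalize_edge(icosahedron())
    units = pts / np.linalg.norm(pts, axis=1)[:, None]
    n = len(pts)
    want = sorted(dots_expand(dots, k))
    for combo in itertools.combinations(range(n), k):
        pair_dots = sorted(units[i] @ units[j]
                           for i, j in itertools.combinations(combo, 2))
        if all(abs(a - b) < 1e-6 for a, b in zip(pair_dots, want)):
            keep = [i for i in range(n) if i not in combo]
            return pts[keep]
    raise GeometryError("no vertex set with requested geometry")


def j62():  # metabidiminished icosahedron
    return _diminished_icosahedron(2, [_META])


def j63():  # tridiminished icosahedron
    return _diminished_icosahedron(3, [_META])


def j64():  # augmented tridiminished icosahedron
    base = j63()
    for f in _faces_of_size(base, 3):
        try:
            cand = augment_pyramid(base, f)
            validate_regular_solid(cand)
            return cand
        except GeometryError:
            continue
    raise GeometryError("no valid augmentation site on J63")


# ---- augmented truncated solids (J65-J71) ----

def _aug_cupola_checked(pts, face):
    for twist in (0, 1):
        cand = augment_cupola(pts, face, twist=twist)
        try:
            validate_regular_solid(cand)
            return cand
        except GeometryError:
            continue
    raise GeometryError("no valid cupola alignment on face")


def j65():
    pts = normalize_edge(truncated_tetrahedron())
    return _aug_cupola_checked(pts, _faces_of_size(pts, 6)[0])


def j66():
    pts = normalize_edge(truncated_cube())
    return _aug_cupola_checked(pts, _faces_of_size(pts, 8)[0])


def j67():
    pts = normalize_edge(truncated_cube())
    f1, f2 = _pick_faces_by_axis(pts, _faces_of_size(pts, 8), 2, [-1.0])
    pts = _aug_cupola_checked(pts, f1)
    # vertex indices of the surviving antipodal octagon are unchanged
    return _aug_cupola_checked(pts, f2)


def _aug_trunc_dodeca(k, dots):
    pts = normalize_edge(truncated_dodecahedron())
    faces = _faces_of_size(pts, 10)
    chosen = [faces[0]] if k == 1 else _pick_faces_by_axis(pts, faces, k, dots)
    for f in chosen:
        pts = _aug_cupola_checked(pts, f)
    return pts


def j68():
    return _aug_trunc_dodeca(1, [])


def j69():
    return _aug_trunc_dodeca(2, [-1.0])


def j70():
    return _aug_trunc_dodeca(2, [_META])


def j71():
    return _aug_trunc_dodeca(3, [_META])


# ---- gyrate / diminished rhombicosidodecahedra (J72-J83) ----

def _rco_ops(ngyr, ndim, dots):
    """Gyrate and/or diminish pentagonal caps of the rhombicosidodecahedron.

    ngyr caps are gyrated (their pentagon rotated by pi/5 about its axis)
    and ndim caps diminished (their pentagon's vertices removed).  The cap
    sites are chosen so the pentagon axes have the requested pairwise dot
    products (para: -1, meta: -1/sqrt(5)); `dots` is empty for one cap,
    a single value for uniform pairs, or one value per pair.
    """
    pts = normalize_edge(rhombicosidodecahedron())
    faces = _faces_of_size(pts, 5)
    k = ngyr + ndim
    if k == 1:
        chosen = [faces[0]]
    else:
        chosen = _pick_faces_by_axis(pts, faces, k, dots)
    gyr_faces, dim_faces = chosen[:ngyr], chosen[ngyr:]
    for f in gyr_faces:
        c, _ = _face_centroid_normal(pts, f)
        axis = c / np.linalg.norm(c)
        rot = _rotation_matrix(axis, math.pi / 5.0)
        sel = np.array(f, dtype=int)
        pts[sel] = pts[sel] @ rot.T
    drop = {int(v) for f in dim_faces for v in f}
    if drop:
        keep = [i for i in range(len(pts)) if i not in drop]
        pts = pts[keep]
    return pts


def j72():  # gyrate rhombicosidodecahedron
    return _rco_ops(1, 0, [])


def j73():  # parabigyrate
    return _rco_ops(2, 0, [-1.0])


def j74():  # metabigyrate
    return _rco_ops(2, 0, [_META])


def j75():  # trigyrate
    return _rco_ops(3, 0, [_META])


def j76():  # diminished
    return _rco_ops(0, 1, [])


def j77():  # paragyrate diminished
    return _rco_ops(1, 1, [-1.0])


def j78():  # metagyrate diminished
    return _rco_ops(1, 1, [_META])


def j79():  # bigyrate diminished
    return _rco_ops(2, 1, [_META])


def j80():  # parabidiminished
    return _rco_ops(0, 2, [-1.0])


def j81():  # metabidiminished
    return _rco_ops(0, 2, [_META])


def j82():  # gyrate bidiminished
    return _rco_ops(1, 2, [_META])


def j83():  # tridiminished
    return _rco_ops(0, 3, [_META])


# ---- elementary Johnson solids (J84-J92) ----

def j84():
    """Snub disphenoid: closed form via the root of 2q^3 + 11q^2 + 4q - 1."""
    q = float(np.roots([2.0, 11.0, 4.0, -1.0]).real.max())
    r = math.sqrt(q)
    s = math.sqrt((1.0 - q) / (2.0 * q))
    t = 2.0 * r * s
    pts = np.array([
        [t, r, 0.0], [-t, r, 0.0], [0.0, -r, t], [0.0, -r, -t],
        [1.0, -s, 0.0], [-1.0, -s, 0.0], [0.0, s, 1.0], [0.0, s, -1.0],
    ])
    return pts / 2.0  # edge length 2 as constructed


def _c2v_points(x, orbits):
    """Build a C2v-symmetric vertex set (mirrors xz and yz).

    orbits: sequence of kinds: 'ex' -> (+-a, 0, c) pair on the xz mirror,
    'ey' -> (0, +-b, c) pair, 'q' -> (+-a, +-b, c) quadruple.  Parameters
    are consumed from x in order (2, 2 and 3 values respectively).
    """
    pts = []
    i = 0
    for kind in orbits:
        if kind == "ex":
            a, c = x[i], x[i + 1]
            i += 2
            pts += [[a, 0.0, c], [-a, 0.0, c]]
        elif kind == "ey":
            b, c = x[i], x[i + 1]
            i += 2
            pts += [[0.0, b, c], [0.0, -b, c]]
        else:
            a, b, c = x[i], x[i + 1], x[i + 2]
            i += 3
            pts += [[a, b, c], [-a, b, c], [a, -b, c], [-a, -b, c]]
    return np.array(pts)


def _try_realize(param_to_points, x0, expect_v, expect_fv, merge_angle=0.25):
    try:
        pts = realize(param_to_points, x0, merge_angle=merge_angle)
        if not np.isfinite(pts).all() or np.abs(pts).max() > 50.0:
            return None
        v, e, fv = validate_regular_solid(pts, tol=1e-7)
    except (GeometryError, QhullError, ValueError, IndexError):
        return None
    if v == expect_v and fv == expect_fv:
        return pts
    return None


def _multistart(param_to_points, sampler, expect_v, expect_fv, seed, tries=400):
    rng = np.random.default_rng(seed)
    for _ in range(tries):
        pts = _try_realize(param_to_points, sampler(rng), expect_v, expect_fv)
        if pts is not None:
            return pts
    raise GeometryError("multistart realization failed")


def j85():
    """Snub square antiprism (D4d): two squares + 24 triangles."""

    def build(x):
        zt, zm, rm, ps = x
        top = ring(4, zt, 0.0)
        bot = ring(4, -zt, math.pi / 4.0)
        mid1 = ring(4, zm, ps, radius=rm)
        mid2 = ring(4, -zm, ps + math.pi / 4.0, radius=rm)
        return np.vstack([top, mid1, mid2, bot])

    def sampler(rng):
        return [rng.uniform(0.6, 1.1), rng.uniform(0.05, 0.45),
                rng.uniform(0.9, 1.4), rng.uniform(0.0, math.pi / 2)]

    return _multistart(build, sampler, 16, {3: 24, 4: 2}, seed=20240) 


def j86():
    """Sphenocorona (C2v): wedge of two squares + corona of 12 triangles."""
    orbits = ["ex", "q", "ex", "ey"]

    def build(x):
        return _c2v_points(np.concatenate([[0.5], x[:1], [0.5], x[1:]]), orbits) \
            if False else _c2v_points(
                np.array([0.5, x[0], 0.5, x[1], x[2], x[3], x[4], x[5], x[6]]),
                orbits)

    def sampler(rng):
        return np.array([
            rng.uniform(0.4, 1.1),            # z of wedge top edge
            rng.uniform(0.5, 1.1), rng.uniform(-0.6, 0.3),   # square quad y,z
            rng.uniform(0.7, 1.5), rng.uniform(-0.8, 0.2),   # side pair x,z
            rng.uniform(0.4, 1.2), rng.uniform(-1.2, -0.2),  # keel pair y,z
        ])

    return _multistart(build, sampler, 10, {3: 12, 4: 2}, seed=8601)


def j87():
    """Augmented sphenocorona: square pyramid on one square of J86."""
    base = j86()
    for f in _faces_of_size(base, 4):
        try:
            cand = augment_pyramid(base, f)
            validate_regular_solid(cand)
            return cand
        except GeometryError:
            continue
    raise GeometryError("no valid augmentation site on J86")


def j88():
    """Sphenomegacorona: wedge of two squares + 16-triangle megacorona.

    The face structure (recovered by exhaustive enumeration of the
    12-vertex triangulations completing the two-square wedge, degree
    sequence 4^4 5^8) is fixed, and the coordinates are the unique
    convex unit-edge realization, solved by least squares from a
    spectral embedding of the graph.
    """
    faces = [[0, 2, 3, 1], [0, 1, 5, 4], [2, 0, 6], [0, 4, 6], [2, 6, 7],
             [6, 4, 7], [2, 7, 8], [7, 4, 9], [3, 2, 8], [8, 7, 9],
             [9, 4, 5], [8, 9, 10], [3, 8, 10], [9, 5, 10], [3, 10, 11],
             [10, 5, 11], [1, 3, 11], [5, 1, 11]]
    edges = sorted({tuple(sorted((f[i], f[(i + 1) % len(f)])))
                    for f in faces for i in range(len(f))})
    sq_diag = [(0, 3), (2, 1), (0, 5), (1, 4)]

    A = np.zeros((12, 12))
    for a, b in edges:
        A[a, b] = A[b, a] = 1.0
    _, vecs = np.linalg.eigh(np.diag(A.sum(1)) - A)
    x0 = vecs[:, 1:4]
    x0 /= np.linalg.norm(x0, axis=1, keepdims=True)
    x0 *= 1.3

    def fun(x):
        P = x.reshape(12, 3)
        res = [np.linalg.norm(P[a] - P[b]) - 1.0 for a, b in edges]
        res += [np.linalg.norm(P[a] - P[b]) - math.sqrt(2.0)
                for a, b in sq_diag]
        return np.array(res)

    sol = least_squares(fun, x0.ravel(), xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if np.abs(sol.fun).max() > 1e-9:
        raise GeometryError("sphenomegacorona realization failed")
    pts = sol.x.reshape(12, 3)
    return pts - pts.mean(axis=0)


def j89():
    """Hebesphenomegacorona (C2v): blunt 3-square wedge + 18 triangles."""

    def build_a(x):
        return _c2v_points(np.asarray(x), ["q", "q", "ex", "ey", "ey"])

    def sampler_a(rng):
        return np.array([
            0.5, rng.uniform(0.3, 0.9), rng.uniform(0.4, 1.1),   # top square
            0.5, rng.uniform(0.7, 1.5), rng.uniform(-0.4, 0.4),  # side squares
            rng.uniform(0.6, 1.6), rng.uniform(-0.8, 0.2),
            rng.uniform(0.3, 1.2), rng.uniform(-1.2, -0.1),
            rng.uniform(0.2, 1.0), rng.uniform(-1.5, -0.3),
        ])

    def build_b(x):
        return _c2v_points(np.asarray(x), ["q", "q", "q", "ey"])

    def sampler_b(rng):
        return np.array([
            0.5, rng.uniform(0.3, 0.9), rng.uniform(0.4, 1.1),
            0.5, rng.uniform(0.7, 1.5), rng.uniform(-0.4, 0.4),
            rng.uniform(0.4, 1.3), rng.uniform(0.3, 1.2), rng.uniform(-1.0, 0.0),
            rng.uniform(0.2, 1.0), rng.uniform(-1.6, -0.4),
        ])

    for build, sampler in ((build_a, sampler_a), (build_b, sampler_b)):
        try:
            return _multistart(build, sampler, 14, {3: 18, 4: 3}, seed=8901,
                               tries=250)
        except GeometryError:
            continue
    raise GeometryError("hebesphenomegacorona realization failed")


def j90():
    """Disphenocingulum (D2d): two orthogonal 2-square wedges + 20 triangles."""

    def build(x):
        z1, y2, z2, x3, y3, z3 = x
        top = [[0.5, 0.0, z1], [-0.5, 0.0, z1],
               [0.5, y2, z2], [-0.5, y2, z2], [0.5, -y2, z2], [-0.5, -y2, z2]]
        top = np.array(top)
        bot = np.array(top)
        bot = bot[:, [1, 0, 2]]
        bot[:, 2] *= -1.0
        belt = np.array([[x3, y3, z3], [-x3, -y3, z3],
                         [y3, -x3, -z3], [-y3, x3, -z3]])
        return np.vstack([top, bot, belt])

    def sampler(rng):
        return np.array([
            rng.uniform(0.7, 1.4),
            rng.uniform(0.5, 1.2), rng.uniform(0.3, 1.0),
            rng.uniform(0.5, 1.4), rng.uniform(0.0, 1.0), rng.uniform(-0.5, 0.5),
        ])

    return _multistart(build, sampler, 16, {3: 20, 4: 4}, seed=9001, tries=400)


def j91():
    """Bilunabirotunda (D2h): two lunes (square + 2 triangles) along +-x,
    two rotunda apexes along +-y, joined by 4 pentagons."""

    def build(x):
        x2, x4, z4, y5 = x
        pts = []
        for sx in (1, -1):
            for sy in (1, -1):
                for sz in (1, -1):
                    pts.append([sx * x2, sy * 0.5, sz * 0.5])
        for sx in (1, -1):
            for sz in (1, -1):
                pts.append([sx * x4, 0.0, sz * z4])
        pts += [[0.0, y5, 0.0], [0.0, -y5, 0.0]]
        return np.array(pts)

    def sampler(rng):
        return np.array([rng.uniform(0.5, 1.1), rng.uniform(0.9, 1.7),
                         rng.uniform(0.3, 1.0), rng.uniform(0.7, 1.4)])

    return _multistart(build, sampler, 14, {3: 8, 4: 2, 5: 4}, seed=9101,
                       tries=400)


def j92():
    """Triangular hebesphenorotunda (C3v): rotunda-like patch + hexagon."""

    def c3v_ring(r, z, theta):
        # orbit of (r, theta) under C3v about z (mirrors through pi/6 + 2pi k/3)
        angs = []
        for k in range(3):
            base = math.pi / 6.0 + 2.0 * math.pi * k / 3.0
            angs += [base + theta, base - theta]
        pts = [[r * math.cos(a), r * math.sin(a), z] for a in angs]
        return np.array(pts)

    def build(x):
        r1, z1, r2, z2, t2, r3, z3, r4, z4, t4 = x
        top = ring(3, z1, math.pi / 6.0, radius=r1)
        mid = c3v_ring(r2, z2, t2)
        low = ring(3, z3, math.pi / 6.0 + math.pi / 3.0, radius=r3)
        bot = c3v_ring(r4, z4, t4)
        return np.vstack([top, mid, low, bot])

    # seed the rotunda-like upper patch from an icosidodecahedron oriented
    # with a triangular face on top, and the closing hexagon below it
    ico = icosidodecahedron()
    _, faces = derive_faces(ico)
    tri = next(f for f in faces if len(f) == 3)
    c, _n = _face_centroid_normal(ico, tri)
    axis = c / np.linalg.norm(c)
    zhat = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, zhat)
    sn, cs = np.linalg.norm(v), axis @ zhat
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    R = np.eye(3) + vx + vx @ vx * ((1 - cs) / (sn * sn))
    pts = ico @ R.T
    order = np.argsort(-pts[:, 2])
    top3 = pts[order[:3]]
    mid6 = pts[order[3:9]]
    low3 = pts[order[9:12]]
    theta2 = abs(math.atan2(mid6[0, 1], mid6[0, 0])) % (2 * math.pi / 3)
    theta2 = min(abs(theta2 - math.pi / 6), abs(math.pi / 2 - theta2))
    base = [
        float(np.linalg.norm(top3[0, :2])), float(top3[0, 2]),
        float(np.linalg.norm(mid6[0, :2])), float(mid6[0, 2]), 0.388,
        float(np.linalg.norm(low3[0, :2])), float(low3[0, 2]),
    ]

    def sampler(rng):
        th4 = rng.choice([math.pi / 6.0, math.pi / 2.0])
        x0 = np.array(base + [rng.uniform(0.9, 1.2),
                              base[6] - rng.uniform(0.4, 1.0), th4])
        x0[:7] += rng.normal(0.0, 0.05, size=7)
        return x0

    return _multistart(build, sampler, 18, {3: 13, 4: 3, 5: 3, 6: 1},
                       seed=9201, tries=200)
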