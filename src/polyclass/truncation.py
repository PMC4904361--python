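"""Missing-wedge simulation: random rotation + parallel-plane truncation.

The anisotropic resolution of a tomographic reconstruction is modelled by
clipping a reference polyhedron with two parallel planes perpendicular to
a randomly oriented truncation axis, at symmetric distances +-d from the
vertex centroid.  The normalized truncation percentage p relates to the
plane distance by p = 200 (1 - d/d_max), where d_max is the largest
vertex-to-centroid distance, so p = 0 leaves the solid untouched and
p -> 100 cuts it down to a thin central slab.

Two implementations are provided: an exact-clipping object path that
returns full `PolyhedralGraph` objects, and a vectorized fast path
(`TruncationSampler`) that maps batches of orientations straight to
231-dimensional topological profiles.  A classical l-point edge
discretization is retained as an independent test oracle
(`discretized_edge_classification`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .features import TP_DIM, TopologicalProfile, compute_profile
from .graph import PolyhedralGraph


@dataclass
class TruncationConfig:
    """Parameters of one truncation job.

    truncation_percent: normalized truncation percentage in [0, 100).
    phi: orientation angles (phi_x, phi_y), each in [0, 2 pi); None for random.
    edge_discretization: points per edge for the discretized oracle (>= 2).
    seed: seed of the random stream.
    """

    truncation_percent: float = 20.0
    phi: tuple[float, float] | None = None
    edge_discretization: int = 50
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.truncation_percent < 100.0:
            raise ValueError("truncation_percent must be in [0, 100)")
        if self.edge_discretization < 2:
            raise ValueError("edge_discretization must be >= 2")

    def plane_distance(self, d_max: float) -> float:
        return d_max * (1.0 - self.truncation_percent / 200.0)


def sample_orientation(rng: np.random.Generator) -> tuple[float, float]:
    """Draw phi = (phi_x, phi_y) ~ U[0, 2pi) x U[0, 2pi)."""
    a, b = rng.uniform(0.0, 2.0 * math.pi, size=2)
    return float(a), float(b)


def rotation_matrix(phi: tuple[float, float]) -> np.ndarray:
    """R_phi = Ry(phi_y) @ Rx(phi_x): rotations about the x then y axis."""
    ax, ay = phi
    ca, sa = math.cos(ax), math.sin(ax)
    cb, sb = math.cos(ay), math.sin(ay)
    Rx = np.array([[1.0, 0.0, 0.0], [0.0, ca, -sa], [0.0, sa, ca]])
    Ry = np.array([[cb, 0.0, sb], [0.0, 1.0, 0.0], [-sb, 0.0, cb]])
    return Ry @ Rx


def truncation_axis(phi: tuple[float, float]) -> np.ndarray:
    """Unit vector u with u.v = rotated z-coordinate of v (third row of R)."""
    ax, ay = phi
    return np.array([-math.sin(ay), math.cos(ay) * math.sin(ax),
                     math.cos(ay) * math.cos(ax)])


def truncate(polyhedron, phi, d) -> PolyhedralGraph:
    """Clip a polyhedron with two parallel planes; return the observed PG.

    Vertices are rotated by R_phi about the vertex centroid; a vertex is
    retained iff its coordinate along the rotated z-axis lies within
    [-d, +d] (boundary retained).  Edges with both endpoints retained are
    complete; edges crossing a plane are clipped at the plane and become
    incomplete (free end on the plane).  Faces with all vertices retained
    are complete; faces with at least one visible edge are incomplete and
    carry their visible edges.  Edge segments whose both endpoints are
    clipped away carry no vertex identity and are dropped.
    """
    if d <= 0:
        raise ValueError("plane distance d must be positive")
    V = np.asarray(polyhedron.vertices, dtype=float)
    mu = V.mean(axis=0)
    R = rotation_matrix(phi)
    P = (V - mu) @ R.T
    z = P[:, 2]
    keep = np.abs(z) <= d

    complete_edges: list[tuple[int, int]] = []
    complete_index: dict[tuple[int, int], int] = {}
    incomplete_edges: list[tuple[int, np.ndarray]] = []
    edge_status: dict[tuple[int, int], tuple[str, int]] = {}

    for a, b in polyhedron.edges:
        a, b = int(a), int(b)
        key = (min(a, b), max(a, b))
        ka, kb = keep[a], keep[b]
        if ka and kb:
            complete_index[key] = len(complete_edges)
            complete_edges.append(key)
            edge_status[key] = ("c", complete_index[key])
        elif ka or kb:
            vin, vout = (a, b) if ka else (b, a)
            plane = d if z[vout] > 0 else -d
            t = (plane - z[vin]) / (z[vout] - z[vin])
            end = P[vin] + t * (P[vout] - P[vin])
            edge_status[key] = ("p", len(incomplete_edges))
            incomplete_edges.append((vin, end))
        # else: both endpoints clipped; any crossing segment is dropped

    complete_faces: list[list[int]] = []
    incomplete_faces: list[list[tuple[str, int]]] = []
    for cyc in polyhedron.faces:
        cyc = [int(v) for v in cyc]
        if all(keep[v] for v in cyc):
            complete_faces.append(cyc)
            continue
        refs = []
        for i in range(len(cyc)):
            a, b = cyc[i], cyc[(i + 1) % len(cyc)]
            st = edge_status.get((min(a, b), max(a, b)))
            if st is not None:
                refs.append(st)
        if refs:
            incomplete_faces.append(refs)

    pg = PolyhedralGraph(
        vertices={int(i): P[i] for i in np.flatnonzero(keep)},
        complete_edges=complete_edges,
        incomplete_edges=incomplete_edges,
        complete_faces=complete_faces,
        incomplete_faces=incomplete_faces,
    )
    pg.validate()
    return pg


def discretized_edge_classification(polyhedron, phi, d, l: int = 50):
    """Discretized-edge classification oracle (l points per edge).

    Each edge is discretized into l equispaced points (endpoints
    included); an edge is complete if all its points survive the slab,
    partial if some do, absent if none do.  Returns a dict
    edge -> 'complete' | 'partial' | 'absent'.
    """
    if l < 2:
        raise ValueError("need at least 2 points per edge")
    V = np.asarray(polyhedron.vertices, dtype=float)
    mu = V.mean(axis=0)
    R = rotation_matrix(phi)
    P = (V - mu) @ R.T
    out = {}
    ts = np.linspace(0.0, 1.0, l)[:, None]
    for a, b in polyhedron.edges:
        a, b = int(a), int(b)
        seg = P[a] + ts * (P[b] - P[a])
        inside = np.abs(seg[:, 2]) <= d
        if inside.all():
            status = "complete"
        elif inside.any():
            status = "partial"
        else:
            status = "absent"
        out[(min(a, b), max(a, b))] = status
    return out


def perturb_delete_vertex(pg: PolyhedralGraph, rng: np.random.Generator,
                          mode: str = "remove") -> PolyhedralGraph:
    """Mis-specify a PG by deleting one uniformly chosen observed vertex.

    mode="remove" (default): the vertex and all its incident edges,
    complete and incomplete, are removed entirely; faces that used the
    vertex become incomplete faces carrying their surviving visible
    edges.  This is the literal missed-vertex-and-linked-edges error
    model used in the robustness study.

    mode="censor": the vertex is removed but its complete edges survive
    as incomplete edges anchored at the other endpoint (the edge was
    seen, its far vertex was not), and faces keep those stubs among
    their visible edges.  This milder error model treats the miss like
    additional censoring and is provided for sensitivity analysis.
    """
    if pg.n_vertices == 0:
        raise ValueError("cannot delete a vertex from an empty graph")
    if mode not in ("remove", "censor"):
        raise ValueError(f"unknown deletion mode {mode!r}")
    ids = sorted(pg.vertices)
    victim = ids[int(rng.integers(len(ids)))]
    vpos = pg.vertices[victim]

    new_cedges: list[tuple[int, int]] = []
    cmap: dict[int, int] = {}
    stubs: list[tuple[int, int]] = []  # (old complete idx, kept endpoint)
    for k, (a, b) in enumerate(pg.complete_edges):
        if victim in (a, b):
            stubs.append((k, b if a == victim else a))
            continue
        cmap[k] = len(new_cedges)
        new_cedges.append((a, b))
    new_pedges: list[tuple[int, np.ndarray]] = []
    pmap: dict[int, int] = {}
    for k, (v, end) in enumerate(pg.incomplete_edges):
        if v == victim:
            continue
        pmap[k] = len(new_pedges)
        new_pedges.append((v, end))
    conv: dict[int, int] = {}
    if mode == "censor":
        for k, keepv in stubs:
            conv[k] = len(new_pedges)
            new_pedges.append((keepv, np.asarray(vpos, dtype=float)))

    def remap(refs):
        out = []
        for kind, k in refs:
            if kind == "c":
                if k in cmap:
                    out.append(("c", cmap[k]))
                elif k in conv:
                    out.append(("p", conv[k]))
            elif kind == "p" and k in pmap:
                out.append(("p", pmap[k]))
        return out

    new_cfaces: list[list[int]] = []
    new_ifaces: list[list[tuple[str, int]]] = []
    cidx = {e: k for k, e in enumerate(pg.complete_edges)}
    for cyc in pg.complete_faces:
        if victim not in cyc:
            new_cfaces.append(list(cyc))
            continue
        refs = []
        for i in range(len(cyc)):
            a, b = cyc[i], cyc[(i + 1) % len(cyc)]
            refs += remap([("c", cidx[(min(a, b), max(a, b))])])
        if refs:
            new_ifaces.append(refs)
    for refs in pg.incomplete_faces:
        refs2 = remap(refs)
        if refs2:
            new_ifaces.append(refs2)

    out = PolyhedralGraph(
        vertices={v: p for v, p in pg.vertices.items() if v != victim},
        complete_edges=new_cedges,
        incomplete_edges=new_pedges,
        complete_faces=new_cfaces,
        incomplete_faces=new_ifaces,
    )
    out.validate()
    return out


# --------------------------------------------------------------------------
# vectorized profile sampler

class TruncationSampler:
    """Fast batch computation of truncated topological profiles.

    Precomputes the incidence structure of one polyhedron so that each
    orientation costs a handful of vectorized operations.  Agrees exactly
    with `truncate` + `compute_profile` (cross-checked in the test suite).
    """

    def __init__(self, polyhedron):
        V = np.asarray(polyhedron.vertices, dtype=float)
        self.Vc = V - V.mean(axis=0)
        self.d_max = float(np.linalg.norm(self.Vc, axis=1).max())
        self.E = np.asarray(polyhedron.edges, dtype=np.int64)
        self.m = len(V)
        self.e = len(self.E)
        faces = [list(map(int, f)) for f in polyhedron.faces]
        self.face_sizes = np.array([len(f) for f in faces], dtype=np.int64)
        self.F = len(faces)

        rows_v, cols_v, rows_e, cols_e = [], [], [], []
        edge_idx = {(min(a, b), max(a, b)): k for k, (a, b) in enumerate(self.E)}
        flanks = [[] for _ in range(self.e)]
        for fi, cyc in enumerate(faces):
            for i, v in enumerate(cyc):
                rows_v.append(fi)
                cols_v.append(v)
                a, b = v, cyc[(i + 1) % len(cyc)]
                k = edge_idx[(min(a, b), max(a, b))]
                rows_e.append(fi)
                cols_e.append(k)
                flanks[k].append(fi)
        self.M_fv = sparse.csr_matrix(
            (np.ones(len(rows_v)), (rows_v, cols_v)), shape=(self.F, self.m))
        self.M_fe = sparse.csr_matrix(
            (np.ones(len(rows_e)), (rows_e, cols_e)), shape=(self.F, self.e))
        if any(len(fl) != 2 for fl in flanks):
            raise ValueError("every edge must flank exactly two faces")
        self.flanks = np.array(flanks, dtype=np.int64)
        # vertex-edge incidence split by endpoint slot (for batched degrees)
        ar = np.arange(self.e)
        one = np.ones(self.e)
        self.B0 = sparse.csr_matrix((one, (self.E[:, 0], ar)),
                                    shape=(self.m, self.e))
        self.B1 = sparse.csr_matrix((one, (self.E[:, 1], ar)),
                                    shape=(self.m, self.e))
        if self.e:
            max_edge = np.linalg.norm(
                self.Vc[self.E[:, 0]] - self.Vc[self.E[:, 1]], axis=1).max()
        else:
            max_edge = 0.0
        #: no edge may cross both planes, else clipped middle segments occur
        self.min_supported_d = max_edge / 2.0

    def plane_distance(self, percent: float) -> float:
        return self.d_max * (1.0 - percent / 200.0)

    def profile_for_axis(self, axis_row: np.ndarray, d: float) -> np.ndarray:
        """Profile (231,) for one truncation axis (unit 3-vector)."""
        vec = np.zeros(TP_DIM, dtype=np.int64)
        z = self.Vc @ axis_row
        keep = np.abs(z) <= d
        e0, e1 = self.E[:, 0], self.E[:, 1]
        k0, k1 = keep[e0], keep[e1]
        complete = k0 & k1
        partial = k0 ^ k1
        visible = complete | partial

        ends = np.concatenate([e0[complete], e1[complete],
                               np.where(k0, e0, e1)[partial]])
        deg_obs = np.bincount(ends, minlength=self.m)
        pinc = np.bincount(np.where(k0, e0, e1)[partial], minlength=self.m)

        nkept_per_face = self.M_fv @ keep
        face_complete = nkept_per_face == self.face_sizes
        nvis = (self.M_fe @ visible).astype(np.int64)
        face_incomplete = (~face_complete) & (nvis > 0)

        vec[0] = int(keep.sum())
        vec[1] = int(visible.sum())
        vec[2] = int(face_complete.sum())

        # complete face distribution
        cs = np.clip(self.face_sizes[face_complete], 3, 8)
        vec[3:9] = np.bincount(cs - 3, minlength=6)[:6]

        # complete vertex distribution (no incident incomplete edge)
        full = keep & (pinc == 0) & (deg_obs >= 3)
        vd = np.clip(deg_obs[full], 3, 8)
        vec[9:15] = np.bincount(vd - 3, minlength=6)[:6]

        # censored face distribution over visible faces
        s_obs = np.where(face_complete, self.face_sizes, nvis)
        s_vis = np.clip(s_obs[face_complete | face_incomplete], 0, 10)
        cnt = np.bincount(s_vis, minlength=11)
        tail = np.cumsum(cnt[::-1])[::-1]  # tail[k] = #faces with s >= k
        vec[15:23] = tail[3:11]

        # censored vertex distribution over observed vertices
        dv = np.clip(deg_obs[keep], 0, 10)
        cnt = np.bincount(dv, minlength=11)
        tail = np.cumsum(cnt[::-1])[::-1]
        vec[23:31] = tail[3:11]

        # EV
        ev = np.zeros(100, dtype=np.int64)
        dc = np.clip(deg_obs, 1, 10)
        i_c, j_c = dc[e0[complete]], dc[e1[complete]]
        i_p = dc[np.where(k0, e0, e1)[partial]]
        j_p = np.ones_like(i_p)
        I = np.concatenate([i_c, i_p])
        J = np.concatenate([j_c, j_p])
        np.add.at(ev, (I - 1) * 10 + (J - 1), 1)
        off = I != J
        np.add.at(ev, (J[off] - 1) * 10 + (I[off] - 1), 1)
        vec[31:131] = ev

        # FV (both flanks of a visible edge are visible faces)
        fv = np.zeros(100, dtype=np.int64)
        sclip = np.clip(s_obs, 1, 10)
        fl = self.flanks[visible]
        I = sclip[fl[:, 0]]
        J = sclip[fl[:, 1]]
        np.add.at(fv, (I - 1) * 10 + (J - 1), 1)
        off = I != J
        np.add.at(fv, (J[off] - 1) * 10 + (I[off] - 1), 1)
        vec[131:231] = fv
        return vec

    def profiles(self, phis: np.ndarray, percent: float) -> np.ndarray:
        """Profiles (n, 231) for an (n, 2) array of orientation angles."""
        phis = np.atleast_2d(np.asarray(phis, dtype=float))
        d = self.plane_distance(percent)
        if d < self.min_supported_d:
            raise ValueError(
                f"truncation {percent}% leaves d={d:.3f} below the "
                f"supported minimum {self.min_supported_d:.3f} "
                "(edges would cross both planes)")
        axes = np.stack([truncation_axis(phi) for phi in phis])
        return self._profiles_batch(axes, d)

    def _profiles_batch(self, axes: np.ndarray, d: float) -> np.ndarray:
        """Vectorized computation of profiles for a batch of axes."""
        n = len(axes)
        out = np.zeros((n, TP_DIM), dtype=np.int64)
        cols = np.arange(n, dtype=np.int64)

        Z = self.Vc @ axes.T                      # (m, n)
        keep = np.abs(Z) <= d
        e0, e1 = self.E[:, 0], self.E[:, 1]
        K0, K1 = keep[e0], keep[e1]               # (e, n)
        complete = K0 & K1
        partial = K0 ^ K1
        visible = complete | partial

        p0 = partial & K0
        p1 = partial & K1
        pinc = (self.B0 @ p0 + self.B1 @ p1).astype(np.int64)
        deg_obs = ((self.B0 + self.B1) @ complete).astype(np.int64) + pinc

        nkept = (self.M_fv @ keep).astype(np.int64)          # (F, n)
        face_complete = nkept == self.face_sizes[:, None]
        nvis = (self.M_fe @ visible).astype(np.int64)
        face_visible = face_complete | ((~face_complete) & (nvis > 0))
        s_obs = np.where(face_complete, self.face_sizes[:, None], nvis)

        out[:, 0] = keep.sum(axis=0)
        out[:, 1] = visible.sum(axis=0)
        out[:, 2] = face_complete.sum(axis=0)

        cs = np.clip(self.face_sizes, 3, 8)[:, None]
        for k in range(3, 9):
            out[:, k] = (face_complete & (cs == k)).sum(axis=0)

        full = keep & (pinc == 0)
        dclip = np.clip(deg_obs, 0, 8)
        for k in range(3, 9):
            out[:, 6 + k] = (full & (dclip == k)).sum(axis=0)

        for k in range(3, 11):
            out[:, 12 + k] = (face_visible & (s_obs >= k)).sum(axis=0)
        for k in range(3, 11):
            out[:, 20 + k] = (keep & (deg_obs >= k)).sum(axis=0)

        # EV over all edges (missing endpoint -> bin 1)
        dc = np.clip(deg_obs, 1, 10)
        I = np.where(K0, dc[e0], 1)
        J = np.where(K1, dc[e1], 1)
        flat = np.broadcast_to(cols * 100, I.shape) + (I - 1) * 10 + (J - 1)
        flat_t = np.broadcast_to(cols * 100, I.shape) + (J - 1) * 10 + (I - 1)
        ev = np.bincount(flat[visible], minlength=100 * n)
        off = visible & (I != J)
        ev += np.bincount(flat_t[off], minlength=100 * n)
        out[:, 31:131] = ev.reshape(n, 100)

        # FV over all edges (both flanks of a visible edge are visible)
        sclip = np.clip(s_obs, 1, 10)
        I = sclip[self.flanks[:, 0]]
        J = sclip[self.flanks[:, 1]]
        flat = np.broadcast_to(cols * 100, I.shape) + (I - 1) * 10 + (J - 1)
        flat_t = np.broadcast_to(cols * 100, I.shape) + (J - 1) * 10 + (I - 1)
        fv = np.bincount(flat[visible], minlength=100 * n)
        off = visible & (I != J)
        fv += np.bincount(flat_t[off], minlength=100 * n)
        out[:, 131:231] = fv.reshape(n, 100)
        return out


def generate_ttps(polyhedron, n: int, truncation_percent: float,
                  seed) -> np.ndarray:
    """n truncated topological profiles at a fixed truncation percent.

    Orientations are sampled independently from the seeded stream; the
    result is an (n, 231) integer array, deterministic given the seed.
    """
    if n < 1:
        raise ValueError("need n >= 1 orientations")
    rng = np.random.default_rng(seed)
    phis = rng.uniform(0.0, 2.0 * math.pi, size=(n, 2))
    sampler = polyhedron.sampler if hasattr(polyhedron, "sampler") else \
        TruncationSampler(polyhedron)
    return sampler.profiles(phis, truncation_percent)


def generate_ttp_objects(polyhedron, n, truncation_percent, seed):
    """Like `generate_ttps` but via the object path (PG + profile)."""
    rng = np.random.default_rng(seed)
    d_max = float(np.linalg.norm(
        np.asarray(polyhedron.vertices) -
        np.asarray(polyhedron.vertices).mean(axis=0), axis=1).max())
    d = d_max * (1.0 - truncation_percent / 200.0)
    out = []
    for _ in range(n):
        phi = sample_orientation(rng)
        out.append(compute_profile(truncate(polyhedron, phi, d)))
    return out


def unique_ttp_curve(profiles: np.ndarray) -> np.ndarray:
    """Cumulative number of unique profiles after 1..n draws."""
    seen = set()
    out = np.empty(len(profiles), dtype=np.int64)
    for i, row in enumerate(profiles):
        seen.add(row.tobytes())
        out[i] = len(seen)
    return out


def profile_objects(array: np.ndarray) -> list[TopologicalProfile]:
    return [TopologicalProfile(row) for row in np.atleast_2d(array)]
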