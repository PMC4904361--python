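"""Topological profiles of (possibly incomplete) polyhedral graphs.

The topological profile (TP) is a 231-dimensional integer feature vector
summarizing a polyhedral graph:

======================  ====  =========================================
block                   dim   content
======================  ====  =========================================
global                   3    V (observed vertices), E (all edges,
                              complete + incomplete), F (complete faces)
face type                6    F3..F8: complete faces by edge count
vertex degree            6    V3..V8: fully observed vertices by degree
at-least face type       8    F3+..F10+: faces with >= k observed edges
at-least vertex degree   8    V3+..V10+: vertices with observed degree >= k
edge adjacency EV       100   10x10, edges by (degree, degree) of endpoints
face adjacency FV       100   10x10, edges by (size, size) of flanking faces
======================  ====  =========================================

The "at least" blocks are cumulative right-censored counts: a partially
visible face with v observed edges has at least v edges, so it counts
towards F_k+ for all k <= v; an observed vertex's degree (counting
incomplete incident edges) is a lower bound on its true degree.  In EV and
FV, information censored away by the missing wedge (an unobserved edge
endpoint, a never-seen flanking face) is binned at the lowest index 1;
observed quantities are clipped into 1..10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import PGError, PolyhedralGraph

TP_DIM = 231

# index layout
_GLOBAL = slice(0, 3)
_FDIST = slice(3, 9)      # F3..F8
_VDIST = slice(9, 15)     # V3..V8
_FCENS = slice(15, 23)    # F3+..F10+
_VCENS = slice(23, 31)    # V3+..V10+
_EV = slice(31, 131)
_FV = slice(131, 231)

#: Table-style feature subsets used in the subset-classification study.
#: "complete" features are computed from fully observed structures only;
#: "incomplete" features incorporate censored (partially observed)
#: information -- this includes V, E, F, which are right-censored counts
#: for truncated objects.
SUBSETS: dict[str, np.ndarray] = {}


def _build_subsets():
    idx = np.arange(TP_DIM)
    SUBSETS["all"] = idx
    SUBSETS["global"] = idx[_GLOBAL]
    SUBSETS["local"] = idx[3:]
    SUBSETS["complete"] = np.concatenate([idx[_FDIST], idx[_VDIST]])
    SUBSETS["incomplete"] = np.concatenate(
        [idx[_GLOBAL], idx[_FCENS], idx[_VCENS], idx[_EV], idx[_FV]])


_build_subsets()


def profile_columns() -> list[str]:
    """Column names for the 231 profile components, in vector order."""
    cols = ["V", "E", "F"]
    cols += [f"F{k}" for k in range(3, 9)]
    cols += [f"V{k}" for k in range(3, 9)]
    cols += [f"F{k}p" for k in range(3, 11)]
    cols += [f"V{k}p" for k in range(3, 11)]
    cols += [f"EV_{i}_{j}" for i in range(1, 11) for j in range(1, 11)]
    cols += [f"FV_{i}_{j}" for i in range(1, 11) for j in range(1, 11)]
    return cols


@dataclass(frozen=True)
class TopologicalProfile:
    """231-dimensional topological profile with named blocks."""

    vector: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vector, dtype=np.int64)
        if v.shape != (TP_DIM,):
            raise ValueError(f"profile must have {TP_DIM} components")
        object.__setattr__(self, "vector", v)

    # block views -----------------------------------------------------------
    @property
    def global_block(self):
        return self.vector[_GLOBAL]

    @property
    def face_dist(self):
        return self.vector[_FDIST]

    @property
    def vertex_dist(self):
        return self.vector[_VDIST]

    @property
    def face_censored(self):
        return self.vector[_FCENS]

    @property
    def vertex_censored(self):
        return self.vector[_VCENS]

    @property
    def EV(self):
        return self.vector[_EV].reshape(10, 10)

    @property
    def FV(self):
        return self.vector[_FV].reshape(10, 10)

    @property
    def hash(self) -> str:
        return profile_hash(self)

    def __eq__(self, other):
        return isinstance(other, TopologicalProfile) and \
            bool(np.array_equal(self.vector, other.vector))

    def __hash__(self):
        return hash(self.vector.tobytes())


def profile_hash(profile) -> str:
    """Canonical string key of a profile (injective on profiles)."""
    vec = profile.vector if isinstance(profile, TopologicalProfile) else profile
    vec = np.asarray(vec, dtype=np.int64)
    blocks = [vec[_GLOBAL], vec[_FDIST], vec[_VDIST], vec[_FCENS],
              vec[_VCENS], vec[_EV], vec[_FV]]
    return "|".join(",".join(str(int(x)) for x in b) for b in blocks)


def parse_profile_hash(text: str) -> TopologicalProfile:
    parts = text.split("|")
    if len(parts) != 7:
        raise ValueError("malformed profile hash")
    vals = [int(x) for p in parts for x in p.split(",")]
    return TopologicalProfile(np.array(vals, dtype=np.int64))


def _clip_bin(x: int, lo: int, hi: int) -> int:
    return min(max(x, lo), hi)


def compute_profile(pg: PolyhedralGraph) -> TopologicalProfile:
    """Topological profile of a polyhedral graph (complete or truncated).

    Complete distributions use only fully observed features: a vertex is
    fully observed when it has no incident incomplete edge; a face is
    fully observed when it is a closed cycle of complete edges.  Censored
    distributions use observed lower bounds over all features.
    """
    pg.validate()
    vec = np.zeros(TP_DIM, dtype=np.int64)

    deg_obs = pg.observed_degrees()
    n_inc = pg.incomplete_incident_counts()

    # global block: observed vertices, all edges, complete faces
    vec[0] = pg.n_vertices
    vec[1] = pg.n_edges
    vec[2] = len(pg.complete_faces)

    # complete face-type distribution F3..F8 (oversize clipped into F8)
    fdist = np.zeros(6, dtype=np.int64)
    for cyc in pg.complete_faces:
        k = _clip_bin(len(cyc), 3, 8)
        fdist[k - 3] += 1
    vec[_FDIST] = fdist

    # complete vertex-degree distribution V3..V8 over fully observed
    # vertices; degrees below 3 (possible only for mis-specified graphs)
    # fall outside the bins and are not counted
    vdist = np.zeros(6, dtype=np.int64)
    for v in pg.vertices:
        if n_inc[v] == 0 and deg_obs[v] >= 3:
            vdist[_clip_bin(deg_obs[v], 3, 8) - 3] += 1
    vec[_VDIST] = vdist

    # censored face distribution over all visible faces
    fcens = np.zeros(8, dtype=np.int64)
    sizes = [len(cyc) for cyc in pg.complete_faces]
    sizes += [len(refs) for refs in pg.incomplete_faces]
    for s in sizes:
        for k in range(3, min(s, 10) + 1):
            fcens[k - 3] += 1
    vec[_FCENS] = fcens

    # censored vertex distribution over all observed vertices
    vcens = np.zeros(8, dtype=np.int64)
    for v in pg.vertices:
        for k in range(3, min(deg_obs[v], 10) + 1):
            vcens[k - 3] += 1
    vec[_VCENS] = vcens

    # EV: all edges by endpoint observed degrees (missing endpoint -> 1)
    EV = np.zeros((10, 10), dtype=np.int64)

    def add_sym(M, i, j):
        M[i - 1, j - 1] += 1
        if i != j:
            M[j - 1, i - 1] += 1

    for a, b in pg.complete_edges:
        add_sym(EV, _clip_bin(deg_obs[a], 1, 10), _clip_bin(deg_obs[b], 1, 10))
    for v, _ in pg.incomplete_edges:
        add_sym(EV, _clip_bin(deg_obs[v], 1, 10), 1)
    vec[_EV] = EV.ravel()

    # FV: all edges by observed sizes of their flanking faces
    # (a flank never seen -> 1)
    flank_sizes: dict[tuple[str, int], list[int]] = {}
    for cyc in pg.complete_faces:
        edge_keys = []
        for i in range(len(cyc)):
            a, b = cyc[i], cyc[(i + 1) % len(cyc)]
            k = pg.complete_edges.index((min(a, b), max(a, b)))
            edge_keys.append(("c", k))
        for key in edge_keys:
            flank_sizes.setdefault(key, []).append(len(cyc))
    for refs in pg.incomplete_faces:
        s = len(refs)
        for key in refs:
            flank_sizes.setdefault(key, []).append(s)

    FV = np.zeros((10, 10), dtype=np.int64)
    for k in range(len(pg.complete_edges)):
        fl = flank_sizes.get(("c", k), [])[:2]
        while len(fl) < 2:
            fl.append(1)
        add_sym(FV, _clip_bin(fl[0], 1, 10), _clip_bin(fl[1], 1, 10))
    for k in range(len(pg.incomplete_edges)):
        fl = flank_sizes.get(("p", k), [])[:2]
        while len(fl) < 2:
            fl.append(1)
        add_sym(FV, _clip_bin(fl[0], 1, 10), _clip_bin(fl[1], 1, 10))
    vec[_FV] = FV.ravel()

    return TopologicalProfile(vec)


# --------------------------------------------------------------------------
# validation statistics

def coplanarity_test(points) -> float:
    """Coplanarity statistic T = lambda3/lambda2 of the centered scatter.

    The k >= 4 points are centered at their centroid; the eigenvalues
    lambda1 >= lambda2 >= lambda3 of the 3x3 scatter matrix of the
    centered coordinates are computed.  T = 0 for exactly coplanar points
    and approaches 1 for isotropic scatter.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be a k x 3 array")
    if len(pts) < 4:
        raise ValueError("need at least 4 points (3 are always coplanar)")
    q = pts - pts.mean(axis=0)
    lam = np.linalg.eigvalsh(q.T @ q)  # ascending
    lam = np.clip(lam, 0.0, None)
    if lam[1] <= 1e-12 * max(lam[2], 1e-300):
        raise ValueError("degenerate (collinear) point set: lambda2 = 0")
    return float(lam[0] / lam[1])


def validate_faces(pg: PolyhedralGraph, candidate_faces, threshold: float = 0.1):
    """Coplanarity screening of candidate faces.

    Returns a list of (face, T, planar) triples; faces with T > threshold
    are flagged non-planar (to be split by adding edges).  Triangles are
    always planar (T = 0 by convention).
    """
    out = []
    for cyc in candidate_faces:
        for v in cyc:
            if v not in pg.vertices:
                raise PGError(f"candidate face references unknown vertex {v}")
        if len(cyc) == 3:
            t = 0.0
        else:
            t = coplanarity_test([pg.vertices[v] for v in cyc])
        out.append((list(cyc), t, t <= threshold))
    return out


def face_regularity(edge_lengths) -> float:
    """Regularity statistic r_e = s_e / mean(e): sample SD (n-1
    denominator) of a face's edge lengths over their mean.

    Zero for a regular polygon; dimensionless and scale-invariant.
    """
    ls = np.asarray(edge_lengths, dtype=float)
    if ls.ndim != 1 or len(ls) < 2:
        raise ValueError("need at least two edge lengths")
    if np.any(ls <= 0):
        raise ValueError("edge lengths must be positive")
    return float(ls.std(ddof=1) / ls.mean())


def profiles_to_frame(profiles, **extra_cols):
    """One-row-per-profile DataFrame with 231 named columns plus hash."""
    import pandas as pd

    mat = np.array([p.vector for p in profiles], dtype=np.int64)
    df = pd.DataFrame(mat, columns=profile_columns())
    df["hash"] = [p.hash for p in profiles]
    for name, vals in extra_cols.items():
        df.insert(0, name, vals)
    return df
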