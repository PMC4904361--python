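"""The 123-solid reference library and the merged class label space.

The library holds the 5 Platonic, 13 Archimedean, 13 Catalan and 92
Johnson solids, ordered by family and conventional index (Johnson solids
J1..J92 follow their standard enumeration).  Vertex coordinates are
packaged data; edges and faces are derived from the convex hull at load
time, so the stored combinatorics can never drift from the geometry.

Eight pairs of solids share a complete topological profile and are
indistinguishable to any profile-based classifier; `find_duplicate_profiles`
discovers these pairs computationally and builds the merged 115-class
label space used for classification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np

from .features import TopologicalProfile, compute_profile
from .geometry import GeometryError, derive_faces
from .graph import PolyhedralGraph

FAMILIES = ("Platonic", "Archimedean", "Catalan", "Johnson")

_PLATONIC_NAMES = ["tetrahedron", "cube", "octahedron", "dodecahedron",
                   "icosahedron"]

_ARCHIMEDEAN_NAMES = [
    "truncated tetrahedron", "cuboctahedron", "truncated cube",
    "truncated octahedron", "rhombicuboctahedron", "truncated cuboctahedron",
    "snub cube", "icosidodecahedron", "truncated dodecahedron",
    "truncated icosahedron", "rhombicosidodecahedron",
    "truncated icosidodecahedron", "snub dodecahedron",
]

_CATALAN_NAMES = [
    "triakis tetrahedron", "rhombic dodecahedron", "triakis octahedron",
    "tetrakis hexahedron", "deltoidal icositetrahedron",
    "disdyakis dodecahedron", "pentagonal icositetrahedron",
    "rhombic triacontahedron", "triakis icosahedron", "pentakis dodecahedron",
    "deltoidal hexecontahedron", "disdyakis triacontahedron",
    "pentagonal hexecontahedron",
]

_JOHNSON_NAMES = [
    "square pyramid", "pentagonal pyramid", "triangular cupola",
    "square cupola", "pentagonal cupola", "pentagonal rotunda",
    "elongated triangular pyramid", "elongated square pyramid",
    "elongated pentagonal pyramid", "gyroelongated square pyramid",
    "gyroelongated pentagonal pyramid", "triangular bipyramid",
    "pentagonal bipyramid", "elongated triangular bipyramid",
    "elongated square bipyramid", "elongated pentagonal bipyramid",
    "gyroelongated square bipyramid", "elongated triangular cupola",
    "elongated square cupola", "elongated pentagonal cupola",
    "elongated pentagonal rotunda", "gyroelongated triangular cupola",
    "gyroelongated square cupola", "gyroelongated pentagonal cupola",
    "gyroelongated pentagonal rotunda", "gyrobifastigium",
    "triangular orthobicupola", "square orthobicupola", "square gyrobicupola",
    "pentagonal orthobicupola", "pentagonal gyrobicupola",
    "pentagonal orthocupolarotunda", "pentagonal gyrocupolarotunda",
    "pentagonal orthobirotunda", "elongated triangular orthobicupola",
    "elongated triangular gyrobicupola", "elongated square gyrobicupola",
    "elongated pentagonal orthobicupola", "elongated pentagonal gyrobicupola",
    "elongated pentagonal orthocupolarotunda",
    "elongated pentagonal gyrocupolarotunda",
    "elongated pentagonal orthobirotunda",
    "elongated pentagonal gyrobirotunda", "gyroelongated triangular bicupola",
    "gyroelongated square bicupola", "gyroelongated pentagonal bicupola",
    "gyroelongated pentagonal cupolarotunda",
    "gyroelongated pentagonal birotunda", "augmented triangular prism",
    "biaugmented triangular prism", "triaugmented triangular prism",
    "augmented pentagonal prism", "biaugmented pentagonal prism",
    "augmented hexagonal prism", "parabiaugmented hexagonal prism",
    "metabiaugmented hexagonal prism", "triaugmented hexagonal prism",
    "augmented dodecahedron", "parabiaugmented dodecahedron",
    "metabiaugmented dodecahedron", "triaugmented dodecahedron",
    "metabidiminished icosahedron", "tridiminished icosahedron",
    "augmented tridiminished icosahedron", "augmented truncated tetrahedron",
    "augmented truncated cube", "biaugmented truncated cube",
    "augmented truncated dodecahedron",
    "parabiaugmented truncated dodecahedron",
    "metabiaugmented truncated dodecahedron",
    "triaugmented truncated dodecahedron", "gyrate rhombicosidodecahedron",
    "parabigyrate rhombicosidodecahedron",
    "metabigyrate rhombicosidodecahedron", "trigyrate rhombicosidodecahedron",
    "diminished rhombicosidodecahedron",
    "paragyrate diminished rhombicosidodecahedron",
    "metagyrate diminished rhombicosidodecahedron",
    "bigyrate diminished rhombicosidodecahedron",
    "parabidiminished rhombicosidodecahedron",
    "metabidiminished rhombicosidodecahedron",
    "gyrate bidiminished rhombicosidodecahedron",
    "tridiminished rhombicosidodecahedron", "snub disphenoid",
    "snub square antiprism", "sphenocorona", "augmented sphenocorona",
    "sphenomegacorona", "hebesphenomegacorona", "disphenocingulum",
    "bilunabirotunda", "triangular hebesphenorotunda",
]


def catalog() -> list[tuple[int, str, str]]:
    """(id, name, family) for all 123 solids in canonical order."""
    entries = []
    i = 1
    for name in _PLATONIC_NAMES:
        entries.append((i, name, "Platonic"))
        i += 1
    for name in _ARCHIMEDEAN_NAMES:
        entries.append((i, name, "Archimedean"))
        i += 1
    for name in _CATALAN_NAMES:
        entries.append((i, name, "Catalan"))
        i += 1
    for k, name in enumerate(_JOHNSON_NAMES, start=1):
        entries.append((i, f"J{k} {name}", "Johnson"))
        i += 1
    assert len(entries) == 123
    return entries


class LibraryError(RuntimeError):
    """A reference solid failed to load or validate."""


@dataclass
class Polyhedron:
    """A complete reference solid with hull-derived combinatorics."""

    id: int
    name: str
    family: str
    vertices: np.ndarray
    edges: list[tuple[int, int]] = field(repr=False)
    faces: list[list[int]] = field(repr=False)

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    @property
    def circumdistance(self) -> float:
        return float(np.linalg.norm(self.vertices - self.centroid, axis=1).max())

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def as_pg(self) -> PolyhedralGraph:
        return PolyhedralGraph.from_polyhedron(self.vertices, self.edges,
                                               self.faces)

    def profile(self) -> TopologicalProfile:
        return compute_profile(self.as_pg())

    def validate(self) -> None:
        V, E, F = self.n_vertices, self.n_edges, self.n_faces
        if V - E + F != 2:
            raise LibraryError(f"{self.name}: Euler violation V-E+F != 2")
        from collections import Counter

        deg = Counter()
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        if sum(k * v for k, v in Counter(
                [len(f) for f in self.faces]).items()) != 2 * E:
            raise LibraryError(f"{self.name}: face handshake violated")
        if sum(deg.values()) != 2 * E:
            raise LibraryError(f"{self.name}: vertex handshake violated")
        cnt = Counter()
        for cyc in self.faces:
            for i in range(len(cyc)):
                a, b = cyc[i], cyc[(i + 1) % len(cyc)]
                cnt[(min(a, b), max(a, b))] += 1
        if any(c != 2 for c in cnt.values()) or set(cnt) != set(
                (min(a, b), max(a, b)) for a, b in self.edges):
            raise LibraryError(f"{self.name}: edge not on exactly two faces")


def _solid_filename(sid: int, name: str) -> str:
    slug = name.replace(" ", "-").replace("(", "").replace(")", "")
    return f"{sid:03d}-{slug}.txt"


def _data_dir():
    return resources.files("polyclass.data") / "solids"


def load_solid_vertices(sid: int, name: str) -> np.ndarray:
    path = _data_dir() / _solid_filename(sid, name)
    try:
        text = path.read_text()
    except FileNotFoundError as ex:
        raise LibraryError(f"missing coordinate file for solid {sid} "
                           f"({name}): {ex}") from ex
    lines = [ln for ln in text.splitlines()
             if ln.strip() and not ln.startswith("#")]
    try:
        pts = np.array([[float(x) for x in ln.split()] for ln in lines])
    except ValueError as ex:
        raise LibraryError(f"corrupt coordinate file for solid {sid} "
                           f"({name})") from ex
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise LibraryError(f"corrupt coordinate file for solid {sid} ({name})")
    return pts


@lru_cache(maxsize=1)
def build_library() -> tuple[Polyhedron, ...]:
    """Load and validate all 123 reference solids (cached)."""
    out = []
    for sid, name, family in catalog():
        pts = load_solid_vertices(sid, name)
        try:
            edges, faces = derive_faces(pts)
        except GeometryError as ex:
            raise LibraryError(f"face derivation failed for solid {sid} "
                               f"({name}): {ex}") from ex
        poly = Polyhedron(id=sid, name=name, family=family, vertices=pts,
                          edges=edges, faces=faces)
        poly.validate()
        out.append(poly)
    return tuple(out)


def get_solid(sid: int) -> Polyhedron:
    lib = build_library()
    if not 1 <= sid <= len(lib):
        raise KeyError(f"solid id {sid} out of range 1..{len(lib)}")
    return lib[sid - 1]


# --------------------------------------------------------------------------
# duplicate complete profiles and the merged class space

@dataclass(frozen=True)
class ClassMap:
    """Merged label space induced by identical complete profiles."""

    duplicate_pairs: tuple[tuple[int, int], ...]
    class_labels: dict[int, int]  # solid id -> canonical class 1..n_classes

    @property
    def n_classes(self) -> int:
        return len(set(self.class_labels.values()))

    def classes(self) -> list[int]:
        return sorted(set(self.class_labels.values()))

    def representative(self, label: int) -> int:
        """Lowest solid id carrying the given class label."""
        return min(s for s, c in self.class_labels.items() if c == label)


def find_duplicate_profiles(library=None) -> ClassMap:
    """All unordered pairs of solids with identical complete profiles.

    The induced canonical labelling keeps the lower id of each duplicate
    group and renumbers the distinct classes 1..n in id order.
    """
    if library is None:
        library = build_library()
    by_hash: dict[str, list[int]] = {}
    for poly in library:
        by_hash.setdefault(poly.profile().hash, []).append(poly.id)
    pairs = []
    canonical: dict[int, int] = {}
    for ids in by_hash.values():
        ids = sorted(ids)
        for other in ids[1:]:
            pairs.append((ids[0], other))
        for sid in ids:
            canonical[sid] = ids[0]
    reps = sorted(set(canonical.values()))
    relabel = {rep: k + 1 for k, rep in enumerate(reps)}
    class_labels = {sid: relabel[canonical[sid]] for sid in canonical}
    return ClassMap(duplicate_pairs=tuple(sorted(pairs)),
                    class_labels=class_labels)


# --------------------------------------------------------------------------
# mesh export / import

def export_mesh(polyhedron: Polyhedron, path) -> None:
    """Write OFF (or OBJ, by extension) with polygonal faces."""
    path = str(path)
    if path.endswith(".obj"):
        lines = [f"o {polyhedron.name.replace(' ', '_')}"]
        for p in polyhedron.vertices:
            lines.append("v %.17g %.17g %.17g" % tuple(p))
        for cyc in polyhedron.faces:
            lines.append("f " + " ".join(str(v + 1) for v in cyc))
    elif path.endswith(".off"):
        lines = ["OFF", f"{polyhedron.n_vertices} {polyhedron.n_faces} "
                        f"{polyhedron.n_edges}"]
        for p in polyhedron.vertices:
            lines.append("%.17g %.17g %.17g" % tuple(p))
        for cyc in polyhedron.faces:
            lines.append(str(len(cyc)) + " " + " ".join(str(v) for v in cyc))
    else:
        raise ValueError("unsupported mesh extension (use .off or .obj)")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_off(path):
    """Read an OFF file back as (vertices, faces)."""
    with open(path) as fh:
        tokens = []
        for line in fh:
            line = line.split("#")[0].strip()
            if line:
                tokens.extend(line.split())
    if tokens[0] != "OFF":
        raise ValueError("not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    pos = 4
    verts = np.array([[float(tokens[pos + 3 * i + j]) for j in range(3)]
                      for i in range(nv)])
    pos += 3 * nv
    faces = []
    for _ in range(nf):
        k = int(tokens[pos])
        faces.append([int(t) for t in tokens[pos + 1:pos + 1 + k]])
        pos += 1 + k
    return verts, faces


def manifest(library=None) -> list[dict]:
    if library is None:
        library = build_library()
    return [{"id": p.id, "name": p.name, "family": p.family,
             "n_vertices": p.n_vertices, "n_edges": p.n_edges,
             "n_faces": p.n_faces} for p in library]


def write_manifest(path, library=None) -> None:
    with open(path, "w") as fh:
        json.dump(manifest(library), fh, indent=1)
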