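"""Polyhedral graphs, complete or incomplete.

An observed polyhedral graph (PG) is the vertex/edge/face structure
extracted from a single reconstructed object.  Because of the missing
wedge, the PG may be incomplete: some edges have only one observed
endpoint ("incomplete edges", drawn yellow in ball-stick diagrams) and
some faces are only partially visible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


class PGError(ValueError):
    """Malformed polyhedral graph."""


@dataclass
class PolyhedralGraph:
    """An observed, possibly incomplete polyhedral graph.

    Attributes
    ----------
    vertices : dict[int, ndarray]
        Observed vertex id -> 3-d coordinate.
    complete_edges : list[tuple[int, int]]
        Edges with both endpoints observed (stored with i < j).
    incomplete_edges : list[tuple[int, ndarray]]
        Edges with exactly one observed endpoint: (vertex id, free-end
        coordinate).  The free end carries no vertex identity.
    complete_faces : list[list[int]]
        Fully observed faces as closed vertex-id cycles.
    incomplete_faces : list[list[tuple[str, int]]]
        Partially visible faces as lists of visible-edge references:
        ("c", k) = k-th complete edge, ("p", k) = k-th incomplete edge.
    """

    vertices: dict[int, np.ndarray] = field(default_factory=dict)
    complete_edges: list[tuple[int, int]] = field(default_factory=list)
    incomplete_edges: list[tuple[int, np.ndarray]] = field(default_factory=list)
    complete_faces: list[list[int]] = field(default_factory=list)
    incomplete_faces: list[list[tuple[str, int]]] = field(default_factory=list)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_polyhedron(cls, vertices, edges, faces) -> "PolyhedralGraph":
        """Wrap a complete polyhedron as a (fully observed) PG."""
        pts = np.asarray(vertices, dtype=float)
        pg = cls(
            vertices={i: pts[i] for i in range(len(pts))},
            complete_edges=[tuple(sorted(e)) for e in edges],
            complete_faces=[list(f) for f in faces],
        )
        pg.validate()
        return pg

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        ids = set(self.vertices)
        seen = set()
        for a, b in self.complete_edges:
            if a not in ids or b not in ids:
                raise PGError(f"edge ({a},{b}) references unknown vertex")
            if a == b:
                raise PGError("self-loop edge")
            key = (min(a, b), max(a, b))
            if key in seen:
                raise PGError(f"duplicate edge {key}")
            seen.add(key)
        for v, _end in self.incomplete_edges:
            if v not in ids:
                raise PGError(f"incomplete edge references unknown vertex {v}")
        for cyc in self.complete_faces:
            if len(cyc) < 3:
                raise PGError("face with fewer than 3 vertices")
            for i in range(len(cyc)):
                a, b = cyc[i], cyc[(i + 1) % len(cyc)]
                if (min(a, b), max(a, b)) not in seen:
                    raise PGError(
                        f"complete face uses non-complete edge ({a},{b})")
        for refs in self.incomplete_faces:
            if not refs:
                raise PGError("incomplete face with no visible edges")
            for kind, k in refs:
                if kind == "c":
                    if not 0 <= k < len(self.complete_edges):
                        raise PGError("bad complete-edge reference")
                elif kind == "p":
                    if not 0 <= k < len(self.incomplete_edges):
                        raise PGError("bad incomplete-edge reference")
                else:
                    raise PGError(f"unknown edge reference kind {kind!r}")

    # -- derived quantities ------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        """All edges, complete plus incomplete."""
        return len(self.complete_edges) + len(self.incomplete_edges)

    def observed_degrees(self) -> dict[int, int]:
        """Observed degree: complete plus incomplete incident edges."""
        deg = {v: 0 for v in self.vertices}
        for a, b in self.complete_edges:
            deg[a] += 1
            deg[b] += 1
        for v, _ in self.incomplete_edges:
            deg[v] += 1
        return deg

    def complete_degrees(self) -> dict[int, int]:
        deg = {v: 0 for v in self.vertices}
        for a, b in self.complete_edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def incomplete_incident_counts(self) -> dict[int, int]:
        cnt = {v: 0 for v in self.vertices}
        for v, _ in self.incomplete_edges:
            cnt[v] += 1
        return cnt

    def adjacency_matrix(self) -> np.ndarray:
        """0/1 adjacency over observed vertices (complete edges only)."""
        order = sorted(self.vertices)
        pos = {v: i for i, v in enumerate(order)}
        A = np.zeros((len(order), len(order)), dtype=int)
        for a, b in self.complete_edges:
            A[pos[a], pos[b]] = A[pos[b], pos[a]] = 1
        return A

    # -- JSON interchange --------------------------------------------------

    def to_json(self) -> str:
        obj = {
            "vertices": [{"id": int(v), "xyz": [float(x) for x in p]}
                         for v, p in sorted(self.vertices.items())],
            "complete_edges": [[int(a), int(b)] for a, b in self.complete_edges],
            "incomplete_edges": [
                {"vertex": int(v), "free_end_xyz": [float(x) for x in p]}
                for v, p in self.incomplete_edges],
            "faces": {
                "complete": [[int(v) for v in cyc] for cyc in self.complete_faces],
                "incomplete": [[[kind, int(k)] for kind, k in refs]
                               for refs in self.incomplete_faces],
            },
        }
        return json.dumps(obj, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PolyhedralGraph":
        obj = json.loads(text)
        pg = cls(
            vertices={int(v["id"]): np.asarray(v["xyz"], dtype=float)
                      for v in obj["vertices"]},
            complete_edges=[(min(a, b), max(a, b))
                            for a, b in obj["complete_edges"]],
            incomplete_edges=[(int(e["vertex"]),
                               np.asarray(e["free_end_xyz"], dtype=float))
                              for e in obj["incomplete_edges"]],
            complete_faces=[list(map(int, cyc))
                            for cyc in obj["faces"]["complete"]],
            incomplete_faces=[[(kind, int(k)) for kind, k in refs]
                              for refs in obj["faces"]["incomplete"]],
        )
        pg.validate()
        return pg

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "PolyhedralGraph":
        with open(path) as fh:
            return cls.from_json(fh.read())

    # -- exporters ---------------------------------------------------------

    def to_bild(self) -> str:
        """UCSF-Chimera BILD ball-stick diagram (blue vertices, red
        complete edges, yellow incomplete edges, green free ends)."""
        lines = []
        scale = 0.03 * max(
            (np.linalg.norm(p) for p in self.vertices.values()), default=1.0)
        lines.append(".color blue")
        for p in self.vertices.values():
            lines.append(".sphere %g %g %g %g" % (*p, 2 * scale))
        lines.append(".color red")
        for a, b in self.complete_edges:
            pa, pb = self.vertices[a], self.vertices[b]
            lines.append(".cylinder %g %g %g %g %g %g %g" % (*pa, *pb, scale))
        lines.append(".color yellow")
        for v, end in self.incomplete_edges:
            pa = self.vertices[v]
            lines.append(".cylinder %g %g %g %g %g %g %g" % (*pa, *end, scale))
        lines.append(".color green")
        for _, end in self.incomplete_edges:
            lines.append(".sphere %g %g %g %g" % (*end, 2 * scale))
        return "\n".join(lines) + "\n"
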