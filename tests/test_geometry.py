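import numpy as np
import pytest

from polyclass import constructions as cons
from polyclass.geometry import (GeometryError, derive_faces,
                                polar_dual_vertices)


@pytest.mark.parametrize("builder,V,E,F,face_sizes", [
    (cons.tetrahedron, 4, 6, 4, {3}),
    (cons.cube, 8, 12, 6, {4}),
    (cons.octahedron, 6, 12, 8, {3}),
    (cons.icosahedron, 12, 30, 20, {3}),
    (cons.dodecahedron, 20, 30, 12, {5}),
    (cons.truncated_cube, 24, 36, 14, {3, 8}),
])
def test_derive_faces_counts(builder, V, E, F, face_sizes):
    """Hull-derived combinatorics match the closed-form polyhedra."""
    pts = builder()
    edges, faces = derive_faces(pts)
    assert len(pts) == V and len(edges) == E and len(faces) == F
    assert {len(f) for f in faces} == face_sizes
    assert V - E + F == 2


def test_coplanar_facets_are_merged():
    """The 12 triangular hull facets of a cube merge into 6 quads."""
    _, faces = derive_faces(cons.cube())
    assert sorted(len(f) for f in faces) == [4] * 6


def test_faces_are_closed_cycles_with_consistent_edges():
    pts = cons.icosidodecahedron()
    edges, faces = derive_faces(pts)
    # every face edge appears in the edge list; each edge flanks 2 faces
    count = {}
    for cyc in faces:
        for i in range(len(cyc)):
            a, b = cyc[i], cyc[(i + 1) % len(cyc)]
            count[(min(a, b), max(a, b))] = count.get((min(a, b), max(a, b)), 0) + 1
    assert set(count) == set(edges)
    assert set(count.values()) == {2}


def test_degenerate_inputs_raise():
    flat = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
    with pytest.raises(GeometryError):
        derive_faces(flat)
    with_interior = np.vstack([cons.cube(), [[0.0, 0.0, 0.0]]])
    with pytest.raises(GeometryError, match="not extreme"):
        derive_faces(with_interior)
    with pytest.raises(GeometryError):
        derive_faces(np.zeros((3, 3)))


def test_polar_dual_of_cube_is_octahedron():
    pts = cons.cube()
    _, faces = derive_faces(pts)
    dual = polar_dual_vertices(pts, faces)
    dedges, dfaces = derive_faces(dual)
    assert (len(dual), len(dedges), len(dfaces)) == (6, 12, 8)
    assert all(len(f) == 3 for f in dfaces)
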