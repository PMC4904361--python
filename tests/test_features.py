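import math

import numpy as np
import pytest

from polyclass import constructions as cons
from polyclass.features import (SUBSETS, TP_DIM, TopologicalProfile,
                                coplanarity_test, compute_profile,
                                face_regularity, parse_profile_hash,
                                profile_columns, profile_hash,
                                profiles_to_frame, validate_faces)
from polyclass.graph import PGError, PolyhedralGraph


def cube_pg(cube_poly):
    return PolyhedralGraph.from_polyhedron(cube_poly.vertices,
                                           cube_poly.edges, cube_poly.faces)


def test_profile_dimension_and_blocks(cube_poly):
    prof = compute_profile(cube_pg(cube_poly))
    assert prof.vector.shape == (TP_DIM,)
    assert TP_DIM == 231
    assert len(prof.global_block) == 3
    assert len(prof.face_dist) == 6
    assert len(prof.vertex_dist) == 6
    assert len(prof.face_censored) == 8
    assert len(prof.vertex_censored) == 8
    assert prof.EV.shape == (10, 10) and prof.FV.shape == (10, 10)
    assert len(profile_columns()) == 231


def test_complete_cube_profile(cube_poly):
    prof = compute_profile(cube_pg(cube_poly))
    V, E, F = prof.global_block
    assert (V, E, F) == (8, 12, 6)
    assert prof.face_dist.tolist() == [0, 6, 0, 0, 0, 0]      # F4 = 6
    assert prof.vertex_dist.tolist() == [8, 0, 0, 0, 0, 0]    # V3 = 8
    # censored blocks include the complete features
    assert prof.face_censored.tolist() == [6, 6, 0, 0, 0, 0, 0, 0]
    assert prof.vertex_censored.tolist() == [8, 0, 0, 0, 0, 0, 0, 0]
    assert prof.EV[2, 2] == 12  # all edges join degree-3 vertices
    assert prof.FV[3, 3] == 12  # all edges flanked by two quads
    # Euler and handshake identities visible in the profile
    assert V - E + F == 2
    assert prof.EV.sum() + np.trace(prof.EV) == 2 * E


def test_empty_pg_gives_zero_profile():
    prof = compute_profile(PolyhedralGraph())
    assert not prof.vector.any()


def test_profile_of_malformed_pg_raises():
    pg = PolyhedralGraph(vertices={0: np.zeros(3)},
                        complete_edges=[(0, 1)])
    with pytest.raises(PGError):
        compute_profile(pg)


# -- coplanarity ------------------------------------------------------------

def test_coplanarity_zero_for_planar_quad():
    sq = [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]
    assert coplanarity_test(sq) == pytest.approx(0.0, abs=1e-15)


def test_coplanarity_one_for_regular_tetrahedron():
    # isotropic scatter: all three eigenvalues equal
    assert coplanarity_test(cons.tetrahedron()) == pytest.approx(1.0)


def test_coplanarity_rejects_merged_icosahedron_triangles(icosahedron_poly):
    faces = icosahedron_poly.faces
    f0 = faces[0]
    adj = next(f for f in faces[1:] if len(set(f) & set(f0)) == 2)
    pts = icosahedron_poly.vertices[sorted(set(f0) | set(adj))]
    assert coplanarity_test(pts) > 0.1


def test_coplanarity_invariances():
    rng = np.random.default_rng(7)
    pts = rng.normal(size=(6, 3))
    t0 = coplanarity_test(pts)
    from polyclass.truncation import rotation_matrix

    R = rotation_matrix((0.7, 1.9))
    for moved in (pts @ R.T, pts + [3.0, -1.0, 2.0], 2.5 * pts):
        assert coplanarity_test(moved) == pytest.approx(t0, rel=1e-9)


def test_coplanarity_errors():
    with pytest.raises(ValueError, match="at least 4"):
        coplanarity_test([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
    line = [[t, 0, 0] for t in range(5)]
    with pytest.raises(ValueError, match="collinear"):
        coplanarity_test(line)


def test_validate_faces_flags_and_threshold(library):
    cube = library[1]
    pg = PolyhedralGraph.from_polyhedron(cube.vertices, cube.edges,
                                         cube.faces)
    res = validate_faces(pg, cube.faces)
    assert all(planar for _, _, planar in res)
    # threshold 1.0 accepts anything since T <= 1
    res = validate_faces(pg, [[0, 1, 2, 7]], threshold=1.0)
    assert res[0][2]
    with pytest.raises(PGError):
        validate_faces(pg, [[0, 1, 99]])


def test_all_library_faces_pass_coplanarity(library):
    for p in library[::9]:
        for cyc in p.faces:
            if len(cyc) >= 4:
                assert coplanarity_test(p.vertices[cyc]) < 1e-6, p.name


# -- face regularity --------------------------------------------------------

def test_face_regularity_isosceles_value():
    r = face_regularity([1.0, 2.0, 2.0])
    assert r == pytest.approx(math.sqrt(1.0 / 3.0) / (5.0 / 3.0))
    assert r == pytest.approx(0.3464, abs=5e-5)


@pytest.mark.parametrize("scale", [0.1, 1.0, 7.3])
def test_face_regularity_zero_and_scale_invariant(scale):
    assert face_regularity([scale] * 5) == 0.0
    base = [1.0, 2.0, 2.0, 3.0]
    assert face_regularity([scale * x for x in base]) == pytest.approx(
        face_regularity(base))


def test_face_regularity_errors():
    with pytest.raises(ValueError):
        face_regularity([1.0])
    with pytest.raises(ValueError):
        face_regularity([1.0, -2.0, 2.0])


# -- hashes and export ------------------------------------------------------

def test_profile_hash_roundtrip_and_injectivity(library):
    cube, tet = library[1], library[0]
    pc, pt = cube.profile(), tet.profile()
    assert pc.hash != pt.hash
    assert parse_profile_hash(pc.hash) == pc
    assert parse_profile_hash(pt.hash) == pt


def test_symmetry_equivalent_truncations_share_hash(cube_poly):
    from polyclass.truncation import TruncationSampler

    s = TruncationSampler(cube_poly)
    d = 0.6
    axis = np.array([1.0, 1.0, 1.0]) / math.sqrt(3)
    # a cube symmetry rotation maps the body diagonal to another diagonal
    axis2 = np.array([-1.0, 1.0, 1.0]) / math.sqrt(3)
    p1 = s.profile_for_axis(axis, d)
    p2 = s.profile_for_axis(axis2, d)
    assert profile_hash(p1) == profile_hash(p2)


def test_feature_subsets_partition():
    assert len(SUBSETS["all"]) == 231
    assert len(SUBSETS["global"]) == 3
    assert len(SUBSETS["local"]) == 228
    assert len(SUBSETS["complete"]) == 12
    assert len(SUBSETS["incomplete"]) == 219
    assert set(SUBSETS["global"]) | set(SUBSETS["local"]) == set(range(231))


def test_profiles_to_frame(cube_poly):
    prof = compute_profile(cube_pg(cube_poly))
    df = profiles_to_frame([prof, prof], solid=[2, 2])
    assert df.shape == (2, 233)
    assert df["hash"].iloc[0] == prof.hash
    assert df["V"].iloc[0] == 8
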