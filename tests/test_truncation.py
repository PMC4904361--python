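import math

import numpy as np
import pytest

from polyclass.features import compute_profile
from polyclass.graph import PolyhedralGraph
from polyclass.truncation import (TruncationConfig, TruncationSampler,
                                  discretized_edge_classification,
                                  generate_ttps, generate_ttp_objects,
                                  perturb_delete_vertex, sample_orientation,
                                  rotation_matrix, truncate, truncation_axis,
                                  unique_ttp_curve)

BODY_DIAGONAL_PHI = (math.atan2(1.0, 1.0),
                     math.asin(-1.0 / math.sqrt(3.0)))


def test_config_validation():
    TruncationConfig(truncation_percent=0.0)
    with pytest.raises(ValueError):
        TruncationConfig(truncation_percent=100.0)
    with pytest.raises(ValueError):
        TruncationConfig(edge_discretization=1)
    cfg = TruncationConfig(truncation_percent=20.0)
    assert cfg.plane_distance(1.0) == pytest.approx(0.9)


def test_identity_orientation():
    R = rotation_matrix((0.0, 0.0))
    assert np.allclose(R, np.eye(3))
    assert np.allclose(truncation_axis((0.0, 0.0)), [0, 0, 1])


def test_orientation_sampling_uniform_and_reproducible():
    rng = np.random.default_rng(123)
    draws = np.array([sample_orientation(rng) for _ in range(10000)])
    assert draws.min() >= 0.0 and draws.max() < 2 * math.pi
    from scipy.stats import kstest

    p = kstest(draws[:, 0] / (2 * math.pi), "uniform").pvalue
    assert p > 0.01
    rng2 = np.random.default_rng(123)
    assert sample_orientation(rng2) == tuple(draws[0])


def test_no_truncation_returns_complete_polyhedron(cube_poly):
    d_max = np.linalg.norm(cube_poly.vertices, axis=1).max()
    pg = truncate(cube_poly, (0.3, 1.2), d_max)
    assert pg.n_vertices == 8
    assert len(pg.complete_edges) == 12
    assert not pg.incomplete_edges
    assert len(pg.complete_faces) == 6


def test_body_diagonal_cube_truncation(cube_poly):
    pg = truncate(cube_poly, BODY_DIAGONAL_PHI, 0.6)
    prof = compute_profile(pg)
    assert prof.global_block.tolist() == [6, 12, 0]
    assert len(pg.complete_edges) == 6
    assert len(pg.incomplete_edges) == 6
    assert len(pg.incomplete_faces) == 6
    assert all(len(refs) == 4 for refs in pg.incomplete_faces)
    assert prof.face_censored.tolist() == [6, 6, 0, 0, 0, 0, 0, 0]


def test_free_ends_lie_on_truncation_planes(icosahedron_poly):
    d = 0.8
    pg = truncate(icosahedron_poly, (1.1, 2.7), d)
    assert pg.incomplete_edges
    for _, end in pg.incomplete_edges:
        assert abs(abs(end[2]) - d) < 1e-9


def test_monotone_truncation(icosahedron_poly):
    phi = (0.4, 5.1)
    d_max = np.linalg.norm(icosahedron_poly.vertices, axis=1).max()
    last = None
    for d in np.linspace(d_max, 0.55 * d_max, 12):
        n = truncate(icosahedron_poly, phi, d).n_vertices
        if last is not None:
            assert n <= last
        last = n


def test_rotation_invariance_of_complete_profile(library):
    rng = np.random.default_rng(42)
    for p in library[::23]:
        sampler = TruncationSampler(p)
        ref = sampler.profile_for_axis(np.array([0.0, 0.0, 1.0]),
                                       sampler.d_max)
        for _ in range(3):
            phi = sample_orientation(rng)
            prof = sampler.profile_for_axis(truncation_axis(phi),
                                            sampler.d_max)
            assert (prof == ref).all(), p.name


def test_fast_sampler_matches_object_path(library):
    rng = np.random.default_rng(11)
    for p in library[10:120:27]:
        sampler = TruncationSampler(p)
        for percent in (10.0, 25.0):
            d = sampler.plane_distance(percent)
            for _ in range(3):
                phi = sample_orientation(rng)
                obj = compute_profile(truncate(p, phi, d)).vector
                fast = sampler.profile_for_axis(truncation_axis(phi), d)
                assert (obj == fast).all(), (p.name, percent, phi)


def test_exact_clipping_agrees_with_discretized_oracle(library):
    rng = np.random.default_rng(3)
    for p in library[::31]:
        sampler = TruncationSampler(p)
        d = sampler.plane_distance(20.0)
        phi = sample_orientation(rng)
        oracle = discretized_edge_classification(p, phi, d, l=50)
        pg = truncate(p, phi, d)
        complete = set(pg.complete_edges)
        partial = {tuple(sorted((v, -1))) for v, _ in pg.incomplete_edges}
        for (a, b), status in oracle.items():
            if status == "complete":
                assert (a, b) in complete
            elif status == "absent":
                assert (a, b) not in complete


def test_generate_ttps_deterministic(cube_poly):
    a = generate_ttps(cube_poly, 50, 20.0, seed=5)
    b = generate_ttps(cube_poly, 50, 20.0, seed=5)
    c = generate_ttps(cube_poly, 50, 20.0, seed=6)
    assert (a == b).all()
    assert (a != c).any()
    with pytest.raises(ValueError):
        generate_ttps(cube_poly, 0, 20.0, seed=1)


def test_object_and_array_generators_agree(cube_poly):
    arr = generate_ttps(cube_poly, 20, 15.0, seed=9)
    objs = generate_ttp_objects(cube_poly, 20, 15.0, seed=9)
    assert (arr == np.array([o.vector for o in objs])).all()


def test_unique_ttp_curve_monotone(cube_poly):
    profs = generate_ttps(cube_poly, 300, 20.0, seed=2)
    curve = unique_ttp_curve(profs)
    assert (np.diff(curve) >= 0).all()
    assert curve[0] == 1


def test_zero_truncation_yields_single_unique_profile(library):
    tet = library[0]
    profs = generate_ttps(tet, 40, 0.0, seed=1)
    assert len({row.tobytes() for row in profs}) == 1
    complete = compute_profile(
        PolyhedralGraph.from_polyhedron(tet.vertices, tet.edges, tet.faces))
    assert (profs[0] == complete.vector).all()


# -- vertex deletion --------------------------------------------------------

def test_delete_vertex_on_complete_tetrahedron(library):
    tet = library[0]
    pg = PolyhedralGraph.from_polyhedron(tet.vertices, tet.edges, tet.faces)
    out = perturb_delete_vertex(pg, np.random.default_rng(0))
    prof = compute_profile(out)
    assert prof.global_block.tolist() == [3, 3, 1]
    assert not out.incomplete_edges
    assert len(out.incomplete_faces) == 3
    assert all(len(r) == 1 for r in out.incomplete_faces)


def test_delete_vertex_reduces_count_and_changes_profile(library):
    rng = np.random.default_rng(4)
    for p in library[:5]:  # all Platonic solids, every deletion equivalent
        pg = PolyhedralGraph.from_polyhedron(p.vertices, p.edges, p.faces)
        before = compute_profile(pg)
        out = perturb_delete_vertex(pg, rng)
        assert out.n_vertices == pg.n_vertices - 1
        assert compute_profile(out) != before


def test_delete_vertex_empty_pg_raises():
    with pytest.raises(ValueError):
        perturb_delete_vertex(PolyhedralGraph(), np.random.default_rng(0))


def test_delete_vertex_from_truncated_pg_valid(icosahedron_poly):
    rng = np.random.default_rng(8)
    pg = truncate(icosahedron_poly, (0.9, 0.2), 0.8)
    out = perturb_delete_vertex(pg, rng)
    out.validate()
    assert out.n_vertices == pg.n_vertices - 1


def test_censor_mode_deletion_keeps_edge_stubs(library):
    """In the milder missed-vertex model the deleted vertex's edges
    survive as incomplete stubs and faces keep them visible."""
    tet = library[0]
    pg = PolyhedralGraph.from_polyhedron(tet.vertices, tet.edges, tet.faces)
    out = perturb_delete_vertex(pg, np.random.default_rng(0), mode="censor")
    assert out.n_vertices == 3
    assert len(out.complete_edges) == 3
    assert len(out.incomplete_edges) == 3
    assert len(out.complete_faces) == 1
    # every broken face shows 1 complete + 2 stub edges
    assert sorted(len(r) for r in out.incomplete_faces) == [3, 3, 3]
    prof = compute_profile(out)
    assert prof.global_block.tolist() == [3, 6, 1]
    with pytest.raises(ValueError, match="mode"):
        perturb_delete_vertex(pg, np.random.default_rng(0), mode="nope")
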