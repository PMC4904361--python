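import collections

import numpy as np
import pytest

from polyclass.geometry import derive_faces
from polyclass.library import (LibraryError, catalog, export_mesh,
                               find_duplicate_profiles, get_solid,
                               load_solid_vertices, manifest, read_off)


def test_library_size_and_family_counts(library):
    assert len(library) == 123
    fam = collections.Counter(p.family for p in library)
    assert fam == {"Platonic": 5, "Archimedean": 13, "Catalan": 13,
                   "Johnson": 92}


def test_catalog_ordering_is_stable():
    cat = catalog()
    assert [c[0] for c in cat] == list(range(1, 124))
    assert cat[0][1:] == ("tetrahedron", "Platonic")
    assert cat[122][1] == "J92 triangular hebesphenorotunda"


def test_every_solid_satisfies_euler_and_handshakes(library):
    for p in library:
        V, E, F = p.n_vertices, p.n_edges, p.n_faces
        assert V - E + F == 2, p.name
        assert sum(len(f) for f in p.faces) == 2 * E, p.name
        deg = collections.Counter()
        for a, b in p.edges:
            deg[a] += 1
            deg[b] += 1
        assert sum(deg.values()) == 2 * E, p.name
        p.validate()


@pytest.mark.parametrize("sid,V,E,F", [
    (1, 4, 6, 4),       # tetrahedron
    (2, 8, 12, 6),      # cube
    (5, 12, 30, 20),    # icosahedron
    (37 + 31, 24, 48, 26),   # J37 pseudo-rhombicuboctahedron
])
def test_known_entries(sid, V, E, F):
    p = get_solid(sid)
    assert (p.n_vertices, p.n_edges, p.n_faces) == (V, E, F)


def test_icosahedron_all_degree_five():
    p = get_solid(5)
    deg = collections.Counter()
    for a, b in p.edges:
        deg[a] += 1
        deg[b] += 1
    assert set(deg.values()) == {5}
    assert all(len(f) == 3 for f in p.faces)


def test_derive_faces_reproduces_stored_combinatorics(library):
    # spot-check a spread of solids across the families
    for p in library[::17]:
        edges, faces = derive_faces(p.vertices)
        assert len(edges) == p.n_edges
        assert sorted(len(f) for f in faces) == sorted(
            len(f) for f in p.faces)


def test_duplicate_profiles(class_map):
    assert len(class_map.duplicate_pairs) == 8
    assert class_map.n_classes == 115
    # pairs are disjoint and the lower id is canonical
    seen = set()
    for a, b in class_map.duplicate_pairs:
        assert a < b
        assert class_map.class_labels[a] == class_map.class_labels[b]
        assert not {a, b} & seen
        seen |= {a, b}
    # labels partition the library
    assert set(class_map.class_labels) == set(range(1, 124))
    assert set(class_map.class_labels.values()) == set(range(1, 116))


def test_platonic_only_library_has_no_duplicates(library):
    cmap = find_duplicate_profiles(library[:5])
    assert cmap.duplicate_pairs == ()
    assert cmap.n_classes == 5


def test_two_solids_share_class_iff_profiles_equal(library, class_map):
    by_id = {p.id: p for p in library}
    for a, b in class_map.duplicate_pairs:
        assert by_id[a].profile() == by_id[b].profile()
    # a non-duplicated pair must differ
    assert by_id[1].profile() != by_id[2].profile()


def test_off_export_roundtrip(tmp_path, library):
    cube = get_solid(2)
    path = tmp_path / "cube.off"
    export_mesh(cube, path)
    text = path.read_text().splitlines()
    assert text[0] == "OFF"
    assert text[1] == "8 6 12"
    verts, faces = read_off(path)
    assert np.allclose(verts, cube.vertices)
    assert sorted(map(len, faces)) == sorted(map(len, cube.faces))
    tet = get_solid(1)
    export_mesh(tet, tmp_path / "tet.off")
    lines = (tmp_path / "tet.off").read_text().splitlines()
    assert len(lines) == 2 + 4 + 4  # header, counts, 4 vertices, 4 faces


def test_manifest_fields(library):
    man = manifest(library)
    assert len(man) == 123
    assert man[1] == {"id": 2, "name": "cube", "family": "Platonic",
                      "n_vertices": 8, "n_edges": 12, "n_faces": 6}


def test_missing_coordinate_file_raises():
    with pytest.raises(LibraryError, match="missing"):
        load_solid_vertices(999, "no such solid")
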