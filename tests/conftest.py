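import numpy as np
import pytest

from polyclass.geometry import derive_faces


class SimplePolyhedron:
    """Minimal polyhedron-like object built straight from coordinates."""

    def __init__(self, vertices):
        self.vertices = np.asarray(vertices, dtype=float)
        self.edges, self.faces = derive_faces(self.vertices)


@pytest.fixture(scope="session")
def library():
    from polyclass.library import build_library

    return build_library()


@pytest.fixture(scope="session")
def class_map(library):
    from polyclass.library import find_duplicate_profiles

    return find_duplicate_profiles(library)


@pytest.fixture(scope="session")
def cube_poly():
    from polyclass.constructions import cube

    return SimplePolyhedron(cube())


@pytest.fixture(scope="session")
def icosahedron_poly():
    from polyclass.constructions import icosahedron

    return SimplePolyhedron(icosahedron())
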