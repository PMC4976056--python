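import numpy as np
import pytest

from mvcpair import TriangleMesh
from mvcpair.synthetic import BoneParams, generate_bone


@pytest.fixture
def tetrahedron() -> TriangleMesh:
    """Regular tetrahedron with outward-wound faces."""
    vertices = np.array(
        [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
    )
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh("tetra", vertices, faces)


def make_icosphere(radius: float = 10.0, subdivisions: int = 3) -> TriangleMesh:
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh("icosphere", np.asarray(ico.vertices), np.asarray(ico.faces))


@pytest.fixture(scope="session")
def icosphere() -> TriangleMesh:
    return make_icosphere()


@pytest.fixture(scope="session")
def bone() -> TriangleMesh:
    """One ~2k-vertex synthetic long bone."""
    return generate_bone(seed=11)


@pytest.fixture(scope="session")
def bone_coarse() -> TriangleMesh:
    return generate_bone(BoneParams(), resolution="coarse")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
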