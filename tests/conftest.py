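import numpy as np
import pytest

from mixdim import mesh as mk
from mixdim.model import model_from_config
from mixdim import presets


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def unit_tet_mesh():
    """One positively oriented unit right tetrahedron with tagged faces."""
    verts = np.array([[0., 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    cells = np.array([[0, 1, 2, 3]])
    facets = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
    return mk.ParentMesh(verts, cells, facets, np.array([1]),
                         np.array([2, 3, 4, 5]))


@pytest.fixture(scope="session")
def slab_mesh():
    return mk.generate_slab(1.0, 1.0, 1.0, 3)


@pytest.fixture(scope="session")
def nested_disk_mesh():
    return mk.generate_nested(2.0, 1.0, 0.25, dim=2)


@pytest.fixture(scope="session")
def nested_ball_mesh():
    return mk.generate_nested(2.0, 1.0, 0.5, dim=3)


@pytest.fixture
def ab_model():
    mesh, cfg = presets.ab_volume(n=2)
    return model_from_config(cfg, mesh)


@pytest.fixture
def slab_model():
    mesh, cfg = presets.slab_phosphorylation(n=4)
    return model_from_config(cfg, mesh)


@pytest.fixture
def binding_model():
    mesh, cfg = presets.volume_surface_binding(n=3)
    return model_from_config(cfg, mesh)


@pytest.fixture
def transport_model():
    mesh, cfg = presets.nested_transport(h=0.5)
    return model_from_config(cfg, mesh)


def two_box_mesh():
    """Two unit cubes sharing the x=1 face; distinct volume tags.

    The shared face carries tag 10, the exterior tag 11; used to exercise
    interior-interface adjacency.
    """
    n = 1
    xs = np.array([0.0, 1.0, 2.0])
    ys = np.array([0.0, 1.0])
    zs = np.array([0.0, 1.0])
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def vid(i, j, k):
        return (i * 2 + j) * 2 + k

    import itertools
    cells, tags = [], []
    for bx in range(2):
        for perm in itertools.permutations(range(3)):
            path = [np.array([bx, 0, 0])]
            for ax in perm:
                nxt = path[-1].copy()
                nxt[ax] += 1
                path.append(nxt)
            cells.append([vid(*p) for p in path])
            tags.append(bx + 1)
    cells = np.asarray(cells)
    # tagged facets: the whole boundary plus the shared x=1 plane
    from mixdim.mesh import _boundary_faces, _cell_faces, _facet_key
    facets, ftags = [], []
    for face in _boundary_faces(cells):
        facets.append(face)
        ftags.append(11)
    count = {}
    for ci, cell in enumerate(cells):
        for face, _ in _cell_faces(cell):
            count.setdefault(_facet_key(face), []).append(ci)
    for face, cs in count.items():
        if len(cs) == 2 and tags[cs[0]] != tags[cs[1]]:
            facets.append(face)
            ftags.append(10)
    return mk.ParentMesh(verts, cells, np.asarray(facets),
                         np.asarray(tags), np.asarray(ftags),
                         cell_names={1: "left", 2: "right"},
                         facet_names={10: "interface", 11: "outer"})
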