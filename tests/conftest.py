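import numpy as np
import pytest

from germorder.tessellation import CellSnapshot


def square_lattice_snapshot(n: int = 21, spacing: float = 1.0) -> CellSnapshot:
    xx, yy = np.meshgrid(np.arange(n) * spacing, np.arange(n) * spacing)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    return CellSnapshot(time=0.0, ids=np.arange(len(pts)), positions=pts)


def triangular_lattice_snapshot(n: int = 20, a: float = 1.0) -> CellSnapshot:
    pts = [(c * a + (r % 2) * a / 2, r * a * np.sqrt(3) / 2)
           for r in range(n) for c in range(n)]
    pts = np.asarray(pts)
    return CellSnapshot(time=0.0, ids=np.arange(len(pts)), positions=pts)


def center_index(snap: CellSnapshot) -> int:
    c = snap.positions.mean(axis=0)
    return int(np.argmin(((snap.positions - c) ** 2).sum(axis=1)))


@pytest.fixture
def square_lattice() -> CellSnapshot:
    return square_lattice_snapshot()


@pytest.fixture
def triangular_lattice() -> CellSnapshot:
    return triangular_lattice_snapshot()


def flat_grid_mesh(n: int = 15, extent: float = 1.0):
    from scipy.spatial import Delaunay
    from germorder.mesh import SurfaceMesh

    xs = np.linspace(0, extent, n)
    xx, yy = np.meshgrid(xs, xs)
    pts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(n * n)])
    tri = Delaunay(pts[:, :2])
    return SurfaceMesh(pts, tri.simplices)


def icosphere_mesh(subdivisions: int = 3, radius: float = 1.0):
    import trimesh
    from germorder.mesh import SurfaceMesh

    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(np.asarray(ico.vertices, float), np.asarray(ico.faces, int))


def closed_cylinder_mesh(radius: float = 1.0, height: float = 4.0,
                         nring: int = 64, nz: int = 21):
    from germorder.mesh import SurfaceMesh

    zs = np.linspace(-height / 2, height / 2, nz)
    th = np.linspace(0, 2 * np.pi, nring, endpoint=False)
    V = np.vstack([np.column_stack([radius * np.cos(th), radius * np.sin(th),
                                    np.full(nring, z)]) for z in zs])
    faces = []
    for i in range(nz - 1):
        for j in range(nring):
            a = i * nring + j
            b = i * nring + (j + 1) % nring
            c = (i + 1) * nring + j
            d = (i + 1) * nring + (j + 1) % nring
            faces += [[a, b, d], [a, d, c]]
    top, bot = len(V), len(V) + 1
    V = np.vstack([V, [0, 0, height / 2], [0, 0, -height / 2]])
    for j in range(nring):
        faces.append([(nz - 1) * nring + j, (nz - 1) * nring + (j + 1) % nring, top])
        faces.append([(j + 1) % nring, j, bot])
    return SurfaceMesh(V, np.asarray(faces))
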