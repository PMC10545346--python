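"""Cell neighbor graphs and n-fold bond-orientational order parameters.

Cell--cell connectivity is approximated by a Voronoi tessellation of the
cell centroids (or taken from the true shared polygon edges of a simulated
vertex tissue).  The n-fold bond-orientational order parameter of cell *j*
is the edge-length-squared weighted phase sum

    psi_n(j) = sum_k l_jk^2 exp(i n theta_jk) / sum_k l_jk^2

over the Voronoi neighbors *k* of *j*, where ``l_jk`` is the length of the
shared Voronoi edge and ``theta_jk`` the angle of the separation vector
with the anterior--posterior (+x) axis.  |psi_n| ranges from 0 (no n-fold
order) to 1 (perfect n-fold order); its phase encodes the local lattice
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Voronoi

__all__ = [
    "CellSnapshot",
    "NeighborGraph",
    "OrderField",
    "voronoi_neighbors",
    "polygon_neighbors",
    "psi_n",
    "global_order",
]


@dataclass
class CellSnapshot:
    """All cell centroids at one time point.

    Parameters
    ----------
    time : float
        Time of the snapshot in hours.
    ids : (N,) int array
        Unique cell identifiers.
    positions : (N, 2) float array
        Planar centroid coordinates (um, or chart coordinates on a
        surface parameterization).
    parasegment : (N,) int array, optional
        Parasegment-row label per cell.
    boundary : (N,) bool array, optional
        Cells flagged as lying on the tissue boundary.
    """

    time: float
    ids: np.ndarray
    positions: np.ndarray
    parasegment: Optional[np.ndarray] = None
    boundary: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (N, 2) array")
        if len(self.ids) != len(self.positions):
            raise ValueError("ids and positions length mismatch")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("cell ids must be unique")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.time < 0:
            raise ValueError("time must be non-negative")

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, time: float = 0.0) -> "CellSnapshot":
        """Build from a DataFrame with columns cell_id, x, y [, parasegment]."""
        ps = df["parasegment"].to_numpy() if "parasegment" in df else None
        return cls(
            time=time,
            ids=df["cell_id"].to_numpy(),
            positions=df[["x", "y"]].to_numpy(float),
            parasegment=ps,
        )


@dataclass
class NeighborGraph:
    """Undirected cell adjacency with shared-edge weights.

    ``edges`` holds one row per undirected bond (j, k) with j < k by array
    index; ``lengths`` the shared Voronoi/polygon edge length l_jk and
    ``angles`` the bond angle theta_jk measured counterclockwise from the
    +x (anterior-posterior) axis for the j->k direction.  ``boundary``
    marks cells excluded from downstream statistics.
    """

    ids: np.ndarray
    edges: np.ndarray          # (M, 2) indices into ids
    lengths: np.ndarray        # (M,)
    angles: np.ndarray         # (M,) for the edges[:,0] -> edges[:,1] direction
    boundary: np.ndarray       # (N,) bool

    def neighbors_of(self, index: int) -> np.ndarray:
        m = (self.edges[:, 0] == index) | (self.edges[:, 1] == index)
        e = self.edges[m]
        return np.where(e[:, 0] == index, e[:, 1], e[:, 0])

    def degree(self) -> np.ndarray:
        deg = np.zeros(len(self.ids), dtype=int)
        np.add.at(deg, self.edges[:, 0], 1)
        np.add.at(deg, self.edges[:, 1], 1)
        return deg


@dataclass
class OrderField:
    """Per-cell complex bond-orientational order parameter psi_n."""

    n: int
    ids: np.ndarray
    psi: np.ndarray            # (N,) complex
    valid: np.ndarray          # (N,) bool: non-boundary cells with >=1 bond

    def __post_init__(self) -> None:
        mags = np.abs(self.psi[self.valid])
        if mags.size and mags.max() > 1 + 1e-12:
            raise ValueError("|psi_n| exceeded 1 beyond tolerance")


_EDGE_TOL_REL = 1e-6   # drop shared edges shorter than this x mean nn spacing
_JITTER_REL = 1e-9     # symmetry-breaking jitter for degenerate point sets


def _mean_nn_spacing(points: np.ndarray) -> float:
    from scipy.spatial import cKDTree

    d, _ = cKDTree(points).query(points, k=2)
    return float(np.mean(d[:, 1]))


def voronoi_neighbors(snapshot: CellSnapshot, jitter: bool = True,
                      seed: int = 0) -> NeighborGraph:
    """Voronoi adjacency of a cell snapshot.

    Bonds connect cells sharing a Voronoi edge of nonzero length; the
    degenerate zero-length edges arising from co-circular points (e.g.
    diagonal contacts on a perfect square lattice) are dropped.  Cells
    whose Voronoi region is unbounded or that lie on the convex hull of
    the point set are flagged ``boundary`` and excluded from downstream
    statistics.
    """
    pts = snapshot.positions
    if len(pts) < 4:
        raise ValueError("Voronoi tessellation requires at least 4 points")
    spacing = _mean_nn_spacing(pts)
    rank = np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-12 * spacing)
    if rank < 2:
        raise ValueError("points are collinear; Voronoi tessellation undefined")

    work = pts
    if jitter:
        rng = np.random.default_rng(seed)
        work = pts + rng.normal(scale=_JITTER_REL * spacing, size=pts.shape)

    vor = Voronoi(work)
    hull = ConvexHull(work)
    hull_idx = set(hull.vertices.tolist())

    # a cell is boundary when its region is unbounded or pokes out of the
    # convex hull of the point set ("touches the hull"); jittered degenerate
    # inputs can replace ideal infinite regions by pseudo-finite ones with
    # astronomically distant vertices, which the hull test also catches
    eq = hull.equations  # rows (a, b, c): a x + b y + c <= 0 inside
    tol_hull = 1e-9 * spacing
    boundary = np.zeros(len(pts), dtype=bool)
    for i, reg in enumerate(vor.point_region):
        region = vor.regions[reg]
        if -1 in region or len(region) == 0:
            boundary[i] = True
            continue
        rv = vor.vertices[region]
        dist = rv @ eq[:, :2].T + eq[:, 2]
        if np.any(dist > tol_hull):
            boundary[i] = True
    for i in hull_idx:
        boundary[i] = True

    tol = _EDGE_TOL_REL * spacing
    edges, lengths = [], []
    for (p, q), rv in zip(vor.ridge_points, vor.ridge_vertices):
        if -1 in rv:
            continue  # unbounded ridge: both cells already flagged boundary
        v0, v1 = vor.vertices[rv[0]], vor.vertices[rv[1]]
        ell = float(np.hypot(*(v1 - v0)))
        if ell <= tol:
            continue
        edges.append((min(p, q), max(p, q)))
        lengths.append(ell)

    edges = np.asarray(edges, dtype=int).reshape(-1, 2)
    lengths = np.asarray(lengths, dtype=float)
    sep = pts[edges[:, 1]] - pts[edges[:, 0]]
    angles = np.arctan2(sep[:, 1], sep[:, 0])
    return NeighborGraph(ids=snapshot.ids, edges=edges, lengths=lengths,
                         angles=angles, boundary=boundary)


def polygon_neighbors(tissue) -> NeighborGraph:
    """Adjacency of a vertex-model tissue from its true shared polygon edges.

    ``l_jk`` is the summed length of the polygon edges shared by cells j
    and k; ``theta_jk`` comes from the centroid separation.  Cells with a
    free (unshared) polygon edge are flagged boundary.
    """
    cells = tissue.cells
    verts = tissue.vertices
    n_cells = len(cells)
    if n_cells == 0:
        raise ValueError("empty tissue")

    edge_owner: dict[tuple[int, int], list[int]] = {}
    for ci, cyc in enumerate(cells):
        for a, b in zip(cyc, list(cyc[1:]) + [cyc[0]]):
            key = (min(a, b), max(a, b))
            edge_owner.setdefault(key, []).append(ci)

    shared: dict[tuple[int, int], float] = {}
    boundary = np.zeros(n_cells, dtype=bool)
    for (a, b), owners in edge_owner.items():
        if len(owners) > 2:
            raise ValueError("non-manifold cell complex: edge shared by >2 cells")
        ell = float(np.hypot(*(verts[b] - verts[a])))
        if len(owners) == 1:
            boundary[owners[0]] = True
            continue
        c0, c1 = sorted(owners)
        shared[(c0, c1)] = shared.get((c0, c1), 0.0) + ell

    centroids = tissue.centroids()
    edges = np.asarray(sorted(shared), dtype=int).reshape(-1, 2)
    lengths = np.asarray([shared[tuple(e)] for e in edges], dtype=float)
    sep = centroids[edges[:, 1]] - centroids[edges[:, 0]] if len(edges) else np.zeros((0, 2))
    angles = np.arctan2(sep[:, 1], sep[:, 0]) if len(edges) else np.zeros(0)
    ids = np.arange(n_cells)
    return NeighborGraph(ids=ids, edges=edges, lengths=lengths,
                         angles=angles, boundary=boundary)


def psi_n(snapshot_or_ids, graph: NeighborGraph, n: int) -> OrderField:
    """Edge-weighted n-fold bond-orientational order parameter per cell.

    Cells with no retained bond are marked invalid; boundary cells keep
    their value but are excluded by ``valid`` as well.
    """
    if n < 2:
        raise ValueError("order n must be >= 2")
    n_cells = len(graph.ids)
    num = np.zeros(n_cells, dtype=complex)
    den = np.zeros(n_cells, dtype=float)
    w = graph.lengths ** 2
    j, k = graph.edges[:, 0], graph.edges[:, 1]
    ph_jk = np.exp(1j * n * graph.angles)
    ph_kj = np.exp(1j * n * (graph.angles + np.pi))
    np.add.at(num, j, w * ph_jk)
    np.add.at(num, k, w * ph_kj)
    np.add.at(den, j, w)
    np.add.at(den, k, w)

    has_bond = den > 0
    psi = np.zeros(n_cells, dtype=complex)
    psi[has_bond] = num[has_bond] / den[has_bond]
    # guard against round-off pushing |psi| over 1
    mag = np.abs(psi)
    over = mag > 1.0
    psi[over] /= mag[over]
    valid = has_bond & ~graph.boundary
    return OrderField(n=n, ids=graph.ids, psi=psi, valid=valid)


def global_order(field: OrderField) -> tuple[float, float]:
    """Magnitude of the mean order parameter over valid cells, with SE.

    The standard error of the complex mean is propagated to the magnitude
    by projecting the component covariance onto the direction of the mean
    (falling back to the isotropic average when the mean vanishes).
    """
    vals = field.psi[field.valid]
    n = len(vals)
    if n == 0:
        raise ValueError("no valid cells")
    mean = vals.mean()
    mag = abs(mean)
    if n == 1:
        return mag, 0.0
    re, im = vals.real, vals.imag
    var_re = re.var(ddof=1) / n
    var_im = im.var(ddof=1) / n
    cov = np.cov(re, im, ddof=1)[0, 1] / n
    if mag > 1e-300:
        ux, uy = mean.real / mag, mean.imag / mag
        se = float(np.sqrt(max(ux * ux * var_re + uy * uy * var_im + 2 * ux * uy * cov, 0.0)))
    else:
        se = float(np.sqrt((var_re + var_im) / 2))
    return float(mag), se
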