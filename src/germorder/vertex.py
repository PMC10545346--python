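"""A 2D vertex model of oriented division waves.

Cells are simple polygons sharing vertices and edges; the tissue energy is

    e = sum_c (A_c - A0)^2 + k_P (P_c - P0)^2

with unit area stiffness, target area A0 = 1 and target perimeter
P0 = p0 sqrt(A0).  The default target shape index p0 = 4 is the shape
index of a perfect square, so a fresh square grid has zero energy.  The
tissue boundary is free (no substrate).  Divisions cut a cell through its
centroid perpendicular to the division axis (daughters separate along the
axis).  Before the cut the mother elongates along the division axis
(its targets swell to a 2:1 rectangle of twice the area, emulating
mitotic elongation); after the cut the daughters target the parent's
original square geometry, so the tissue doubles its area over a division
round while growth pushes only along the division axes.  The tissue is
relaxed quasi-statically (damped gradient descent with backtracking)
after every division, with T1 edge swaps applied to interior edges that
collapse below a threshold length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .tessellation import global_order, polygon_neighbors, psi_n

__all__ = ["VertexTissue", "WaveSchedule", "init_square_tissue", "shape_index",
           "tissue_energy", "relax", "divide_cell", "divide_with_growth",
           "run_division_round"]

T1_THRESHOLD_FACTOR = 0.05   # x sqrt(A0)
T1_NEW_LENGTH_FACTOR = 1.5   # x threshold


@dataclass
class VertexTissue:
    """Polygonal cell complex: shared vertices plus per-cell CCW cycles.

    ``A0`` and ``P0`` are per-cell target areas and perimeters (scalars
    broadcast at construction).
    """

    vertices: np.ndarray                 # (V, 2)
    cells: list[list[int]]
    A0: np.ndarray | float = 1.0
    P0: np.ndarray | float = 4.0
    k_P: float = 1.0
    lineage: np.ndarray = None           # divisions per cell lineage

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        n = len(self.cells)
        self.A0 = np.broadcast_to(np.asarray(self.A0, dtype=float), (n,)).copy()
        self.P0 = np.broadcast_to(np.asarray(self.P0, dtype=float), (n,)).copy()
        if self.lineage is None:
            self.lineage = np.zeros(n, dtype=int)
        self._topo = None

    def invalidate_topology(self) -> None:
        self._topo = None

    # -- geometry ---------------------------------------------------------
    def cell_areas(self) -> np.ndarray:
        return np.array([_poly_area(self.vertices[c]) for c in self.cells])

    def cell_perimeters(self) -> np.ndarray:
        return np.array([_poly_perimeter(self.vertices[c]) for c in self.cells])

    def centroids(self) -> np.ndarray:
        return np.array([_poly_centroid(self.vertices[c]) for c in self.cells])

    def copy(self) -> "VertexTissue":
        return VertexTissue(vertices=self.vertices.copy(),
                            cells=[list(c) for c in self.cells],
                            A0=self.A0.copy(), P0=self.P0.copy(), k_P=self.k_P,
                            lineage=self.lineage.copy())


@dataclass
class WaveSchedule:
    """Who divides when, and along which axes."""

    ordering: Literal["wave", "random"] = "wave"
    theta0: float = 0.0                  # von Mises location (A-P axis)
    kappa: float = np.inf                # doubled-angle concentration; inf = fixed axis
    rounds: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.rounds < 1:
            raise ValueError("need at least one round")


def _poly_area(p: np.ndarray) -> float:
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _poly_perimeter(p: np.ndarray) -> float:
    return float(np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1).sum())


def _poly_centroid(p: np.ndarray) -> np.ndarray:
    x, y = p[:, 0], p[:, 1]
    cr = x * np.roll(y, -1) - np.roll(x, -1) * y
    a = 0.5 * cr.sum()
    if abs(a) < 1e-14:
        return p.mean(axis=0)
    cx = np.sum((x + np.roll(x, -1)) * cr) / (6 * a)
    cy = np.sum((y + np.roll(y, -1)) * cr) / (6 * a)
    return np.array([cx, cy])


def init_square_tissue(rows: int, cols: int, p0: float = 4.0) -> VertexTissue:
    """Uniform square-grid tissue with unit cells; zero energy at p0 = 4."""
    if rows < 2 or cols < 2:
        raise ValueError("need rows, cols >= 2")
    # vertex (i, j) at (i, j), i in [0, cols], j in [0, rows]
    verts = np.array([[i, j] for j in range(rows + 1) for i in range(cols + 1)],
                     dtype=float)

    def vid(i: int, j: int) -> int:
        return j * (cols + 1) + i

    cells = []
    for j in range(rows):
        for i in range(cols):
            cells.append([vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)])
    return VertexTissue(vertices=verts, cells=cells, A0=1.0, P0=p0)


def shape_index(tissue: VertexTissue) -> np.ndarray:
    """Per-cell dimensionless shape index p = P / sqrt(A)."""
    A = tissue.cell_areas()
    if np.any(A <= 0):
        bad = int(np.argmin(A))
        raise ValueError(f"cell {bad} has non-positive area")
    return tissue.cell_perimeters() / np.sqrt(A)


def _flatten_topology(tissue: VertexTissue):
    """Edge-table view (cell id, vertex, prev, next) for vectorized energy;
    cached on the tissue and invalidated by topological moves."""
    if getattr(tissue, "_topo", None) is not None:
        return tissue._topo
    cell_of, v, vp, vn = [], [], [], []
    for ci, cyc in enumerate(tissue.cells):
        k = len(cyc)
        for a in range(k):
            cell_of.append(ci)
            v.append(cyc[a])
            vp.append(cyc[a - 1])
            vn.append(cyc[(a + 1) % k])
    tissue._topo = (np.asarray(cell_of), np.asarray(v), np.asarray(vp),
                    np.asarray(vn))
    return tissue._topo


def tissue_energy(tissue: VertexTissue, positions: Optional[np.ndarray] = None,
                  with_grad: bool = False):
    """Total energy (and optionally its gradient w.r.t. vertex positions)."""
    pos = tissue.vertices if positions is None else positions
    cell_of, v, vp, vn = _flatten_topology(tissue)
    n_cells = len(tissue.cells)
    P_v, Pp, Pn = pos[v], pos[vp], pos[vn]

    cross = P_v[:, 0] * Pn[:, 1] - P_v[:, 1] * Pn[:, 0]
    A = np.zeros(n_cells)
    np.add.at(A, cell_of, 0.5 * cross)
    seg = np.linalg.norm(Pn - P_v, axis=1)
    P = np.zeros(n_cells)
    np.add.at(P, cell_of, seg)

    dA = A - tissue.A0
    dP = P - tissue.P0
    E = float(np.sum(dA ** 2) + tissue.k_P * np.sum(dP ** 2))
    if not with_grad:
        return E

    grad = np.zeros_like(pos)
    # area gradient: dA_c/dv = 0.5 * rot90(next - prev)
    ga = 0.5 * np.column_stack([Pn[:, 1] - Pp[:, 1], Pp[:, 0] - Pn[:, 0]])
    coefA = 2.0 * dA[cell_of]
    np.add.at(grad, v, coefA[:, None] * ga)
    # perimeter gradient: unit vectors toward both neighbors
    d1 = P_v - Pp
    d2 = P_v - Pn
    n1 = np.linalg.norm(d1, axis=1)
    n2 = np.linalg.norm(d2, axis=1)
    n1[n1 == 0] = 1.0
    n2[n2 == 0] = 1.0
    gp = d1 / n1[:, None] + d2 / n2[:, None]
    coefP = 2.0 * tissue.k_P * dP[cell_of]
    np.add.at(grad, v, coefP[:, None] * gp)
    return E, grad


def _is_simple(poly: np.ndarray) -> bool:
    from shapely.geometry import Polygon
    try:
        return Polygon(poly).is_valid
    except Exception:
        return False


def _interior_edges(tissue: VertexTissue) -> dict[tuple[int, int], list[int]]:
    owners: dict[tuple[int, int], list[int]] = {}
    for ci, cyc in enumerate(tissue.cells):
        for a, b in zip(cyc, cyc[1:] + cyc[:1]):
            owners.setdefault((min(a, b), max(a, b)), []).append(ci)
    return owners


def _try_t1(tissue: VertexTissue, a: int, b: int) -> bool:
    """Attempt a T1 swap on interior edge (a, b); returns success."""
    owners = _interior_edges(tissue)
    cells_ab = owners.get((min(a, b), max(a, b)), [])
    if len(cells_ab) != 2:
        return False
    with_a = [ci for ci, cyc in enumerate(tissue.cells) if a in cyc]
    with_b = [ci for ci, cyc in enumerate(tissue.cells) if b in cyc]
    side_a = [ci for ci in with_a if ci not in cells_ab]
    side_b = [ci for ci in with_b if ci not in cells_ab]
    if len(side_a) != 1 or len(side_b) != 1:
        return False
    c1, c2 = cells_ab
    ca, cb = side_a[0], side_b[0]

    pa, pb = tissue.vertices[a], tissue.vertices[b]
    mid = 0.5 * (pa + pb)
    e = pb - pa
    en = np.linalg.norm(e)
    perp = (np.array([-e[1], e[0]]) / en) if en > 0 else np.array([1.0, 0.0])
    delta = T1_NEW_LENGTH_FACTOR * T1_THRESHOLD_FACTOR * np.sqrt(tissue.A0.mean())
    # orient the new edge so vertex a lands on cell c1's side
    cen1 = _poly_centroid(tissue.vertices[tissue.cells[c1]])
    if np.dot(cen1 - mid, perp) < 0:
        perp = -perp

    old_vertices = tissue.vertices.copy()
    old_cells = [list(c) for c in tissue.cells]
    tissue.vertices[a] = mid + 0.5 * delta * perp
    tissue.vertices[b] = mid - 0.5 * delta * perp
    tissue.cells[c1] = [x for x in tissue.cells[c1] if x != b]
    tissue.cells[c2] = [x for x in tissue.cells[c2] if x != a]

    def insert_after(cyc: list[int], anchor: int, new: int) -> list[int]:
        i = cyc.index(anchor)
        return cyc[:i + 1] + [new] + cyc[i + 1:]

    # the new edge runs a-b inside both side cells; its traversal direction
    # must be opposite in the two CCW cycles -- try both assignments
    for first in (True, False):
        if first:
            tissue.cells[ca] = insert_after(list(old_cells[ca]), a, b)
            tissue.cells[cb] = insert_after(list(old_cells[cb]), b, a)
        else:
            tissue.cells[ca] = _insert_before(list(old_cells[ca]), a, b)
            tissue.cells[cb] = _insert_before(list(old_cells[cb]), b, a)
        ok = all(len(tissue.cells[ci]) >= 3 and
                 _poly_area(tissue.vertices[tissue.cells[ci]]) > 0 and
                 _is_simple(tissue.vertices[tissue.cells[ci]])
                 for ci in (c1, c2, ca, cb))
        if ok:
            tissue.invalidate_topology()
            return True
    tissue.vertices[:] = old_vertices
    tissue.cells[:] = [list(c) for c in old_cells]
    tissue.invalidate_topology()
    return False


def _insert_before(cyc: list[int], anchor: int, new: int) -> list[int]:
    i = cyc.index(anchor)
    return cyc[:i] + [new] + cyc[i:]


def relax(tissue: VertexTissue, tol: float = 1e-6, max_iter: int = 150,
          t1_passes: int = 4) -> tuple[VertexTissue, bool]:
    """Quasi-static relaxation: energy descent to force tolerance.

    Minimizes the tissue energy over vertex positions (L-BFGS, analytic
    gradient), then applies T1 swaps to interior edges shorter than the
    threshold and repeats, up to ``t1_passes`` topology passes.  Returns
    (tissue, converged); non-convergence is flagged, never raised.
    """
    converged = True
    for _ in range(t1_passes):
        # damped gradient descent with backtracking: follows the physical
        # force field, which preserves the symmetric relaxation paths that
        # keep lattice rows aligned during division waves
        pos = tissue.vertices
        e, g = tissue_energy(tissue, pos, with_grad=True)
        alpha = 0.1
        converged = False
        for _it in range(max_iter):
            gmax = np.max(np.abs(g))
            if gmax < tol:
                converged = True
                break
            for _bt in range(30):
                trial = pos - alpha * g
                e_new = tissue_energy(tissue, trial)
                if e_new <= e:
                    break
                alpha *= 0.5
            else:
                converged = gmax < 10 * tol
                break
            pos = trial
            e = e_new
            g = tissue_energy(tissue, pos, with_grad=True)[1]
            alpha = min(alpha * 1.2, 1.0)
        tissue.vertices = pos

        thresh = T1_THRESHOLD_FACTOR * np.sqrt(tissue.A0.mean())
        swapped = False
        owners = _interior_edges(tissue)
        for (a, b), cs in owners.items():
            if len(cs) != 2:
                continue
            if np.linalg.norm(tissue.vertices[a] - tissue.vertices[b]) < thresh:
                if _try_t1(tissue, a, b):
                    swapped = True
                    break
        if not swapped:
            break
    return tissue, converged


def divide_cell(tissue: VertexTissue, cell: int, axis: float) -> tuple[int, int]:
    """Split a cell by the centroid line whose normal is the division axis.

    The daughters separate along ``axis``; the daughter areas sum to the
    parent area at the instant of the cut.  Returns the two daughter cell
    indices (the first reuses the parent's slot); both lineage counters
    are incremented.  Raises if the cut cannot produce two simple
    polygons.
    """
    cyc = tissue.cells[cell]
    poly = tissue.vertices[cyc]
    cen = _poly_centroid(poly)
    nhat = np.array([np.cos(axis), np.sin(axis)])

    for trial_rot in (0.0, 0.08, -0.08, 0.16, -0.16, 0.3, -0.3):
        c, s = np.cos(trial_rot), np.sin(trial_rot)
        n_try = np.array([c * nhat[0] - s * nhat[1], s * nhat[0] + c * nhat[1]])
        sv = (poly - cen) @ n_try
        if np.any(np.abs(sv) < 1e-12):
            sv = sv + 1e-9
        cross_at = [i for i in range(len(cyc)) if sv[i] * sv[(i + 1) % len(cyc)] < 0]
        if len(cross_at) == 2:
            break
    else:
        raise ValueError(f"cannot cut cell {cell} into two simple polygons")

    new_ids = []
    k = len(cyc)
    insert_info = []
    snap = 0.12 * np.sqrt(max(abs(_poly_area(poly)), 1e-12))
    for i in cross_at:
        va, vb = cyc[i], cyc[(i + 1) % k]
        t = sv[i] / (sv[i] - sv[(i + 1) % k])
        p = tissue.vertices[va] + t * (tissue.vertices[vb] - tissue.vertices[va])
        # reuse an existing endpoint when the cut passes close by: avoids
        # near-duplicate vertices and the tiny-edge T1 churn they cause
        if np.linalg.norm(p - tissue.vertices[va]) < snap:
            new_ids.append(va)
            insert_info.append(None)
            continue
        if np.linalg.norm(p - tissue.vertices[vb]) < snap:
            new_ids.append(vb)
            insert_info.append(None)
            continue
        tissue.vertices = np.vstack([tissue.vertices, p[None, :]])
        new_ids.append(len(tissue.vertices) - 1)
        insert_info.append((va, vb))
    if new_ids[0] == new_ids[1]:
        raise ValueError(f"cut of cell {cell} collapsed to a single vertex")

    # insert genuinely new vertices into every cell sharing the cut edges
    for info, nid in zip(insert_info, new_ids):
        if info is None:
            continue
        va, vb = info
        for ci, c2 in enumerate(tissue.cells):
            kk = len(c2)
            for j in range(kk):
                x, y = c2[j], c2[(j + 1) % kk]
                if {x, y} == {va, vb}:
                    tissue.cells[ci] = c2[:j + 1] + [nid] + c2[j + 1:]
                    break
            else:
                continue
            break  # each edge belongs to at most... (handled below)
    # the loop above inserted into the first cell found; also handle the
    # second owner of each edge
    for info, nid in zip(insert_info, new_ids):
        if info is None:
            continue
        va, vb = info
        for ci, c2 in enumerate(tissue.cells):
            if nid in c2:
                continue
            kk = len(c2)
            for j in range(kk):
                x, y = c2[j], c2[(j + 1) % kk]
                if {x, y} == {va, vb}:
                    tissue.cells[ci] = c2[:j + 1] + [nid] + c2[j + 1:]
                    break

    # split the parent cycle at the two new vertices
    cyc = tissue.cells[cell]
    i1, i2 = sorted((cyc.index(new_ids[0]), cyc.index(new_ids[1])))
    half1 = cyc[i1:i2 + 1]
    half2 = cyc[i2:] + cyc[:i1 + 1]
    if len(half1) < 3 or len(half2) < 3:
        raise ValueError(f"cut of cell {cell} produced a degenerate polygon")
    a1 = _poly_area(tissue.vertices[half1])
    a2 = _poly_area(tissue.vertices[half2])
    if a1 <= 0 or a2 <= 0:
        raise ValueError(f"cut of cell {cell} produced a non-simple polygon")

    tissue.cells[cell] = half1
    tissue.cells.append(half2)
    parent_count = tissue.lineage[cell]
    tissue.lineage[cell] = parent_count + 1
    tissue.lineage = np.append(tissue.lineage, parent_count + 1)
    # daughters target half the parent's area at the parent's shape index
    p_idx = tissue.P0[cell] / np.sqrt(tissue.A0[cell])
    a_d = tissue.A0[cell] / 2.0
    tissue.A0[cell] = a_d
    tissue.P0[cell] = p_idx * np.sqrt(a_d)
    tissue.A0 = np.append(tissue.A0, a_d)
    tissue.P0 = np.append(tissue.P0, p_idx * np.sqrt(a_d))
    tissue.invalidate_topology()
    return cell, len(tissue.cells) - 1


def divide_with_growth(tissue: VertexTissue, cell: int, axis: float
                       ) -> tuple[int, int]:
    """Mitotic elongation, cut, and post-division relaxation.

    The mother's targets are set to a 2:1 rectangle of twice its area
    elongated along ``axis`` and the tissue relaxed; the cell is then cut
    and both daughters restored to the mother's original target geometry
    before a final relaxation.
    """
    a0 = float(tissue.A0[cell])
    p0 = float(tissue.P0[cell])
    tissue.A0[cell] = 2.0 * a0
    tissue.P0[cell] = 6.0 * np.sqrt(a0)   # perimeter of the 2:1 rectangle
    relax(tissue)
    d1, d2 = divide_cell(tissue, cell, axis)
    for d in (d1, d2):
        tissue.A0[d] = a0
        tissue.P0[d] = p0
    relax(tissue)
    return d1, d2


def _wave_order(tissue: VertexTissue) -> list[int]:
    """Anterior-to-posterior rows, midline outward within each row."""
    cen = tissue.centroids()
    mid = 0.5 * (cen[:, 1].min() + cen[:, 1].max())
    side = np.sqrt(np.median(tissue.cell_areas()))
    rows = np.floor((cen[:, 0] - cen[:, 0].min()) / side + 0.25).astype(int)
    keys = list(zip(rows, np.abs(cen[:, 1] - mid), cen[:, 1], range(len(cen))))
    return [k[3] for k in sorted(keys)]


def run_division_round(tissue: VertexTissue, schedule: WaveSchedule,
                       record_every: int = 1):
    """Run full division rounds: every pre-round cell divides exactly once.

    After each division the tissue is relaxed and the global fourfold and
    sixfold order recorded (from the true shared-polygon adjacency).
    Returns (tissue, records): records are dicts with event index,
    dividing cell, axis, post-relax energy, |psi4| and |psi6|.
    """
    from .synthetic import sample_nematic_von_mises

    rng = np.random.default_rng(schedule.seed)
    records: list[dict] = []
    event = 0
    for _ in range(schedule.rounds):
        if schedule.ordering == "wave":
            order = _wave_order(tissue)
        else:
            order = list(rng.permutation(len(tissue.cells)))
        axes = sample_nematic_von_mises(len(order), schedule.kappa,
                                        schedule.theta0, rng)
        for ci, ax in zip(order, axes):
            divide_with_growth(tissue, ci, float(ax))
            event += 1
            if event % record_every == 0:
                rec = {"event": event, "cell": ci, "axis": float(ax),
                       "energy": tissue_energy(tissue)}
                g = polygon_neighbors(tissue)
                for n in (4, 6):
                    fld = psi_n(None, g, n)
                    if fld.valid.any():
                        rec[f"psi{n}"] = global_order(fld)[0]
                    else:
                        rec[f"psi{n}"] = float("nan")
                records.append(rec)
    return tissue, records
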