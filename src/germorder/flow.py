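"""Division-driven tissue flow: FEM boundary-value solver, amplitude fits
and the normalized velocity residual.

Tissue velocity v solves the renormalized active-elastic problem

    laplacian(v) + 1/(1 - 2 nu) grad(div v) = 0

in the tissue domain with circular holes excised at dividing cells
(active forces live on the hole boundaries).  Dirichlet data: measured
velocities on the exterior boundary; on each hole boundary the analytic
displacement field of that inclusion plus a uniform advection velocity.
The solver is a piecewise-linear (P1) Galerkin discretization assembled
from the weak form  integral( grad u : grad v + (1/(1-2 nu)) div u div v ).

Predictions are scored with the scale-invariant velocity residual

    R(x) = |<v> u(x) - <u> v(x)|^2 / (2 <u>^2 <v>^2),

where <.> is the root-mean-square field magnitude; R = 0 for fields equal
up to a positive scale and R = 1 for typical-magnitude orthogonal fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.interpolate import LinearNDInterpolator
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve
from scipy.spatial import Delaunay

from .eshelby import InclusionSpec, inclusion_displacement, interior_strain

__all__ = [
    "HydroParams", "FlowField", "ResidualMap", "TriMesh",
    "punctured_rectangle_mesh", "annulus_mesh", "solve_navier",
    "solve_tissue_flow", "fit_inclusion_params", "velocity_residual",
    "division_only_prediction", "average_division_flow",
]


@dataclass
class HydroParams:
    """Effective-medium parameter of the renormalized flow equation.

    The shear and bulk viscosities of the dimensional model are absorbed
    into the single Poisson-like ratio nu of the renormalized form; they
    never enter the numerics individually.
    """

    nu: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if not -1.0 < self.nu < 0.5:
            raise ValueError("nu must lie in (-1, 1/2)")


@dataclass
class FlowField:
    """A sampled 2D velocity field."""

    points: np.ndarray       # (N, 2)
    vectors: np.ndarray      # (N, 2), um/h
    provenance: str = "measured"   # measured | predicted | division_only

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if self.points.shape != self.vectors.shape:
            raise ValueError("points/vectors shape mismatch")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("velocity vectors must be finite")

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.sum(self.vectors ** 2, axis=1))))


@dataclass
class ResidualMap:
    points: np.ndarray
    residual: np.ndarray
    u_rms: float
    v_rms: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.residual))


@dataclass
class TriMesh:
    """A conforming triangulation with tagged boundary node groups."""

    nodes: np.ndarray                 # (N, 2)
    triangles: np.ndarray             # (T, 3)
    exterior_nodes: np.ndarray        # indices
    hole_nodes: list[np.ndarray] = field(default_factory=list)  # per hole


def _circle_points(cx: float, cy: float, r: float, n: int,
                   phase: float = 0.0) -> np.ndarray:
    th = phase + np.arange(n) * (2 * np.pi / n)
    return np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])


def punctured_rectangle_mesh(rect: tuple[float, float, float, float],
                             holes: Sequence[tuple[float, float, float]],
                             h: Optional[float] = None) -> TriMesh:
    """Delaunay mesh of a rectangle with circular holes excised.

    ``holes`` are (cx, cy, radius).  Target edge length is ``h`` in the
    bulk and at most radius/4 on hole rims.  Overlapping holes or holes
    touching the exterior boundary raise.
    """
    x0, y0, x1, y1 = rect
    if x1 <= x0 or y1 <= y0:
        raise ValueError("degenerate rectangle")
    holes = list(holes)
    for i, (cx, cy, a) in enumerate(holes):
        if a <= 0:
            raise ValueError(f"hole {i} has non-positive radius")
        if (cx - a <= x0 or cx + a >= x1 or cy - a <= y0 or cy + a >= y1):
            raise ValueError(f"hole {i} touches the exterior boundary")
        for j, (ox, oy, oa) in enumerate(holes[:i]):
            if np.hypot(cx - ox, cy - oy) < a + oa:
                raise ValueError(f"holes {j} and {i} overlap")
    if h is None:
        h = min(x1 - x0, y1 - y0) / 24.0
        if holes:
            h = min(h, min(a for _, _, a in holes))

    xs = np.linspace(x0, x1, max(int(round((x1 - x0) / h)) + 1, 2))
    ys = np.linspace(y0, y1, max(int(round((y1 - y0) / h)) + 1, 2))
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel()])

    keep = np.ones(len(grid), dtype=bool)
    ring_pts = []
    hole_slices = []
    for cx, cy, a in holes:
        h_rim = min(a / 4.0, h)
        n_rim = max(int(np.ceil(2 * np.pi * a / h_rim)), 12)
        d = np.hypot(grid[:, 0] - cx, grid[:, 1] - cy)
        keep &= d > a + 0.55 * h_rim
        rim = _circle_points(cx, cy, a, n_rim)
        guard = _circle_points(cx, cy, a + h_rim, n_rim, phase=np.pi / n_rim)
        ring_pts.append((rim, guard))

    pts = [grid[keep]]
    offset = len(pts[0])
    for rim, guard in ring_pts:
        hole_slices.append(np.arange(offset, offset + len(rim)))
        pts.append(rim)
        offset += len(rim)
        pts.append(guard)
        offset += len(guard)
    nodes = np.vstack(pts)

    tri = Delaunay(nodes)
    cent = nodes[tri.simplices].mean(axis=1)
    good = np.ones(len(tri.simplices), dtype=bool)
    for cx, cy, a in holes:
        good &= np.hypot(cent[:, 0] - cx, cent[:, 1] - cy) > a * (1 - 1e-9)
    # drop slivers hugging the rectangle edge with near-zero area
    tris = tri.simplices[good]
    p = nodes[tris]
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    areas = 0.5 * np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
    tris = tris[areas > 1e-12 * h * h]

    # compact away nodes orphaned by hole excision
    used = np.zeros(len(nodes), dtype=bool)
    used[tris.ravel()] = True
    remap = -np.ones(len(nodes), dtype=int)
    remap[used] = np.arange(used.sum())
    nodes = nodes[used]
    tris = remap[tris]
    hole_slices = [remap[s][remap[s] >= 0] for s in hole_slices]

    tol = 1e-9 * max(x1 - x0, y1 - y0)
    ext = np.where((np.abs(nodes[:, 0] - x0) < tol) | (np.abs(nodes[:, 0] - x1) < tol)
                   | (np.abs(nodes[:, 1] - y0) < tol) | (np.abs(nodes[:, 1] - y1) < tol))[0]
    return TriMesh(nodes=nodes, triangles=tris, exterior_nodes=ext,
                   hole_nodes=hole_slices)


def annulus_mesh(a: float, R: float, n_rings: int = 40,
                 center: tuple[float, float] = (0.0, 0.0)) -> TriMesh:
    """Graded polar mesh of the annulus a <= r <= R (for oracle tests)."""
    if not 0 < a < R:
        raise ValueError("need 0 < a < R")
    radii = a * (R / a) ** (np.arange(n_rings + 1) / n_rings)  # geometric grading
    pts = []
    ring_idx = []
    offset = 0
    for k, r in enumerate(radii):
        n = max(int(np.ceil(2 * np.pi * r / (radii[min(k + 1, n_rings)] - radii[max(k - 1, 0)]) * 0.9)), 16)
        n = min(n, 512)
        ring = _circle_points(center[0], center[1], r, n, phase=(k % 2) * np.pi / n)
        ring_idx.append(np.arange(offset, offset + n))
        offset += n
        pts.append(ring)
    nodes = np.vstack(pts)
    tri = Delaunay(nodes)
    cent = nodes[tri.simplices].mean(axis=1)
    rr = np.hypot(cent[:, 0] - center[0], cent[:, 1] - center[1])
    tris = tri.simplices[(rr > a) & (rr < R)]
    return TriMesh(nodes=nodes, triangles=tris, exterior_nodes=ring_idx[-1],
                   hole_nodes=[ring_idx[0]])


def _assemble_stiffness(mesh: TriMesh, nu: float) -> coo_matrix:
    nodes, tris = mesh.nodes, mesh.triangles
    c_fac = 1.0 / (1.0 - 2.0 * nu)
    p = nodes[tris]                                    # (T, 3, 2)
    v1 = p[:, 1] - p[:, 0]
    v2 = p[:, 2] - p[:, 0]
    det = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    if np.any(np.abs(det) < 1e-30):
        raise ValueError("non-conforming mesh: degenerate triangle")
    area = 0.5 * np.abs(det)
    # gradients of P1 basis functions
    g = np.empty((len(tris), 3, 2))
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        g[:, i, 0] = (p[:, j, 1] - p[:, k, 1])
        g[:, i, 1] = (p[:, k, 0] - p[:, j, 0])
    g /= det[:, None, None]
    n = len(nodes)
    G = np.einsum("tid,tjd->tij", g, g)                # grad.grad
    rows, cols, vals = [], [], []
    for a_ in range(2):
        for b_ in range(2):
            # K[(i,a),(j,b)] = area * (delta_ab G_ij + c_fac g_i^a g_j^b)
            blk = c_fac * np.einsum("ti,tj->tij", g[:, :, a_], g[:, :, b_])
            if a_ == b_:
                blk = blk + G
            blk = blk * area[:, None, None]
            ii = np.repeat(tris, 3, axis=1) + a_ * n   # (T, 9)
            jj = np.tile(tris, (1, 3)) + b_ * n
            rows.append(ii.ravel())
            cols.append(jj.ravel())
            vals.append(blk.reshape(len(tris), 9).ravel())
    return coo_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(2 * n, 2 * n))


def solve_navier(mesh: TriMesh, dirichlet: dict[int, tuple[float, float]],
                 nu: float = 1.0 / 3.0) -> np.ndarray:
    """Solve the renormalized flow equation with Dirichlet data.

    ``dirichlet`` maps node index -> velocity vector; returns (N, 2)
    nodal velocities.
    """
    n = len(mesh.nodes)
    K = _assemble_stiffness(mesh, nu).tocsr()
    fixed = np.fromiter(dirichlet.keys(), dtype=int)
    vals = np.asarray([dirichlet[i] for i in fixed], dtype=float)
    fixed_dofs = np.concatenate([fixed, fixed + n])
    fixed_vals = np.concatenate([vals[:, 0], vals[:, 1]])
    free = np.setdiff1d(np.arange(2 * n), fixed_dofs)
    u = np.zeros(2 * n)
    u[fixed_dofs] = fixed_vals
    rhs = -K[free][:, fixed_dofs] @ fixed_vals
    u[free] = spsolve(K[free][:, free].tocsc(), rhs)
    return u.reshape(2, n).T


def solve_tissue_flow(
    domain: tuple[float, float, float, float],
    inclusions: Sequence[InclusionSpec],
    exterior_velocity: Callable[[np.ndarray], np.ndarray] | np.ndarray,
    advection: tuple[float, float] = (0.0, 0.0),
    nu: float = 1.0 / 3.0,
    mesh_size: Optional[float] = None,
    mesh: Optional[TriMesh] = None,
) -> tuple[FlowField, TriMesh]:
    """Predict tissue velocities from divisions in a rectangular domain.

    Each inclusion's hole boundary carries its own analytic displacement
    plus the uniform advection velocity; the exterior boundary carries the
    supplied (measured) velocities, given either as a callable on points
    or a constant vector.  Returns nodal velocities and the mesh.
    """
    if mesh is None:
        mesh = punctured_rectangle_mesh(
            domain, [(s.center[0], s.center[1], s.radius) for s in inclusions],
            h=mesh_size)
    adv = np.asarray(advection, dtype=float)
    dirichlet: dict[int, tuple[float, float]] = {}
    ext_pts = mesh.nodes[mesh.exterior_nodes]
    if callable(exterior_velocity):
        ext_v = np.atleast_2d(np.asarray(exterior_velocity(ext_pts), dtype=float))
    else:
        ext_v = np.broadcast_to(np.asarray(exterior_velocity, dtype=float),
                                ext_pts.shape)
    for idx, v in zip(mesh.exterior_nodes, ext_v):
        dirichlet[int(idx)] = (float(v[0]), float(v[1]))
    for spec, ring in zip(inclusions, mesh.hole_nodes):
        u_ring = inclusion_displacement(mesh.nodes[ring], spec, nu=nu,
                                        strict_exterior=False) + adv
        for idx, v in zip(ring, u_ring):
            dirichlet[int(idx)] = (float(v[0]), float(v[1]))
    sol = solve_navier(mesh, dirichlet, nu=nu)
    return FlowField(points=mesh.nodes, vectors=sol, provenance="predicted"), mesh


def velocity_residual(u: FlowField, v: FlowField) -> ResidualMap:
    """Normalized velocity residual between prediction u and measurement v.

    Requires both fields on identical sample locations and nonzero RMS
    magnitudes.  Symmetric in (u, v) and pointwise non-negative.
    """
    if u.points.shape != v.points.shape or not np.allclose(u.points, v.points):
        raise ValueError("fields must be sampled at identical locations")
    gu, gv = u.rms(), v.rms()
    if gu == 0 or gv == 0:
        raise ValueError("velocity residual undefined for a zero field")
    diff = gv * u.vectors - gu * v.vectors
    r = np.sum(diff ** 2, axis=1) / (2 * gu ** 2 * gv ** 2)
    return ResidualMap(points=u.points, residual=r, u_rms=gu, v_rms=gv)


def division_only_prediction(
    inclusions: Sequence[InclusionSpec],
    points: np.ndarray,
    nu: float = 1.0 / 3.0,
    M: Optional[float] = None,
    q: Optional[float] = None,
) -> FlowField:
    """Superposed analytic inclusion fields, with no boundary-value solve.

    Points inside an inclusion get that inclusion's uniform interior
    field.  ``M``/``q`` override the per-inclusion amplitudes when given.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    total = np.zeros_like(pts)
    for spec in inclusions:
        if M is not None or q is not None:
            spec = InclusionSpec(center=spec.center, radius=spec.radius,
                                 M=spec.M if M is None else M,
                                 q=spec.q if q is None else q, axis=spec.axis)
        rel = pts - np.asarray(spec.center)
        r = np.hypot(rel[:, 0], rel[:, 1])
        inside = r < spec.radius
        u = inclusion_displacement(pts, spec, nu=nu, strict_exterior=False)
        if inside.any():
            u[inside] = rel[inside] @ interior_strain(spec, nu).T
        total += u
    return FlowField(points=pts, vectors=total, provenance="division_only")


def fit_inclusion_params(
    measured: FlowField,
    inclusions: Sequence[InclusionSpec],
    domain: tuple[float, float, float, float],
    nu: float = 1.0 / 3.0,
    advection: Optional[tuple[float, float]] = None,
    mesh_size: Optional[float] = None,
    grid: Sequence[float] = (-1.0, -0.5, 0.0, 0.5, 1.0),
    exterior_velocity: Optional[Callable[[np.ndarray], np.ndarray] | np.ndarray] = None,
) -> tuple[float, float, FlowField]:
    """Fit the shared inclusion amplitudes (M, q) to a measured field.

    The predicted field is affine in (M, q), so three FEM solves give the
    full family; the mean velocity residual against ``measured`` is then
    minimized deterministically from a fixed 5x5 start grid (Nelder-Mead
    refinement; ties broken by smallest |q|).  Sample locations of
    ``measured`` falling inside holes are excluded from the fit.
    """
    if len(inclusions) == 0:
        raise ValueError("no divisions in frame: use a homogeneous solve instead")
    if measured.rms() == 0:
        # the residual is scale-invariant, so a zero measured field admits
        # any parallel prediction; the zero-residual solution is (0, 0)
        return 0.0, 0.0, FlowField(points=measured.points,
                                   vectors=np.zeros_like(measured.vectors),
                                   provenance="predicted")
    if advection is None:
        advection = tuple(measured.vectors.mean(axis=0))
    mesh = punctured_rectangle_mesh(
        domain, [(s.center[0], s.center[1], s.radius) for s in inclusions],
        h=mesh_size)

    def solve(mm: float, qq: float, ext, adv) -> np.ndarray:
        specs = [InclusionSpec(center=s.center, radius=s.radius, M=mm, q=qq,
                               axis=s.axis) for s in inclusions]
        f, _ = solve_tissue_flow(domain, specs, ext, advection=adv, nu=nu,
                                 mesh=mesh)
        return f.vectors

    if exterior_velocity is None:
        # fall back to the measured field, nearest-sample extrapolated at the rim
        meas_interp = LinearNDInterpolator(measured.points, measured.vectors)

        def ext_measured(pts: np.ndarray) -> np.ndarray:
            v = meas_interp(pts)
            bad = ~np.isfinite(v[:, 0])
            if bad.any():
                from scipy.spatial import cKDTree
                _, nn = cKDTree(measured.points).query(pts[bad])
                v[bad] = measured.vectors[nn]
            return v

        exterior_velocity = ext_measured

    u00 = solve(0.0, 0.0, exterior_velocity, advection)
    uM = solve(1.0, 0.0, lambda p: np.zeros_like(p), (0.0, 0.0))
    uq = solve(0.0, 1.0, lambda p: np.zeros_like(p), (0.0, 0.0))

    interp00 = LinearNDInterpolator(mesh.nodes, u00)
    interpM = LinearNDInterpolator(mesh.nodes, uM)
    interpQ = LinearNDInterpolator(mesh.nodes, uq)
    s00 = interp00(measured.points)
    sM = interpM(measured.points)
    sQ = interpQ(measured.points)
    ok = np.isfinite(s00[:, 0]) & np.isfinite(sM[:, 0]) & np.isfinite(sQ[:, 0])
    if ok.sum() < 3:
        raise ValueError("too few measurement points outside the holes")
    vmeas = measured.vectors[ok]
    pts_ok = measured.points[ok]

    def objective(x: np.ndarray) -> float:
        pred = s00[ok] + x[0] * sM[ok] + x[1] * sQ[ok]
        if not np.any(np.sum(pred ** 2, axis=1) > 0):
            return 1.0
        r = velocity_residual(FlowField(pts_ok, pred, "predicted"),
                              FlowField(pts_ok, vmeas, "measured"))
        return r.mean

    best = None
    for m0 in grid:
        for q0 in grid:
            res = optimize.minimize(objective, x0=[m0, q0],
                                    method="Nelder-Mead",
                                    options={"xatol": 1e-6, "fatol": 1e-10,
                                             "maxiter": 400})
            cand = (res.fun, abs(res.x[1]), tuple(res.x))
            if best is None or cand[:2] < best[:2]:
                best = cand
    M_hat, q_hat = best[2]
    pred = s00[ok] + M_hat * sM[ok] + q_hat * sQ[ok]
    fitted = FlowField(points=pts_ok, vectors=pred, provenance="predicted")
    return float(M_hat), float(q_hat), fitted


def average_division_flow(
    patches: Sequence[dict],
    grid_radius: float = 3.0,
    grid_n: int = 41,
) -> FlowField:
    """Average division-local velocity patches in a common reference frame.

    Each patch is a dict with keys ``points`` (K, 2), ``velocities``
    (K, 2), ``com`` (daughter center of mass) and ``axis`` (division axis,
    rad).  Patches are translated to the origin and rotated so the
    division axis lies along +y, velocities co-rotated, interpolated onto
    a common grid and averaged pointwise; patches without daughter
    positions (``com``) are skipped with a warning.
    """
    import warnings

    xs = np.linspace(-grid_radius, grid_radius, grid_n)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    gpts = np.column_stack([gx.ravel(), gy.ravel()])
    gpts = gpts[np.hypot(gpts[:, 0], gpts[:, 1]) <= grid_radius]

    acc = np.zeros_like(gpts)
    cnt = np.zeros(len(gpts))
    used = 0
    for i, patch in enumerate(patches):
        if patch.get("com") is None:
            warnings.warn(f"patch {i} has no daughter positions; skipped")
            continue
        ang = np.pi / 2 - float(patch["axis"])
        c, s = np.cos(ang), np.sin(ang)
        R = np.array([[c, -s], [s, c]])
        pts = (np.asarray(patch["points"], float) - np.asarray(patch["com"], float)) @ R.T
        vel = np.asarray(patch["velocities"], float) @ R.T
        interp = LinearNDInterpolator(pts, vel)
        v = interp(gpts)
        good = np.isfinite(v[:, 0])
        acc[good] += v[good]
        cnt[good] += 1
        used += 1
    if used == 0:
        raise ValueError("no usable patches")
    out = np.zeros_like(acc)
    nz = cnt > 0
    out[nz] = acc[nz] / cnt[nz, None]
    return FlowField(points=gpts[nz], vectors=out[nz], provenance="predicted")
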