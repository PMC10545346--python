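"""Synthetic inputs: disordered nulls, ordered controls and a germband emulator.

The germband generator reproduces, at the track level, the proliferation
choreography of the crustacean trunk ectoderm: parasegment precursor rows
(PSPRs) assembled anterior to posterior, two successive mitotic waves per
row that start at the ventral midline and spread dorsally, division axes
drawn from a nematic von Mises distribution about the A-P axis, and
exponential growth of the cell count with a configurable doubling time.
Rows are static in space and daughters are placed symmetrically about the
mother along the division axis, so the emitted division events advance
exactly at the configured A-P and D-V wave speeds (up to timing jitter)
and snapshots remain a plausible, nearly rectangular lattice.

Null models: blue-noise (Poisson-disc / Bridson) point patterns at a
matched density, and square lattices perturbed by Gaussian noise with a
configurable signal-to-noise ratio (signal = lattice constant).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import special

from .kinetics import DivisionEvent, LineageForest, wrap_nematic
from .tessellation import CellSnapshot

__all__ = [
    "NullModelParams",
    "SyntheticGermbandParams",
    "GermbandRealization",
    "poisson_disc",
    "noisy_lattice",
    "synth_germband",
    "ks_two_sample",
    "sample_nematic_von_mises",
]

_BRIDSON_DENSITY = 0.678  # empirical points per r_min^2 delivered by Bridson


@dataclass
class NullModelParams:
    """Geometry and sampling parameters for the synthetic null models."""

    length: float                      # rectangle extent along A-P (um)
    width: float                       # rectangle extent along D-V (um)
    density: float                     # target cell density (cells / um^2)
    min_spacing: Optional[float] = None  # Poisson-disc exclusion radius (um)
    lattice_constant: Optional[float] = None  # noisy-lattice spacing (um)
    snr: float = 5.0                   # lattice constant / noise SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValueError("rectangle dimensions must be positive")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.snr <= 0:
            raise ValueError("snr must be positive")


def _bridson(length: float, width: float, r_min: float,
             rng: np.random.Generator, k: int = 30) -> np.ndarray:
    """Bridson blue-noise sampling in [0, length] x [0, width]."""
    cell = r_min / np.sqrt(2)
    nx_, ny_ = int(np.ceil(length / cell)), int(np.ceil(width / cell))
    grid = -np.ones((nx_, ny_), dtype=int)
    pts: list[np.ndarray] = []

    def gidx(p):
        return int(p[0] / cell), int(p[1] / cell)

    def fits(p) -> bool:
        gx, gy = gidx(p)
        for ix in range(max(gx - 2, 0), min(gx + 3, nx_)):
            for iy in range(max(gy - 2, 0), min(gy + 3, ny_)):
                j = grid[ix, iy]
                if j >= 0 and np.hypot(*(pts[j] - p)) < r_min:
                    return False
        return True

    p0 = rng.uniform([0, 0], [length, width])
    pts.append(p0)
    grid[gidx(p0)] = 0
    active = [0]
    while active:
        ai = rng.integers(len(active))
        base = pts[active[ai]]
        placed = False
        radii = rng.uniform(r_min, 2 * r_min, size=k)
        angs = rng.uniform(0, 2 * np.pi, size=k)
        for r, a in zip(radii, angs):
            p = base + r * np.array([np.cos(a), np.sin(a)])
            if not (0 <= p[0] < length and 0 <= p[1] < width):
                continue
            if fits(p):
                pts.append(p)
                grid[gidx(p)] = len(pts) - 1
                active.append(len(pts) - 1)
                placed = True
                break
        if not placed:
            active.pop(ai)
    return np.asarray(pts)


def poisson_disc(params: NullModelParams) -> CellSnapshot:
    """Blue-noise null pattern at the requested density.

    Bridson sampling with exclusion radius ``min_spacing`` (derived from
    the density when not given), thinned at random to the exact target
    count.  Raises before sampling when the requested density is not
    achievable at the requested spacing.
    """
    area = params.length * params.width
    n_target = int(round(params.density * area))
    if n_target < 1:
        raise ValueError("target density yields no points in the rectangle")
    r_min = params.min_spacing
    if r_min is None:
        r_min = np.sqrt(_BRIDSON_DENSITY / (1.12 * params.density))
    if params.density * r_min ** 2 > _BRIDSON_DENSITY:
        raise ValueError(
            f"density {params.density:g} unreachable at min spacing {r_min:g}")
    rng = np.random.default_rng(params.seed)
    pts = _bridson(params.length, params.width, r_min, rng)
    if len(pts) < n_target:
        raise ValueError("Poisson-disc sampling fell short of the target density")
    keep = rng.choice(len(pts), size=n_target, replace=False)
    pts = pts[np.sort(keep)]
    return CellSnapshot(time=0.0, ids=np.arange(len(pts)), positions=pts)


def noisy_lattice(params: NullModelParams) -> CellSnapshot:
    """Square lattice filling the rectangle, with Gaussian positional noise.

    Noise SD = lattice constant / SNR per coordinate; SNR -> inf recovers
    the perfect lattice.  The lattice constant defaults to the spacing
    matching the requested density (a = 1/sqrt(rho)).
    """
    a = params.lattice_constant
    if a is None:
        a = 1.0 / np.sqrt(params.density)
    if a <= 0:
        raise ValueError("lattice constant must be positive")
    xs = np.arange(a / 2, params.length, a)
    ys = np.arange(a / 2, params.width, a)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    sd = a / params.snr if np.isfinite(params.snr) else 0.0
    if sd > 0:
        rng = np.random.default_rng(params.seed)
        pts = pts + rng.normal(scale=sd, size=pts.shape)
    return CellSnapshot(time=0.0, ids=np.arange(len(pts)), positions=pts)


def sample_nematic_von_mises(n: int, kappa: float, loc: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Draw nematic axes from a von Mises distribution in doubled angles.

    kappa = 0 is uniform; kappa = inf is the delta at ``loc``.
    """
    if not np.isfinite(kappa):
        return np.full(n, wrap_nematic(loc), dtype=float)
    if kappa == 0:
        doubled = rng.uniform(0, 2 * np.pi, size=n)
    else:
        doubled = rng.vonmises(2 * loc, kappa, size=n)
    return wrap_nematic(doubled / 2)


@dataclass
class SyntheticGermbandParams:
    """Conditions of the emulated germband choreography.

    Defaults follow the study system: ~10 h doubling time, wave-1 A-P
    speed 7.5 um/h, wave-1 D-V speed 19.2 um/h, tightly A-P-aligned axes,
    and a small planted fraction of late pre-division reorientations.
    """

    n_rows: int = 8                    # parasegment precursor rows
    cells_per_row: int = 8
    row_spacing: float = 10.0          # um between adjacent rows (and columns)
    doubling_time: float = 10.0        # h
    v_ap: float = 7.5                  # anterior-posterior wave speed, um/h
    v_dv: float = 19.2                 # dorso-ventral wave speed, um/h
    stagger: Optional[float] = None    # h between row wave onsets; default row_spacing / v_ap
    kappa: float = 20.0                # doubled-angle von Mises concentration about A-P
    sigma_t: float = 0.1               # division-timing jitter, h
    pos_jitter: float = 0.3            # positional jitter, um
    reorient_fraction: float = 0.074   # planted >45-degree late reorienters
    n_waves: int = 2
    differential_cleavage: bool = False
    frame_dt: float = 0.5              # h between lineage frames
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.cells_per_row < 1:
            raise ValueError("need at least one row and one cell per row")
        for name in ("row_spacing", "doubling_time", "v_ap", "v_dv", "frame_dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma_t < 0 or self.pos_jitter < 0:
            raise ValueError("jitters must be non-negative")
        if not 0 <= self.reorient_fraction <= 1:
            raise ValueError("reorient_fraction must lie in [0, 1]")
        if self.stagger is None:
            self.stagger = self.row_spacing / self.v_ap
        if self.stagger <= 0:
            raise ValueError("stagger must be positive; check row_spacing / v_ap")


@dataclass
class GermbandRealization:
    """Everything one synthetic germband run produces."""

    params: SyntheticGermbandParams
    forest: LineageForest
    events: list[DivisionEvent]
    snapshots: list[CellSnapshot]
    reorientation_series: dict[int, tuple[np.ndarray, np.ndarray, float]]
    reorienter_ids: set[int]

    def cell_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Alive-cell count per frame (times in h)."""
        frames = sorted({f for (_, f) in self.forest.graph.nodes})
        times = []
        counts = []
        for f in frames:
            nodes = [n for n in self.forest.graph.nodes if n[1] == f]
            times.append(self.forest.graph.nodes[nodes[0]]["time"])
            counts.append(len(nodes))
        return np.asarray(times), np.asarray(counts, dtype=int)


def synth_germband(params: SyntheticGermbandParams) -> GermbandRealization:
    """Generate a synthetic germband lineage with choreographed divisions.

    Wave w of row r starts at t = r * stagger + w * doubling_time; within
    a row the wave reaches a cell at distance |y| from the ventral midline
    after |y| / v_dv.  Division axes are von Mises about the A-P axis in
    doubled angles.  Daughters of a generation-g cell are displaced by
    +/- row_spacing / 2^(g+2) along the division axis, so each completed
    wave tiles the tissue into a finer rectangular lattice.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    d = p.row_spacing

    # cell records: id -> dict(pos, birth time, death time (inf if alive), generation)
    cells: dict[int, dict] = {}
    next_id = 0
    y0 = (p.cells_per_row - 1) / 2.0
    row_members: dict[int, list[int]] = {r: [] for r in range(p.n_rows)}
    for r in range(p.n_rows):
        for c in range(p.cells_per_row):
            pos = np.array([r * d, (c - y0) * d])
            cells[next_id] = dict(pos=pos, birth=0.0, death=np.inf, gen=0,
                                  row=r)
            row_members[r].append(next_id)
            next_id += 1

    events: list[DivisionEvent] = []
    reorient_series: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}
    reorienter_ids: set[int] = set()
    wave_names = {0: "wave1", 1: "wave2"}

    current: list[int] = list(cells)
    for w in range(p.n_waves):
        next_gen: list[int] = []
        for cid in current:
            rec = cells[cid]
            r = rec["row"]
            onset = r * p.stagger + w * p.doubling_time
            t_div = onset + abs(rec["pos"][1]) / p.v_dv
            if p.sigma_t > 0:
                t_div += rng.normal(scale=p.sigma_t)
            t_div = max(t_div, rec["birth"] + 1e-6)
            axis = float(sample_nematic_von_mises(1, p.kappa, 0.0, rng)[0])
            off = d / 2 ** (rec["gen"] + 2)
            u = np.array([np.cos(axis), np.sin(axis)])
            jit = (rng.normal(scale=p.pos_jitter, size=2)
                   if p.pos_jitter > 0 else np.zeros(2))
            d1, d2 = next_id, next_id + 1
            next_id += 2
            for did, sgn in ((d1, +1.0), (d2, -1.0)):
                cells[did] = dict(pos=rec["pos"] + sgn * off * u, birth=t_div,
                                  death=np.inf, gen=rec["gen"] + 1, row=r)
                next_gen.append(did)
            rec["death"] = t_div
            label = wave_names.get(w, f"wave{w + 1}")
            if w == 1:
                # daughters of the anterior ('a/b') sub-row vs posterior ('c/d')
                label = "wave2AB" if rec["pos"][0] <= r * d else "wave2CD"
            ev = DivisionEvent(
                time=t_div, x=float(rec["pos"][0] + jit[0]),
                y=float(rec["pos"][1] + jit[1]), theta=axis,
                parent_id=cid, daughter_ids=(d1, d2), wave=label,
                parasegment=r)
            events.append(ev)
            _plant_reorientation(ev, len(events) - 1, p, rng,
                                 reorient_series, reorienter_ids)
        current = next_gen

    if p.differential_cleavage:
        for cid in list(current):
            rec = cells[cid]
            if abs(rec["pos"][1]) > 1.5 * d:
                continue
            r = rec["row"]
            t_div = (r * p.stagger + p.n_waves * p.doubling_time
                     + rng.uniform(0, 0.3 * p.doubling_time))
            axis = float(sample_nematic_von_mises(1, 0.3, 0.0, rng)[0])
            off = d / 2 ** (rec["gen"] + 2)
            u = np.array([np.cos(axis), np.sin(axis)])
            d1, d2 = next_id, next_id + 1
            next_id += 2
            for did, sgn in ((d1, +1.0), (d2, -1.0)):
                cells[did] = dict(pos=rec["pos"] + sgn * off * u, birth=t_div,
                                  death=np.inf, gen=rec["gen"] + 1, row=r)
            rec["death"] = t_div
            events.append(DivisionEvent(
                time=t_div, x=float(rec["pos"][0]), y=float(rec["pos"][1]),
                theta=axis, parent_id=cid, daughter_ids=(d1, d2),
                wave="differential_cleavage", parasegment=r))

    events.sort(key=lambda e: e.time)
    t_end = max(e.time for e in events) + p.frame_dt
    forest, snapshots = _assemble_forest(cells, events, p, t_end)
    return GermbandRealization(params=p, forest=forest, events=events,
                               snapshots=snapshots,
                               reorientation_series=reorient_series,
                               reorienter_ids=reorienter_ids)


def _plant_reorientation(ev: DivisionEvent, idx: int,
                         p: SyntheticGermbandParams, rng: np.random.Generator,
                         series: dict, reorienters: set[int]) -> None:
    """Presumptive-axis angle track over the 10 min before one division."""
    window = 10.0 / 60.0
    ts = ev.time - window + np.arange(11) * (window / 10)
    is_re = rng.random() < p.reorient_fraction
    noise = rng.normal(scale=np.deg2rad(3.0), size=ts.size)
    if is_re:
        start = ev.theta + np.deg2rad(rng.uniform(60.0, 85.0)) * rng.choice([-1, 1])
        # hold the wrong axis, then swing during the final two minutes
        ang = np.full(ts.size, start)
        swing = ts >= ev.time - 2.0 / 60.0
        frac = (ts[swing] - (ev.time - 2.0 / 60.0)) / (2.0 / 60.0)
        ang[swing] = start + frac * (ev.theta - start)
        reorienters.add(idx)
    else:
        ang = np.full(ts.size, ev.theta)
    series[idx] = (ts, wrap_nematic(ang + noise), ev.theta)


def _assemble_forest(cells: dict, events: list[DivisionEvent],
                     p: SyntheticGermbandParams,
                     t_end: float) -> tuple[LineageForest, list[CellSnapshot]]:
    frames = np.arange(0.0, t_end + p.frame_dt, p.frame_dt)
    forest = LineageForest()
    snapshots: list[CellSnapshot] = []
    div_by_parent = {e.parent_id: e for e in events}
    alive_prev: dict[int, int] = {}
    for fi, t in enumerate(frames):
        ids, pos = [], []
        for cid, rec in cells.items():
            if rec["birth"] <= t < rec["death"] or (
                    rec["death"] is np.inf and rec["birth"] <= t):
                ids.append(cid)
                pos.append(rec["pos"])
                forest.add_node(cid, fi, rec["pos"], t)
        for cid in ids:
            if cid in alive_prev:
                forest.add_edge(cid, fi - 1, cid, fi)
        if fi > 0:
            for pid in alive_prev:
                if pid not in set(ids) and pid in div_by_parent:
                    e = div_by_parent[pid]
                    for did in e.daughter_ids:
                        if did in set(ids):
                            forest.add_edge(pid, fi - 1, did, fi)
        alive_prev = {cid: fi for cid in ids}
        snapshots.append(CellSnapshot(time=float(t), ids=np.asarray(ids),
                                      positions=np.asarray(pos, dtype=float)))
    forest.validate()
    return forest, snapshots


def ks_two_sample(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum difference of the empirical CDFs; the p value is the
    asymptotic Kolmogorov tail evaluated with the finite-sample effective
    size correction lambda = (sqrt(ne) + 0.12 + 0.11 / sqrt(ne)) D, with
    ne = n m / (n + m).
    """
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    allv = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, allv, side="right") / a.size
    cdf_b = np.searchsorted(b, allv, side="right") / b.size
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    ne = a.size * b.size / (a.size + b.size)
    lam = (np.sqrt(ne) + 0.12 + 0.11 / np.sqrt(ne)) * d
    p = float(np.clip(special.kolmogorov(lam), 0.0, 1.0))
    return d, p
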