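"""Circular statistics and kinetic fits for cell-division choreography.

Division axes are nematic: an axis at theta is the same axis at theta +/- pi.
All circular statistics therefore work in doubled-angle space.  The
modified circular mean is

    theta_bar = (1/2) arg( sum_n exp(2 i theta_n) )  in  [-pi/2, pi/2),

and the angular dispersion s = sqrt(2 (1 - R2)) with R2 the doubled-angle
resultant length: s = 0 for perfectly aligned axes and sqrt(2) for an
isotropic set.  Mitotic-wave speeds come from ordinary least-squares fits
of division position against division time, and the proliferation rate
from a least-squares fit of log2 cell counts against time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "DivisionEvent",
    "DivisionStats",
    "KineticsFit",
    "LineageForest",
    "nematic_mean",
    "nematic_dispersion",
    "fit_von_mises",
    "fit_wave_speed",
    "doubling_time",
    "detect_reorientation",
    "nematic_difference",
]

KAPPA_MAX = 1e4  # saturation cap for degenerate (delta-like) von Mises fits


@dataclass
class DivisionEvent:
    """One cell division: when, where, and along which nematic axis."""

    time: float                      # h
    x: float                         # A-P coordinate, um
    y: float                         # signed D-V coordinate, um (midline y=0)
    theta: float                     # nematic axis in [-pi/2, pi/2), rad from A-P
    parent_id: int
    daughter_ids: tuple[int, int]
    wave: str = "unlabeled"          # wave1 | wave2AB | wave2CD | differential_cleavage
    parasegment: int = -1

    def __post_init__(self) -> None:
        self.theta = wrap_nematic(self.theta)
        if self.daughter_ids[0] == self.daughter_ids[1]:
            raise ValueError("daughters must be distinct")


@dataclass
class DivisionStats:
    mean: float                      # modified circular mean, rad
    dispersion: float                # s in [0, sqrt(2)]
    n: int
    vm_location: Optional[float] = None
    vm_kappa: Optional[float] = None
    kappa_saturated: bool = False


@dataclass
class KineticsFit:
    value: float                     # slope (um/h) or doubling time (h)
    stderr: float
    n: int
    intercept: float = np.nan
    residual_rms: float = np.nan


class LineageForest:
    """Temporal digraph of cell tracks.

    Nodes are (cell_id, frame); edges connect a cell at frame f to its
    continuation or to its two daughters at frame f+1.  Node attributes
    ``pos`` (x, y) and ``time`` (h).
    """

    def __init__(self) -> None:
        self.graph = nx.DiGraph()

    def add_node(self, cell_id: int, frame: int, pos, time: float) -> None:
        self.graph.add_node((cell_id, frame), pos=tuple(map(float, pos)), time=float(time))

    def add_edge(self, cell_id: int, frame: int, next_id: int, next_frame: int) -> None:
        if next_frame != frame + 1:
            raise ValueError("lineage edges must advance exactly one frame")
        self.graph.add_edge((cell_id, frame), (next_id, next_frame))

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("lineage graph has a cycle")
        for node in self.graph.nodes:
            od = self.graph.out_degree(node)
            if od not in (0, 1, 2):
                raise ValueError(f"node {node} has out-degree {od}")

    def division_nodes(self) -> list[tuple[int, int]]:
        return [n for n in self.graph.nodes if self.graph.out_degree(n) == 2]

    def cell_count(self, frame: int) -> int:
        return sum(1 for (_, f) in self.graph.nodes if f == frame)


def wrap_nematic(theta: float | np.ndarray) -> float | np.ndarray:
    """Map an angle to the nematic fundamental interval [-pi/2, pi/2)."""
    return (np.asarray(theta) + np.pi / 2) % np.pi - np.pi / 2


def nematic_difference(a, b):
    """Smallest unsigned angle between two nematic axes, in [0, pi/2]."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % np.pi
    return np.minimum(d, np.pi - d)


def _resultant(angles: np.ndarray) -> complex:
    return np.exp(2j * np.asarray(angles, dtype=float)).mean()


def nematic_mean(angles: Sequence[float]) -> float:
    """Modified circular mean of nematic angles, in [-pi/2, pi/2).

    Undefined (NaN) when the doubled-angle resultant vanishes, e.g. for an
    exactly orthogonal pair.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("need at least one angle")
    z = _resultant(angles)
    if abs(z) < 1e-12:
        return float("nan")
    return float(wrap_nematic(0.5 * np.angle(z)))


def nematic_dispersion(angles: Sequence[float], squared: bool = False) -> float:
    """Modified angular dispersion s = sqrt(2 (1 - R2)) in [0, sqrt(2)].

    ``squared=True`` returns the unrooted variant 2 (1 - R2) in [0, 2].
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("need at least one angle")
    r2 = abs(_resultant(angles))
    s2 = 2.0 * (1.0 - min(r2, 1.0))
    return float(s2) if squared else float(np.sqrt(s2))


def fit_von_mises(angles: Sequence[float]) -> tuple[float, float, bool]:
    """Maximum-likelihood von Mises fit in doubled-angle space.

    Returns (location, kappa, saturated).  The location is a nematic angle
    in [-pi/2, pi/2); kappa refers to the doubled-angle distribution.
    Degenerate (all-identical) samples saturate at ``KAPPA_MAX``.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size < 5:
        raise ValueError("need at least 5 angles for a von Mises fit")
    doubled = (2.0 * angles) % (2 * np.pi)
    z = np.exp(1j * doubled).mean()
    rbar = abs(z)
    loc2 = np.angle(z)
    if rbar > 1 - 1e-12:
        return float(wrap_nematic(loc2 / 2)), KAPPA_MAX, True
    kappa, _, _ = stats.vonmises.fit(doubled, fscale=1, floc=loc2)
    kappa = float(kappa)
    sat = kappa >= KAPPA_MAX
    return float(wrap_nematic(loc2 / 2)), min(kappa, KAPPA_MAX), sat


def fit_wave_speed(
    events: Iterable[DivisionEvent],
    axis: Literal["AP", "DV"],
    wave: Optional[str] = None,
) -> KineticsFit:
    """Mitotic-wave speed from an OLS fit of division position vs time.

    For the A-P axis the fit is x against absolute division time.  For the
    D-V axis (waves start at the ventral midline and spread outward) the
    fit is |y| against time normalized to the first event of the wave in
    each parasegment, pooling the two sides of the midline.
    """
    evs = [e for e in events if wave is None or e.wave == wave]
    if len(evs) < 3:
        raise ValueError("need at least 3 events for a wave-speed fit")
    t = np.array([e.time for e in evs])
    if axis == "AP":
        pos = np.array([e.x for e in evs])
    else:
        pos = np.array([abs(e.y) for e in evs])
        ps = np.array([e.parasegment for e in evs])
        t = t.copy()
        for p in np.unique(ps):
            sel = ps == p
            t[sel] -= t[sel].min()
    if np.ptp(t) == 0:
        raise ValueError("zero time variance among events")
    res = stats.linregress(t, pos)
    pred = res.intercept + res.slope * t
    return KineticsFit(value=float(res.slope), stderr=float(res.stderr),
                       n=len(evs), intercept=float(res.intercept),
                       residual_rms=float(np.sqrt(np.mean((pos - pred) ** 2))))


def doubling_time(times: Sequence[float], counts: Sequence[float]) -> KineticsFit:
    """Cell doubling time from a least-squares fit of log2 N(t) vs t.

    The fitted model is log2 N(t) = log2 N0 + t / tau; a zero slope
    (constant counts) yields an infinite tau, returned as ``inf``.
    """
    times = np.asarray(times, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if len(times) < 3:
        raise ValueError("need at least 3 time points")
    if np.any(counts <= 0):
        raise ValueError("all counts must be positive")
    res = stats.linregress(times, np.log2(counts))
    if res.slope <= 0:
        return KineticsFit(value=float("inf"), stderr=float("nan"), n=len(times),
                           intercept=float(res.intercept))
    tau = 1.0 / res.slope
    se = float(res.stderr) / res.slope ** 2 if np.isfinite(res.stderr) else float("nan")
    pred = res.intercept + res.slope * times
    return KineticsFit(value=float(tau), stderr=se, n=len(times),
                       intercept=float(res.intercept),
                       residual_rms=float(np.sqrt(np.mean((np.log2(counts) - pred) ** 2))))


def detect_reorientation(
    series: dict[int, tuple[np.ndarray, np.ndarray, float]],
    window: float = 5.0 / 60.0,
    threshold: float = np.deg2rad(45.0),
) -> tuple[dict[int, bool], float, int]:
    """Flag divisions whose presumptive axis swung by more than ``threshold``
    within ``window`` hours before division.

    ``series`` maps division id -> (sample times (h), presumptive-axis
    angles (rad), final division axis (rad)).  An event whose samples do
    not cover the window start is excluded from the denominator.  Returns
    (flags, flagged fraction, denominator).
    """
    flags: dict[int, bool] = {}
    excluded = 0
    for div_id, (t, ang, final_axis) in series.items():
        t = np.asarray(t, dtype=float)
        ang = np.asarray(ang, dtype=float)
        t_div = t.max()
        t_start = t_div - window
        if t.min() > t_start + 1e-9:
            excluded += 1
            continue
        # axis at the start of the window (last sample at or before it)
        i0 = np.searchsorted(t, t_start, side="right") - 1
        swing = nematic_difference(ang[i0], final_axis)
        flags[div_id] = bool(swing > threshold)
    denom = len(flags)
    if denom == 0:
        return flags, float("nan"), 0
    frac = sum(flags.values()) / denom
    return flags, float(frac), denom


def division_stats(angles: Sequence[float], fit: bool = True) -> DivisionStats:
    """Summary circular statistics (and optional von Mises fit) of axes."""
    angles = np.asarray(angles, dtype=float)
    mean = nematic_mean(angles)
    s = nematic_dispersion(angles)
    loc = kappa = None
    sat = False
    if fit and angles.size >= 5:
        loc, kappa, sat = fit_von_mises(angles)
    return DivisionStats(mean=mean, dispersion=s, n=angles.size,
                         vm_location=loc, vm_kappa=kappa, kappa_saturated=sat)
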