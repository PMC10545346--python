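"""Closed-form plane-elastic fields of a circular inclusion with eigenstrain.

A dividing cell is modelled as a circular Eshelby inclusion of radius *a*
carrying the uniform eigenstrain

    eps* = (M/2) I + q (2 n n^T - I),

with isotropic amplitude M (area growth), deviatoric amplitude q
(constant-area shear) and nematic axis n.  For the plane problem with
Kolosov constant kappa = 3 - 4 nu, the exterior displacement for n = x-hat
is, in complex form (u = u_x + i u_y, z = x + i y),

    u(z) = a^2 / (4 (1 - nu)) * [ M / conj(z)
            + q ( kappa / z + z / conj(z)^2 - a^2 / conj(z)^3 ) ],

derived by matching Muskhelishvili potentials across the interface; the
interior total strain is uniform with components (M + q kappa)/(kappa+1)
along the axis and (M - q kappa)/(kappa+1) across it, consistent with the
two-dimensional Eshelby tensor of a circular inclusion.  A general axis is
handled by frame rotation.  The field is linear in M and q separately and
decays to zero far from the inclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["InclusionSpec", "inclusion_displacement", "interior_strain",
           "deformed_ellipse", "foci_displacements"]


@dataclass
class InclusionSpec:
    """A circular eigenstrain inclusion (one cell division)."""

    center: tuple[float, float]
    radius: float
    M: float = 0.0
    q: float = 0.0
    axis: float = 0.0  # nematic axis angle from A-P (+x), rad

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("inclusion radius must be positive")

    @property
    def n_hat(self) -> np.ndarray:
        return np.array([np.cos(self.axis), np.sin(self.axis)])


def _kappa(nu: float) -> float:
    if not -1.0 < nu < 0.5:
        raise ValueError("nu must lie in (-1, 1/2)")
    return 3.0 - 4.0 * nu


def inclusion_displacement(points: np.ndarray, spec: InclusionSpec,
                           nu: float = 1.0 / 3.0,
                           strict_exterior: bool = True) -> np.ndarray:
    """Exterior displacement field of a circular eigenstrain inclusion.

    ``points`` is (N, 2); all points must lie on or outside the inclusion
    boundary (interior points raise unless ``strict_exterior=False``,
    which is used by the solver when excising holes).
    """
    kappa = _kappa(nu)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    z = (pts[:, 0] - spec.center[0]) + 1j * (pts[:, 1] - spec.center[1])
    r = np.abs(z)
    if strict_exterior and np.any(r < spec.radius * (1 - 1e-9)):
        bad = int(np.argmin(r))
        raise ValueError(f"evaluation point {bad} lies inside the inclusion")
    # rotate into the inclusion frame (axis -> +x)
    rot = np.exp(-1j * spec.axis)
    zf = z * rot
    a2 = spec.radius ** 2
    zc = np.conj(zf)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (a2 / (4 * (1 - nu))) * (
            spec.M / zc
            + spec.q * (kappa / zf + zf / zc ** 2 - a2 / zc ** 3))
    u = np.where(r == 0, 0.0, u)
    u = u * np.conj(rot)  # rotate back to the lab frame
    return np.column_stack([u.real, u.imag])


def interior_strain(spec: InclusionSpec, nu: float = 1.0 / 3.0) -> np.ndarray:
    """Uniform total strain inside the inclusion (lab frame, 2x2)."""
    kappa = _kappa(nu)
    e_par = (spec.M + spec.q * kappa) / (kappa + 1)
    e_perp = (spec.M - spec.q * kappa) / (kappa + 1)
    c, s = np.cos(spec.axis), np.sin(spec.axis)
    R = np.array([[c, -s], [s, c]])
    return R @ np.diag([e_par, e_perp]) @ R.T


def deformed_ellipse(spec: InclusionSpec, nu: float = 1.0 / 3.0
                     ) -> tuple[float, float]:
    """Semi-axes (along axis, across axis) of the deformed inclusion."""
    kappa = _kappa(nu)
    e_par = (spec.M + spec.q * kappa) / (kappa + 1)
    e_perp = (spec.M - spec.q * kappa) / (kappa + 1)
    return spec.radius * (1 + e_par), spec.radius * (1 + e_perp)


def foci_displacements(spec: InclusionSpec, nu: float = 1.0 / 3.0) -> np.ndarray:
    """Displacements of the two foci of the deformed-inclusion ellipse
    from the undeformed center: the model's daughter-cell velocities."""
    A, B = deformed_ellipse(spec, nu)
    if A >= B:
        c = np.sqrt(max(A * A - B * B, 0.0))
        direction = spec.n_hat
    else:
        c = np.sqrt(B * B - A * A)
        direction = np.array([-spec.n_hat[1], spec.n_hat[0]])
    return np.array([c * direction, -c * direction])
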