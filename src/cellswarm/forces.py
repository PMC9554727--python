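"""Ground-truth interaction forces and species definitions.

The synthetic benchmark populations are driven by three anisotropic
pairwise forces acting on cell accelerations:

* a quadrupolar attraction-repulsion kernel
  ``f_ar(r, theta) = (A0 + A2 cos 2theta)(exp(-c_f r) - rho exp(-c_s r))``
  applied along ``x_i - x_j`` (repulsive at short range, attractive at
  long range),
* a dipolar alignment kernel
  ``f_align(r, theta) = -(B0 + B1 cos theta) exp(-c_a r)`` applied to the
  velocity difference ``v_i - v_j``, and
* a linear isotropic drag ``f_drag(s, theta) = -D s`` applied to the
  cell's own velocity (s = speed).

``theta`` is the angle between cell i's velocity and the displacement
``x_j - x_i``.  A species is a subset of these three forces: species A
carries all three, species B attraction-repulsion + drag, and species C
alignment + drag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: below this speed no direction is defined; only isotropic modes act
EPS_V = 1e-12

# default force parameters (dimensionless model units)
AR_AMP0 = 15.0
AR_AMP2 = 10.0
AR_DECAY_FAST = 20.0
AR_DECAY_SLOW = 10.0
AR_RATIO = 0.25
ALIGN_AMP0 = 8.0
ALIGN_AMP1 = 8.0
ALIGN_DECAY = 8.0
DRAG_COEF = 5.0


@dataclass(frozen=True)
class SpeciesSpec:
    """Which forces a species carries, and their parameters."""

    name: str
    has_ar: bool = False
    has_align: bool = False
    has_drag: bool = False
    ar_params: tuple[float, float, float, float, float] = (
        AR_AMP0, AR_AMP2, AR_DECAY_FAST, AR_DECAY_SLOW, AR_RATIO)
    align_params: tuple[float, float, float] = (ALIGN_AMP0, ALIGN_AMP1, ALIGN_DECAY)
    drag_params: tuple[float] = (DRAG_COEF,)

    def __post_init__(self) -> None:
        if not (self.has_ar or self.has_align or self.has_drag):
            raise ValueError(f"species {self.name!r} carries no force")

    def force(self, kind: str, r_or_s, theta=0.0):
        """Evaluate one of this species' force kernels (vectorized)."""
        return ground_truth_force(kind, r_or_s, theta,
                                  ar_params=self.ar_params,
                                  align_params=self.align_params,
                                  drag_params=self.drag_params)


def species_registry() -> dict[str, SpeciesSpec]:
    """The three benchmark species keyed by label."""
    return {
        "A": SpeciesSpec("A", has_ar=True, has_align=True, has_drag=True),
        "B": SpeciesSpec("B", has_ar=True, has_align=False, has_drag=True),
        "C": SpeciesSpec("C", has_ar=False, has_align=True, has_drag=True),
    }


def ground_truth_force(kind: str, r_or_s, theta=0.0, *,
                       ar_params=(AR_AMP0, AR_AMP2, AR_DECAY_FAST, AR_DECAY_SLOW, AR_RATIO),
                       align_params=(ALIGN_AMP0, ALIGN_AMP1, ALIGN_DECAY),
                       drag_params=(DRAG_COEF,)):
    """Scalar force magnitude of one ground-truth kernel.

    Parameters
    ----------
    kind : {"a-r", "align", "drag"}
    r_or_s : distance (a-r, align) or speed (drag), nonnegative
    theta : angle in [0, pi]; ignored by the isotropic drag force
    """
    r = np.asarray(r_or_s, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance/speed argument must be nonnegative")
    th = np.asarray(theta, dtype=float)
    if kind == "a-r":
        a0, a2, cf, cs, rho = ar_params
        return (a0 + a2 * np.cos(2 * th)) * (np.exp(-cf * r) - rho * np.exp(-cs * r))
    if kind == "align":
        b0, b1, ca = align_params
        return -(b0 + b1 * np.cos(th)) * np.exp(-ca * r)
    if kind == "drag":
        (d,) = drag_params
        return -d * r + 0.0 * th
    raise ValueError(f"unknown force kind {kind!r}")


def pairwise_angle(v, disp, eps_v: float = EPS_V):
    """Angle between velocity ``v`` and displacement ``disp = x_j - x_i``.

    Returns ``(theta, (1, cos(theta), cos(2 theta)))``.  When the speed is
    below ``eps_v`` the directional factors for n >= 1 are zero by
    convention (isotropic fallback) and theta is reported as pi/2.

    Raises on a zero displacement: the self-pair must be excluded upstream.
    """
    v = np.asarray(v, dtype=float)
    disp = np.asarray(disp, dtype=float)
    rn = float(np.hypot(disp[0], disp[1]))
    if rn == 0.0:
        raise ValueError("zero displacement: coincident pair")
    sn = float(np.hypot(v[0], v[1]))
    if sn < eps_v:
        return np.pi / 2, (1.0, 0.0, 0.0)
    c = float(np.clip(np.dot(v, disp) / (sn * rn), -1.0, 1.0))
    return float(np.arccos(c)), (1.0, c, 2.0 * c * c - 1.0)
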