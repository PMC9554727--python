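"""Weak-form machinery: test functions, velocities, system assembly.

The second-order dynamics are never differentiated from data.  Instead
each scalar equation is integrated against compactly supported C^2 bumps

    phi_q(t) = max(1 - ((t - t_q) / (m dt))^2, 0)^p,

and two integrations by parts move the second time derivative onto
phi_q, whose derivatives are known analytically.  All time integrals use
the trapezoidal rule on the frame grid; since every phi_q (and its
derivatives, for p >= 3) vanishes at its support endpoints, the
composite trapezoid is a plain weighted dot product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist


def finite_diff_velocity(positions: np.ndarray, dt: float) -> np.ndarray:
    """Second-order finite-difference velocities along the frame axis.

    Interior frames use the centred stencil (x_{k+1} - x_{k-1}) / (2 dt);
    the two endpoints use one-sided second-order stencils.  Input may be
    (L,), (L, 2) or (N, L, 2); frames are the axis of length L.
    """
    positions = np.asarray(positions, dtype=float)
    axis = 1 if positions.ndim == 3 else 0
    if positions.shape[axis] < 3:
        raise ValueError("need at least 3 frames for second-order velocities")
    return np.gradient(positions, dt, axis=axis, edge_order=2)


@dataclass
class TestFunctionBasis:
    """Tabulated test functions phi_q and their second derivatives.

    phi : (Q, L) values on the frame grid; ddphi : (Q, L) analytic second
    derivatives; centers : (Q,) center times t_q = (m dt, ..., (L-m-1) dt);
    Q = L - 2m.
    """

    m: int
    p: int
    dt: float
    centers: np.ndarray
    phi: np.ndarray
    ddphi: np.ndarray

    @property
    def n_test(self) -> int:
        return self.phi.shape[0]


def build_test_functions(L: int, dt: float, m: int, p: int) -> TestFunctionBasis:
    """Tabulate the Q = L - 2m test functions on the L-point frame grid."""
    if p < 3:
        raise ValueError("p >= 3 required for C^2 test functions")
    if L <= 2 * m:
        raise ValueError(f"L = {L} must exceed 2m = {2 * m}")
    t = dt * np.arange(L)
    centers = dt * np.arange(m, L - m)
    u = (t[None, :] - centers[:, None]) / (m * dt)      # (Q, L)
    g = 1.0 - u * u
    inside = g > 0
    gp = np.where(inside, g, 0.0)
    phi = gp ** p
    # phi'' = p(p-1) g^{p-2} (2u/(m dt))^2 - 2p g^{p-1} / (m dt)^2
    scale = 1.0 / (m * dt) ** 2
    ddphi = np.where(
        inside,
        p * (p - 1) * gp ** (p - 2) * (2.0 * u) ** 2 * scale
        - 2.0 * p * gp ** (p - 1) * scale,
        0.0)
    return TestFunctionBasis(m=m, p=p, dt=dt, centers=centers,
                             phi=phi, ddphi=ddphi)


@dataclass
class WeakSystem:
    """Weak-form linear system b ~ G w for one focal cell.

    Rows are stacked coordinate-major: all test functions for the x
    coordinate, then all for y (2Q rows, J columns).
    """

    G: np.ndarray
    b: np.ndarray
    focal: int
    col_norms: np.ndarray
    b_norm: float


def assemble_weak_system(x_focal: np.ndarray, theta: np.ndarray,
                         basis: TestFunctionBasis, dt: float,
                         focal: int = -1) -> WeakSystem:
    """Assemble G (2Q x J) and b (2Q) by trapezoidal inner products.

    x_focal : (L, 2) focal positions; theta : (L, 2, J) feature tensor.
    """
    x_focal = np.asarray(x_focal, dtype=float)
    L = x_focal.shape[0]
    if theta.shape[0] != L or basis.phi.shape[1] != L:
        raise ValueError("frame counts of data, features and basis disagree")
    J = theta.shape[2]
    Q = basis.n_test
    # trapezoid on the full grid: weight dt, except dt/2 at the two ends
    wts = np.full(L, dt)
    wts[0] = wts[-1] = 0.5 * dt
    phiw = basis.phi * wts[None, :]
    ddphiw = basis.ddphi * wts[None, :]
    G = np.empty((2 * Q, J))
    b = np.empty(2 * Q)
    for d in range(2):
        G[d * Q:(d + 1) * Q] = phiw @ theta[:, d, :]
        b[d * Q:(d + 1) * Q] = ddphiw @ x_focal[:, d]
    if not (np.all(np.isfinite(G)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite entries in weak system")
    return WeakSystem(G=G, b=b, focal=focal,
                      col_norms=np.linalg.norm(G, axis=0),
                      b_norm=float(np.linalg.norm(b)))


def compute_near_field_radius(positions: np.ndarray, p_nf: float) -> float:
    """Empirical p_nf-quantile of all pairwise distances over all frames.

    The near-field radius r_nf is the distance below which pairwise
    separations are observed with probability p_nf; the learned
    attraction-repulsion force is constrained repulsive below it.
    """
    if not 0.0 < p_nf < 1.0:
        raise ValueError("p_nf must lie in (0, 1)")
    positions = np.asarray(positions, dtype=float)
    N, L = positions.shape[:2]
    if N < 2:
        raise ValueError("need at least two cells")
    d = np.concatenate([pdist(positions[:, k, :]) for k in range(L)])
    return float(np.quantile(d, p_nf, method="inverted_cdf"))


def max_pairwise_distance(positions: np.ndarray) -> float:
    """Maximum interparticle distance over all frames (r_max)."""
    positions = np.asarray(positions, dtype=float)
    L = positions.shape[1]
    return float(max(np.max(pdist(positions[:, k, :])) for k in range(L)))


def max_speed(velocities: np.ndarray) -> float:
    """Maximum observed cell speed (s_max)."""
    v = np.asarray(velocities, dtype=float)
    return float(np.sqrt(np.max(np.sum(v * v, axis=-1))))
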