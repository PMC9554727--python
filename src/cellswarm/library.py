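"""Force library: the ordered basis the sparse regression selects from.

Three blocks, J = 88 columns in total:

* attraction-repulsion (54): ``cos(n th) p_l(alpha r) exp(-alpha r / 2)``
  for angular index n = 0..2 and Laguerre degree l = 0..17, paired with
  the displacement ``x_i - x_j``.  The weighted Laguerre polynomials are
  orthonormal under ``int_0^inf p_m p_n e^{-r} dr = delta_mn``; the scale
  alpha = 36 maps the maximum observed distance r_max ~ 2 to the point
  where the weight reaches machine precision.
* alignment (24): ``(1 + cos(n th)) exp(-2 l r)`` for n = 0..2 and
  l = -2..5, paired with the velocity difference ``v_i - v_j``.  The
  nonnegative prefactor makes the sign constraint f_align <= 0 equivalent
  to elementwise nonpositive coefficients.
* drag (10): ``(1 + cos(n th)) |v|^l`` for n = 0..1 and l = 0..4, paired
  with the cell's own velocity; likewise sign-constrained elementwise.

Each ``(1 + cos(n th))`` term with n >= 1 activates angular modes {0, n}
of its block for force-mode coding; plain ``cos(n th)`` terms activate
mode n only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forces import EPS_V

#: force-mode order used for 8-bit model codes
MODE_NAMES = ("a-r:0", "a-r:1", "a-r:2",
              "align:0", "align:1", "align:2",
              "drag:0", "drag:1")


def laguerre_polynomials(x, lmax: int) -> np.ndarray:
    """Laguerre polynomials p_0..p_lmax at x, shape (lmax + 1, *x.shape)."""
    x = np.asarray(x, dtype=float)
    out = np.empty((lmax + 1,) + x.shape)
    out[0] = 1.0
    if lmax >= 1:
        out[1] = 1.0 - x
    for k in range(1, lmax):
        out[k + 1] = ((2 * k + 1 - x) * out[k] - k * out[k - 1]) / (k + 1)
    return out


@dataclass(frozen=True)
class LibraryTerm:
    block: str   # "a-r" | "align" | "drag"
    n: int       # angular index
    ell: int     # radial degree / exponential rate index / speed exponent

    @property
    def modes(self) -> tuple[int, ...]:
        """Force modes (bit positions) this term activates."""
        if self.block == "a-r":
            return (self.n,)
        base = 3 if self.block == "align" else 6
        return (base,) if self.n == 0 else (base, base + self.n)


class ForceLibrary:
    """Default 88-term directional force library."""

    def __init__(self, alpha: float = 36.0, n_laguerre: int = 18,
                 align_rates: tuple[int, ...] = tuple(range(-2, 6)),
                 drag_powers: tuple[int, ...] = tuple(range(5)),
                 eps_v: float = EPS_V):
        self.alpha = float(alpha)
        self.n_laguerre = int(n_laguerre)
        self.align_rates = tuple(align_rates)
        self.drag_powers = tuple(drag_powers)
        self.eps_v = float(eps_v)
        terms: list[LibraryTerm] = []
        for n in range(3):
            for ell in range(self.n_laguerre):
                terms.append(LibraryTerm("a-r", n, ell))
        for n in range(3):
            for ell in self.align_rates:
                terms.append(LibraryTerm("align", n, ell))
        for n in range(2):
            for ell in self.drag_powers:
                terms.append(LibraryTerm("drag", n, ell))
        self.terms = tuple(terms)
        n_ar = 3 * self.n_laguerre
        n_al = 3 * len(self.align_rates)
        n_dr = 2 * len(self.drag_powers)
        self.ar_slice = slice(0, n_ar)
        self.align_slice = slice(n_ar, n_ar + n_al)
        self.drag_slice = slice(n_ar + n_al, n_ar + n_al + n_dr)

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def size(self) -> int:
        return len(self.terms)

    def index_of(self, block: str, n: int, ell: int) -> int:
        return self.terms.index(LibraryTerm(block, n, ell))

    # ------------------------------------------------------------------
    # feature evaluation on trajectory data
    # ------------------------------------------------------------------
    def _angular(self, vi: np.ndarray, X: np.ndarray, xi: np.ndarray):
        """cos factors for focal velocities vi (L,2) against all cells X
        (N,L,2); returns (c1, c2) of shape (N, L) with the degenerate-speed
        convention applied, plus distances r (N, L) and D = x_i - x_j."""
        D = xi[None, :, :] - X                       # (N, L, 2)
        r = np.sqrt(np.sum(D * D, axis=2))           # (N, L)
        s = np.sqrt(np.sum(vi * vi, axis=1))         # (L,)
        rs = np.where(r == 0, 1.0, r)
        ss = np.where(s < self.eps_v, 1.0, s)
        # v_i . (x_j - x_i) = -v_i . D
        dot = -(D[:, :, 0] * vi[None, :, 0] + D[:, :, 1] * vi[None, :, 1])
        c1 = np.clip(dot / (rs * ss[None, :]), -1.0, 1.0)
        c1[:, s < self.eps_v] = 0.0
        c2 = 2.0 * c1 * c1 - 1.0
        c2[:, s < self.eps_v] = 0.0
        return c1, c2, r, D

    def evaluate_features(self, positions: np.ndarray, velocities: np.ndarray,
                          focal: int) -> np.ndarray:
        """Feature tensor Theta of shape (L, 2, J) for one focal cell.

        Column j at frame k, coordinate d is the population-normalized sum
        over neighbours of basis term j paired with its multiplier
        (displacement, velocity difference, or own velocity).
        """
        N, L, _ = positions.shape
        if not 0 <= focal < N:
            raise IndexError(f"focal cell {focal} out of range for N={N}")
        xi = positions[focal]
        vi = velocities[focal]
        c1, c2, r, D = self._angular(vi, positions, xi)
        mask = np.ones((N, L))
        mask[focal] = 0.0
        if np.any((r == 0) & (mask > 0)):
            raise ValueError("coincident distinct cells in trajectory data")
        A = np.stack([np.ones_like(c1), c1, c2])       # (3, N, L)
        # attraction-repulsion block
        P = laguerre_polynomials(self.alpha * r, self.n_laguerre - 1)
        e_ar = np.exp(-0.5 * self.alpha * r)
        W = A * (e_ar * mask)[None]
        C_ar = np.einsum("anl,pnl,nld->apld", W, P, D) / N
        # alignment block
        E = np.exp(np.multiply.outer(-2.0 * np.array(self.align_rates), r))
        DV = vi[None, :, :] - velocities
        F = (1.0 + A) * mask[None]
        C_al = np.einsum("anl,pnl,nld->apld", F, E, DV) / N
        # drag block
        s = np.sqrt(np.sum(vi * vi, axis=1))
        S = np.power.outer(s, np.array(self.drag_powers)).T  # (5, L)
        G = np.sum(F[:2], axis=1)                            # (2, L)
        C_dr = np.einsum("al,pl,ld->apld", G, S, vi) / N
        theta = np.concatenate([
            C_ar.reshape(-1, L, 2),
            C_al.reshape(-1, L, 2),
            C_dr.reshape(-1, L, 2),
        ]).transpose(1, 2, 0)
        return np.ascontiguousarray(theta)

    # ------------------------------------------------------------------
    # force kernels as functions of (r, theta) / (s, theta)
    # ------------------------------------------------------------------
    def ar_force(self, w: np.ndarray, r, theta):
        """f_ar(r, theta) for a-r block coefficients w (54,)."""
        r = np.asarray(r, dtype=float)
        th = np.asarray(theta, dtype=float)
        P = laguerre_polynomials(self.alpha * r, self.n_laguerre - 1)
        wb = np.asarray(w).reshape(3, self.n_laguerre)
        radial = np.einsum("nl,l...->n...", wb, P)
        ang = np.stack([np.ones_like(th), np.cos(th), np.cos(2 * th)])
        return np.sum(radial * ang, axis=0) * np.exp(-0.5 * self.alpha * r)

    def align_force(self, w: np.ndarray, r, theta):
        r = np.asarray(r, dtype=float)
        th = np.asarray(theta, dtype=float)
        rates = np.array(self.align_rates)
        E = np.exp(np.multiply.outer(-2.0 * rates, r))
        wb = np.asarray(w).reshape(3, len(rates))
        radial = np.einsum("nl,l...->n...", wb, E)
        ang = 1.0 + np.stack([np.ones_like(th), np.cos(th), np.cos(2 * th)])
        return np.sum(radial * ang, axis=0)

    def drag_force(self, w: np.ndarray, s, theta):
        s = np.asarray(s, dtype=float)
        th = np.asarray(theta, dtype=float)
        powers = np.array(self.drag_powers)
        S = np.stack([s ** p for p in powers])
        wb = np.asarray(w).reshape(2, len(powers))
        radial = np.einsum("nl,l...->n...", wb, S)
        ang = 1.0 + np.stack([np.ones_like(th), np.cos(th)])
        return np.sum(radial * ang, axis=0)

    def block_force(self, block: str, w_full: np.ndarray, r_or_s, theta):
        """Evaluate one force block of a full coefficient vector w (J,)."""
        if block == "a-r":
            return self.ar_force(np.asarray(w_full)[self.ar_slice], r_or_s, theta)
        if block == "align":
            return self.align_force(np.asarray(w_full)[self.align_slice], r_or_s, theta)
        if block == "drag":
            return self.drag_force(np.asarray(w_full)[self.drag_slice], r_or_s, theta)
        raise ValueError(f"unknown block {block!r}")

    def ar_design(self, r, theta) -> np.ndarray:
        """Design matrix (npts, 54) of the a-r block on flat (r, theta)."""
        r = np.atleast_1d(np.asarray(r, dtype=float))
        th = np.atleast_1d(np.asarray(theta, dtype=float))
        P = laguerre_polynomials(self.alpha * r, self.n_laguerre - 1)  # (18, M)
        ang = np.stack([np.ones_like(th), np.cos(th), np.cos(2 * th)])  # (3, M)
        e = np.exp(-0.5 * self.alpha * r)
        return (ang[:, None, :] * P[None, :, :] * e).reshape(
            3 * self.n_laguerre, -1).T

    # ------------------------------------------------------------------
    # sparse-model encoding for the numba kernels
    # ------------------------------------------------------------------
    def model_arrays(self, w: np.ndarray):
        """Split a coefficient vector into per-block (n, ell, w) arrays of
        its nonzero terms, in the layout the simulation kernels consume."""
        w = np.asarray(w, dtype=float)
        out = []
        for sl in (self.ar_slice, self.align_slice, self.drag_slice):
            idx = [i for i in range(sl.start, sl.stop) if w[i] != 0.0]
            out.append(np.array([self.terms[i].n for i in idx], dtype=np.int64))
            out.append(np.array([self.terms[i].ell for i in idx], dtype=np.int64))
            out.append(np.array([w[i] for i in idx], dtype=np.float64))
        return tuple(out)
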