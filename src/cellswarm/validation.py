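"""Data-driven model validation and GMM classification.

A candidate model is validated on a cell by forward-simulating *only that
cell* with forward Euler on a fine grid (dt' = dt / 32 by default), while
every neighbour replays the recorded data, interpolated in time by
shape-preserving cubic Hermite (PCHIP) polynomials.  The validation
error is the relative summed-squared velocity mismatch over the first
quarter of the series.  Log-validation errors of a well-matched species
are approximately Gaussian, so remaining cells are split with an
averaged two-component Gaussian mixture; the low-error component is the
newly identified species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from sklearn.mixture import GaussianMixture

from . import _kernels
from .config import PipelineConfig
from .library import ForceLibrary
from .weakform import finite_diff_velocity


def validation_error(sim_v: np.ndarray, data_v: np.ndarray, l_prime: int) -> float:
    """Relative squared velocity mismatch over the first ``l_prime`` frames."""
    sim_v = np.asarray(sim_v, dtype=float)[:l_prime]
    data_v = np.asarray(data_v, dtype=float)[:l_prime]
    den = float(np.sum(data_v * data_v))
    if den == 0.0:
        raise ValueError("validation error undefined: data velocities are all zero")
    num = float(np.sum((sim_v - data_v) ** 2))
    return num / den


class DataDrivenValidator:
    """Precomputes neighbour interpolants and scores models on cells.

    The fine-grid neighbour states are shared by every simulation on the
    dataset; each call evolves one cell only and never touches the state
    of other simulated cells.
    """

    def __init__(self, data, config: PipelineConfig,
                 library: ForceLibrary | None = None,
                 velocities: np.ndarray | None = None,
                 n_frames: int | None = None):
        self.data = data
        self.config = config
        self.library = library if library is not None else ForceLibrary(
            alpha=config.alpha, eps_v=config.eps_v)
        self.V = velocities if velocities is not None else finite_diff_velocity(
            data.positions, data.dt)
        L = data.n_frames
        self.l_prime = max(2, int(round(config.l_prime_frac * L)))
        self.n_frames = n_frames if n_frames is not None else self.l_prime
        self.substep = config.substep
        self.h = data.dt / config.substep
        n_fine = (self.n_frames - 1) * self.substep + 1
        t_fine = data.times[0] + self.h * np.arange(n_fine)
        # neighbour positions and velocities are interpolated independently
        # (velocities are the finite-difference estimates, not derivatives
        # of the position interpolant)
        px = PchipInterpolator(data.times, data.positions, axis=1)
        pv = PchipInterpolator(data.times, self.V, axis=1)
        self.Xf = np.ascontiguousarray(px(t_fine).transpose(1, 0, 2))
        self.Vf = np.ascontiguousarray(pv(t_fine).transpose(1, 0, 2))
        self.denominators = np.sum(
            self.V[:, :self.l_prime, :] ** 2, axis=(1, 2))
        self._model_cache: dict[int, tuple] = {}

    def _arrays(self, w: np.ndarray) -> tuple:
        key = hash(np.asarray(w).tobytes())
        arrs = self._model_cache.get(key)
        if arrs is None:
            arrs = self.library.model_arrays(w)
            self._model_cache[key] = arrs
        return arrs

    def simulate(self, w: np.ndarray, cell: int,
                 n_frames: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Simulate ``cell`` under coefficients ``w``; return (xbar, vbar)
        at the coarse frames."""
        nf = n_frames if n_frames is not None else self.n_frames
        if nf > self.n_frames:
            raise ValueError("validator was not built for that many frames")
        xbar = np.empty((nf, 2))
        vbar = np.empty((nf, 2))
        x0, y0 = self.data.positions[cell, 0]
        vx0, vy0 = self.V[cell, 0]
        _kernels.simulate_cell(
            x0, y0, vx0, vy0, self.Xf, self.Vf, cell, *self._arrays(w),
            self.library.alpha, self.data.n_cells, self.h, self.substep,
            nf, np.ascontiguousarray(self.V[cell, :nf]), np.inf,
            self.config.eps_v, xbar, vbar)
        return xbar, vbar

    def delta_v(self, w: np.ndarray, cell: int, cap: float = np.inf) -> float:
        """Validation error of coefficients ``w`` on ``cell``.

        Simulations that blow up return +inf (scored as worst).  ``cap``
        enables early exit: any return above cap means "worse than cap".
        """
        den = self.denominators[cell]
        if den == 0.0:
            raise ValueError("validation error undefined: cell at rest in data")
        xbar = np.empty((self.l_prime, 2))
        vbar = np.empty((self.l_prime, 2))
        x0, y0 = self.data.positions[cell, 0]
        vx0, vy0 = self.V[cell, 0]
        num, status = _kernels.simulate_cell(
            x0, y0, vx0, vy0, self.Xf, self.Vf, cell, *self._arrays(w),
            self.library.alpha, self.data.n_cells, self.h, self.substep,
            self.l_prime, np.ascontiguousarray(self.V[cell, :self.l_prime]),
            cap * den if np.isfinite(cap) else np.inf,
            self.config.eps_v, xbar, vbar)
        if status == 2:
            return np.inf
        return num / den

    def model_validator(self):
        """Callable (model, cell, cap) -> dV for the replacement pass."""
        def _v(model, cell, cap=np.inf):
            return self.delta_v(model.w, cell, cap)
        return _v


@dataclass
class GMMPartition:
    """Two-component Gaussian mixture split of log10 validation errors."""

    means: np.ndarray          # averaged component means (low first)
    variances: np.ndarray
    weights: np.ndarray
    posteriors: np.ndarray     # (n_cells, 2) averaged; column 0 = species
    species_mask: np.ndarray   # True for cells assigned to the low-error mode
    degenerate: bool = False


def classify_gmm(ve: np.ndarray, n_gmm: int = 20, seed: int = 0) -> GMMPartition:
    """Split validation errors with an averaged two-component 1-D GMM.

    ``n_gmm`` EM fits from random initializations are averaged at the
    posterior level (components ordered by mean before averaging); cells
    join the component with the larger averaged posterior.  Infinite
    errors always land in the high-error component.  If the errors are
    (numerically) all equal the split degenerates to a single species.
    """
    ve = np.asarray(ve, dtype=float)
    if ve.size < 2:
        raise ValueError("need at least two validation errors")
    finite = np.isfinite(ve)
    logv = np.log10(np.clip(ve[finite], 1e-300, None)).reshape(-1, 1)
    if logv.size == 0 or np.ptp(logv) < 1e-12:
        post = np.zeros((ve.size, 2))
        post[:, 0] = 1.0
        post[~finite, 0] = 0.0
        post[~finite, 1] = 1.0
        mean = float(logv.mean()) if logv.size else np.inf
        return GMMPartition(means=np.array([mean, mean]),
                            variances=np.zeros(2), weights=np.array([1.0, 0.0]),
                            posteriors=post, species_mask=finite.copy(),
                            degenerate=True)
    rng = np.random.default_rng(seed)
    post_sum = np.zeros((logv.shape[0], 2))
    mean_sum = np.zeros(2)
    var_sum = np.zeros(2)
    wt_sum = np.zeros(2)
    n_ok = 0
    for _ in range(n_gmm):
        gm = GaussianMixture(n_components=2, covariance_type="full",
                             reg_covar=1e-10, n_init=1,
                             init_params="random_from_data",
                             random_state=int(rng.integers(2 ** 31)))
        try:
            gm.fit(logv)
        except ValueError:  # pragma: no cover - EM degeneracy
            continue
        order = np.argsort(gm.means_.ravel())
        post_sum += gm.predict_proba(logv)[:, order]
        mean_sum += gm.means_.ravel()[order]
        var_sum += gm.covariances_.ravel()[order]
        wt_sum += gm.weights_[order]
        n_ok += 1
    if n_ok == 0:
        raise RuntimeError("all GMM fits failed")
    post_f = post_sum / n_ok
    post = np.zeros((ve.size, 2))
    post[finite] = post_f
    post[~finite, 1] = 1.0
    mask = post[:, 0] > post[:, 1]
    return GMMPartition(means=mean_sum / n_ok, variances=var_sum / n_ok,
                        weights=wt_sum / n_ok, posteriors=post,
                        species_mask=mask)


def stopping_decision(n_remaining: int, ve: np.ndarray | None,
                      n_species: int, config: PipelineConfig) -> str:
    """One of 'continue', 'stop_outliers', 'stop_threshold',
    'stop_max_species', checked in that order of the stopping rules."""
    if n_remaining < config.n_min:
        return "stop_outliers"
    if ve is not None and len(ve):
        ve = np.asarray(ve, dtype=float)
        if np.mean(ve < config.eps_gmm) >= 1.0 - config.delta_gmm:
            return "stop_threshold"
    if n_species >= config.s_max_species:
        return "stop_max_species"
    return "continue"
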