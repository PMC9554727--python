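"""Synthetic population simulator.

Integrates the second-order directional interacting-particle system

    x_i'' = (1/N) sum_{j != i} f_ar(r_ij, th_ij) (x_i - x_j)
          + (1/N) sum_{j != i} f_align(r_ij, th_ij) (v_i - v_j)
          + (1/N) sum_{j != i} f_drag(|v_i|, th_ij) v_i

forward in time with RK4 on a fine substep grid and records positions at
L uniformly spaced coarse frames.  The default protocol packs cells on a
small disc, integrates a discarded burn-in so recording starts from the
settled jostling colony, and redraws velocities at frame zero so the
recorded window contains a wide range of speeds; see docs/methods.md for
why each stage matters for identifiability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .forces import EPS_V, SpeciesSpec, species_registry


class SimulationBlowupError(RuntimeError):
    """Raised when a simulated cell leaves the admissible domain."""

    def __init__(self, cell: int, step: int, bound: float):
        self.cell = cell
        self.step = step
        super().__init__(
            f"simulation blow-up: cell {cell} exceeded |x| = {bound} "
            f"at fine step {step}")


@dataclass
class TrajectoryData:
    """Positions of N cells over L uniformly spaced times.

    positions : (N, L, 2); times : (L,) strictly increasing, uniform;
    labels : optional (N,) true species labels; velocities : optional
    (N, L, 2).
    """

    positions: np.ndarray
    times: np.ndarray
    labels: np.ndarray | None = None
    velocities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (N, L, 2)")
        if self.times.shape != (self.positions.shape[1],):
            raise ValueError("times length must match frame count")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        d = np.diff(self.times)
        if len(d) and (np.any(d <= 0) or
                       np.max(np.abs(d - d[0])) > 1e-10 * max(abs(d[0]), 1.0)):
            raise ValueError("times must be strictly increasing and uniform")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (self.positions.shape[0],):
                raise ValueError("labels length must match cell count")

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class SimulationConfig:
    """Population size, composition, time grid and initial conditions."""

    n_tot: int = 200
    proportions: dict[str, float] = field(default_factory=lambda: {"A": 1.0})
    n_frames: int = 200
    dt: float = 0.02
    substep: int = 32               # RK4 runs at dt / substep
    ic_radius: float = 0.3          # positions uniform on a disc
    ic_speed_std: float = 0.12      # normal components ("normal" draw)
    ic_speed_dist: str = "normal"   # or "uniform": speeds U(0, ic_speed_max)
    ic_speed_max: float = 0.25      # speed cap of the uniform draw
    burn_in: float = 2.0            # settling time integrated before frame 0
    rejuvenate: bool = True         # redraw velocities at recording start
    blowup_bound: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_frames < 2:
            raise ValueError("need at least two frames")
        tot = sum(self.proportions.values())
        if abs(tot - 1.0) > 1e-6:
            raise ValueError("species proportions must sum to 1")


def _species_arrays(labels: np.ndarray, specs: dict[str, SpeciesSpec]):
    n = len(labels)
    has_ar = np.zeros(n, dtype=np.uint8)
    has_al = np.zeros(n, dtype=np.uint8)
    has_dr = np.zeros(n, dtype=np.uint8)
    ar_p = np.zeros((n, 5))
    al_p = np.zeros((n, 3))
    dr_p = np.zeros((n, 1))
    for i, lab in enumerate(labels):
        sp = specs[str(lab)]
        has_ar[i] = sp.has_ar
        has_al[i] = sp.has_align
        has_dr[i] = sp.has_drag
        ar_p[i] = sp.ar_params
        al_p[i] = sp.align_params
        dr_p[i] = sp.drag_params
    return has_ar, has_al, has_dr, ar_p, al_p, dr_p


def acceleration_rhs(X: np.ndarray, V: np.ndarray, labels,
                     specs: dict[str, SpeciesSpec] | None = None) -> np.ndarray:
    """Accelerations of all cells given positions X and velocities V (N, 2)."""
    specs = specs if specs is not None else species_registry()
    X = np.ascontiguousarray(X, dtype=float)
    V = np.ascontiguousarray(V, dtype=float)
    if X.shape != V.shape or X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("X and V must both have shape (N, 2)")
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("one species label per cell required")
    arrs = _species_arrays(labels, specs)
    out = np.empty_like(X)
    bad = _kernels.truth_accel(X, V, *arrs, EPS_V, out)
    if bad >= 0:
        raise ValueError(f"coincident cells: cell {bad} overlaps a neighbour")
    return out


def make_labels(config: SimulationConfig) -> np.ndarray:
    """Deterministic per-cell species labels matching the proportions."""
    names = sorted(config.proportions)
    counts = {k: int(round(config.proportions[k] * config.n_tot)) for k in names}
    # fix rounding drift on the largest group
    drift = config.n_tot - sum(counts.values())
    counts[max(names, key=lambda k: counts[k])] += drift
    labels = []
    for k in names:
        labels += [k] * counts[k]
    return np.array(labels)


def simulate_population(config: SimulationConfig,
                        specs: dict[str, SpeciesSpec] | None = None) -> TrajectoryData:
    """Simulate a (possibly mixed) population and return its trajectory data.

    Deterministic given ``config.seed``.  Velocities recorded are the exact
    integrator velocities at the coarse frames (the learning pipeline
    re-estimates velocities by finite differences and never reads these).
    """
    specs = specs if specs is not None else species_registry()
    rng = np.random.default_rng(config.seed)
    labels = make_labels(config)
    n = config.n_tot
    # uniform on a disc
    r = config.ic_radius * np.sqrt(rng.uniform(size=n))
    phi = rng.uniform(0, 2 * np.pi, size=n)
    X0 = np.column_stack([r * np.cos(phi), r * np.sin(phi)])

    def draw_velocities() -> np.ndarray:
        if config.ic_speed_dist == "uniform":
            # uniform speeds with random headings: the whole speed range
            # up to the cap is densely sampled
            s = rng.uniform(0.0, config.ic_speed_max, size=n)
            a = rng.uniform(0, 2 * np.pi, size=n)
            return np.column_stack([s * np.cos(a), s * np.sin(a)])
        if config.ic_speed_dist == "normal":
            return rng.normal(scale=config.ic_speed_std, size=(n, 2))
        raise ValueError(f"unknown ic_speed_dist {config.ic_speed_dist!r}")

    V0 = draw_velocities()
    arrs = _species_arrays(labels, specs)
    L = config.n_frames
    h = config.dt / config.substep
    n_burn = int(round(config.burn_in / config.dt))
    if n_burn > 0:
        # settle the colony into its packed jostling state first
        Xb = np.empty((n_burn + 1, n, 2))
        Vb = np.empty((n_burn + 1, n, 2))
        bad, step = _kernels.rk4_simulate(
            np.ascontiguousarray(X0), np.ascontiguousarray(V0), *arrs,
            n_burn + 1, config.substep, h, config.blowup_bound, EPS_V, Xb, Vb)
        if bad >= 0:
            raise SimulationBlowupError(bad, step, config.blowup_bound)
        X0, V0 = Xb[-1].copy(), Vb[-1].copy()
    if config.rejuvenate:
        # fresh velocity draw at recording start: wide speed range in-window
        V0 = draw_velocities()
    Xf = np.empty((L, n, 2))
    Vf = np.empty((L, n, 2))
    bad, step = _kernels.rk4_simulate(
        np.ascontiguousarray(X0), np.ascontiguousarray(V0), *arrs,
        L, config.substep, h, config.blowup_bound, EPS_V, Xf, Vf)
    if bad >= 0:
        raise SimulationBlowupError(bad, step, config.blowup_bound)
    times = config.dt * np.arange(L)
    return TrajectoryData(positions=Xf.transpose(1, 0, 2).copy(),
                          times=times, labels=labels,
                          velocities=Vf.transpose(1, 0, 2).copy())
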