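"""Model replacement ("cross-pollination") between statistically similar cells.

A cell with an uninformative trajectory can inherit the model of a cell
whose local environment looks statistically alike.  Similarity is
measured on three per-cell distributions — neighbour distances, velocity
differences to neighbours, and own speed — via squared Kullback-Leibler
divergences.  A model M_j replaces M_i only if the two cells are mutual
validation neighbours, M_j beats M_i on both cells, and M_j achieves a
validation error below ``tol`` on both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_KL_EPS = 1e-10


@dataclass
class CellStatistics:
    """Three 50-bin normalized histograms characterizing a cell's context."""

    rho_rr: np.ndarray
    rho_vv: np.ndarray
    rho_v: np.ndarray
    edges_rr: np.ndarray
    edges_vv: np.ndarray
    edges_v: np.ndarray


def compute_population_statistics(positions: np.ndarray, velocities: np.ndarray,
                                  n_bins: int = 50) -> list[CellStatistics]:
    """Per-cell statistics with bin edges shared across the population.

    For cell i the three histograms pool, over all frames: distances
    ``|x_i - x_j|`` and velocity differences ``|v_i - v_j|`` over j != i,
    and the cell's own speeds ``|v_i|``.  Shared edges span [0, population
    maximum] in ``n_bins`` equal bins so divergences are comparable.
    """
    N, L, _ = positions.shape
    if N < 2:
        raise ValueError("need at least two cells")
    counts_rr = np.zeros((N, n_bins))
    counts_vv = np.zeros((N, n_bins))
    speeds = np.sqrt(np.sum(velocities * velocities, axis=2))  # (N, L)
    # first pass: global maxima for the shared edges
    max_d = 0.0
    max_dv = 0.0
    for k in range(L):
        D = positions[:, k, :]
        dd = D[:, None, :] - D[None, :, :]
        rd = np.sqrt(np.sum(dd * dd, axis=2))
        max_d = max(max_d, float(rd.max()))
        Vk = velocities[:, k, :]
        dv = Vk[:, None, :] - Vk[None, :, :]
        rv = np.sqrt(np.sum(dv * dv, axis=2))
        max_dv = max(max_dv, float(rv.max()))
    edges_rr = np.linspace(0.0, max_d if max_d > 0 else 1.0, n_bins + 1)
    edges_vv = np.linspace(0.0, max_dv if max_dv > 0 else 1.0, n_bins + 1)
    smax = float(speeds.max())
    edges_v = np.linspace(0.0, smax if smax > 0 else 1.0, n_bins + 1)
    off = ~np.eye(N, dtype=bool)
    for k in range(L):
        D = positions[:, k, :]
        dd = D[:, None, :] - D[None, :, :]
        rd = np.sqrt(np.sum(dd * dd, axis=2))
        idx = np.clip(np.searchsorted(edges_rr, rd, side="right") - 1, 0, n_bins - 1)
        Vk = velocities[:, k, :]
        dv = Vk[:, None, :] - Vk[None, :, :]
        rv = np.sqrt(np.sum(dv * dv, axis=2))
        jdx = np.clip(np.searchsorted(edges_vv, rv, side="right") - 1, 0, n_bins - 1)
        for i in range(N):
            counts_rr[i] += np.bincount(idx[i][off[i]], minlength=n_bins)
            counts_vv[i] += np.bincount(jdx[i][off[i]], minlength=n_bins)
    sdx = np.clip(np.searchsorted(edges_v, speeds, side="right") - 1, 0, n_bins - 1)
    out = []
    for i in range(N):
        cv = np.bincount(sdx[i], minlength=n_bins).astype(float)
        out.append(CellStatistics(
            rho_rr=counts_rr[i] / counts_rr[i].sum(),
            rho_vv=counts_vv[i] / counts_vv[i].sum(),
            rho_v=cv / cv.sum(),
            edges_rr=edges_rr, edges_vv=edges_vv, edges_v=edges_v))
    return out


def compute_cell_statistics(positions: np.ndarray, velocities: np.ndarray,
                            i: int, n_bins: int = 50) -> CellStatistics:
    """Statistics of a single cell (shared population edges)."""
    return compute_population_statistics(positions, velocities, n_bins)[i]


def kl_divergence(rho: np.ndarray, nu: np.ndarray,
                  edges_rho: np.ndarray | None = None,
                  edges_nu: np.ndarray | None = None) -> float:
    """Discrete KL divergence D(rho | nu) in nats.

    ``nu`` receives an additive pseudo-mass of 1e-10 per bin (then
    renormalized) so that bins empty under nu but occupied under rho give
    a large finite rather than infinite divergence.
    """
    if edges_rho is not None and edges_nu is not None and \
            not np.array_equal(edges_rho, edges_nu):
        raise ValueError("histograms must share bin edges")
    rho = np.asarray(rho, dtype=float)
    nu = np.asarray(nu, dtype=float) + _KL_EPS
    nu = nu / nu.sum()
    pos = rho > 0
    return float(np.sum(rho[pos] * np.log(rho[pos] / nu[pos])))


def kl_cost_matrix(stats: list[CellStatistics]) -> np.ndarray:
    """Pairwise replacement cost L_ij = sum of squared KL divergences."""
    cost = np.zeros((len(stats), len(stats)))
    for attr in ("rho_rr", "rho_vv", "rho_v"):
        P = np.stack([getattr(s, attr) for s in stats])
        nu = P + _KL_EPS
        nu /= nu.sum(axis=1, keepdims=True)
        logs = np.log(nu)
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(P > 0, P * np.log(np.where(P > 0, P, 1.0)), 0.0)
        H = plogp.sum(axis=1)
        kl = H[:, None] - P @ logs.T
        cost += kl ** 2
    return cost


def select_validation_cells(i: int, costs: np.ndarray, K: int) -> np.ndarray:
    """The K cells j != i of smallest cost; ties break to the lower id."""
    if K < 1:
        raise ValueError("K must be >= 1")
    N = len(costs)
    others = np.array([j for j in range(N) if j != i])
    order = np.lexsort((others, costs[others]))
    return others[order][:min(K, N - 1)]


def replacement_pass(models: list, cost_matrix: np.ndarray, validator,
                     K: int, tol: float) -> tuple[list, list[dict]]:
    """One model-replacement pass over the population.

    ``validator(model, cell, cap)`` must return the validation error of
    simulating ``model`` on ``cell``; it may return any value above
    ``cap`` early (the decision logic only needs exact values below it).

    A model M_j replaces M_i when cells i, j are mutual validation
    neighbours and (1) dV_{j->i} < dV_{i->i}, (2) dV_{i->j} > dV_{j->j},
    (3) max(dV_{j->i}, dV_{j->j}) < tol.  Among qualifying j the one with
    smallest dV_{j->i} wins.  Replacements are closed transitively: if
    M_j replaces M_i and M_k replaces M_j, cell i receives M_k.

    Returns (new model list, log of replacement records).
    """
    N = len(models)
    val_sets = [set(select_validation_cells(i, cost_matrix[i], K).tolist())
                for i in range(N)]
    dv_self = np.array([validator(models[i], i, np.inf) for i in range(N)])
    pairs = [(i, j) for i in range(N) for j in val_sets[i]
             if j > i and i in val_sets[j]]
    dv: dict[tuple[int, int], float] = {}
    for i, j in pairs:
        dv[(j, i)] = validator(models[j], i, max(tol, dv_self[i]) * (1 + 1e-9))
        dv[(i, j)] = validator(models[i], j, max(tol, dv_self[j]) * (1 + 1e-9))
    replaced_by: dict[int, int] = {}
    for i in range(N):
        best_j = -1
        best_dv = np.inf
        for j in sorted(val_sets[i]):
            if i not in val_sets[j] or (j, i) not in dv:
                continue
            dv_ji = dv[(j, i)]
            dv_ij = dv[(i, j)]
            if (dv_ji < dv_self[i] and dv_ij > dv_self[j]
                    and max(dv_ji, dv_self[j]) < tol and dv_ji < best_dv):
                best_dv = dv_ji
                best_j = j
        if best_j >= 0:
            replaced_by[i] = best_j

    # transitive closure: follow chains to their root, guarding cycles
    def root_of(i: int) -> int:
        seen = {i}
        j = i
        while j in replaced_by and replaced_by[j] not in seen:
            j = replaced_by[j]
            seen.add(j)
        return j

    new_models = []
    log = []
    for i in range(N):
        r = root_of(i)
        if r == i:
            new_models.append(models[i])
        else:
            new_models.append(models[r].copy_as_replacement(i))
            dv_after = dv.get((r, i))
            if dv_after is None:
                dv_after = validator(models[r], i, np.inf)
            log.append({"cell_id": i, "replaced_by": r,
                        "dV_before": float(dv_self[i]),
                        "dV_after": float(dv_after)})
    return new_models, log
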