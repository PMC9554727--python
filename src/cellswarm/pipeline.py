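"""End-to-end pipeline: learn, replace, then iterate
cluster -> aggregate -> validate -> classify until all cells are sorted,
plus evaluation metrics against ground truth.

The pipeline is unsupervised: true species labels, when present in the
data, are used only by the evaluation helpers (classification success
CS, force errors against the generating kernels).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .clustering import AggregateModel, aggregate_cluster, partition_by_code
from .config import PipelineConfig
from .exchange import compute_population_statistics, kl_cost_matrix, replacement_pass
from .forces import SpeciesSpec, species_registry
from .library import ForceLibrary
from .regression import (CellModel, build_constraint_system, lambda_sweep)
from .validation import DataDrivenValidator, classify_gmm, stopping_decision
from .weakform import (assemble_weak_system, build_test_functions,
                       compute_near_field_radius, finite_diff_velocity,
                       max_pairwise_distance, max_speed)

logger = logging.getLogger("cellswarm")


@dataclass
class SpeciesResult:
    """One identified species: members, model, per-cell validation errors."""

    ordinal: int
    members: list[int]
    aggregate: AggregateModel
    delta_v: dict[int, float]
    metrics: dict = field(default_factory=dict)

    @property
    def mean_delta_v(self) -> float:
        return float(np.mean([self.delta_v[i] for i in self.members]))


@dataclass
class PipelineResult:
    species: list[SpeciesResult]
    outliers: list[int]
    models: list[CellModel]
    stop_reason: str
    replacement_log: list[dict]
    iteration_log: list[dict]
    config: PipelineConfig


def learn_all_models(data, config: PipelineConfig, library: ForceLibrary,
                     constraints, velocities: np.ndarray) -> list[CellModel]:
    """Learn one sparse model per focal cell (all cells are focal)."""
    basis = build_test_functions(data.n_frames, data.dt, config.m, config.p)
    models = []
    for i in range(data.n_cells):
        theta = library.evaluate_features(data.positions, velocities, i)
        system = assemble_weak_system(data.positions[i], theta, basis,
                                      data.dt, focal=i)
        w, lam = lambda_sweep(system, constraints, config.lambda_grid)
        models.append(CellModel(w=w, selected_lambda=lam, focal=i))
    return models


def run_pipeline(data, config: PipelineConfig | None = None) -> PipelineResult:
    """Full unsupervised species identification on one trajectory dataset.

    Models are learned once and replaced once; the
    cluster/aggregate/validate/classify loop then peels off one species
    per iteration until a stopping rule fires.  Deterministic given
    ``config.seed``.
    """
    config = config if config is not None else PipelineConfig()
    library = ForceLibrary(alpha=config.alpha, eps_v=config.eps_v)
    V = finite_diff_velocity(data.positions, data.dt)
    try:
        r_nf = compute_near_field_radius(data.positions, config.p_nf)
        r_max = max(max_pairwise_distance(data.positions), config.r_ff + 1e-9)
        constraints = build_constraint_system(
            library, r_nf, config.r_ff, r_max, max_speed(V),
            n_radii=config.n_colloc_radii, n_angles=config.n_colloc_angles)
    except Exception as exc:
        raise RuntimeError(f"[constraints] {exc}") from exc
    try:
        models = learn_all_models(data, config, library, constraints, V)
    except Exception as exc:
        raise RuntimeError(f"[learn] {exc}") from exc
    logger.info("learned %d models", len(models))
    validator = DataDrivenValidator(data, config, library=library, velocities=V)
    try:
        stats = compute_population_statistics(data.positions, V)
        costs = kl_cost_matrix(stats)
        models, repl_log = replacement_pass(
            models, costs, validator.model_validator(), config.K, config.tol)
    except Exception as exc:
        raise RuntimeError(f"[replace] {exc}") from exc
    logger.info("replacement pass: %d cells replaced", len(repl_log))
    return _classification_loop(data, config, library, validator, models, repl_log)


def _classification_loop(data, config: PipelineConfig, library: ForceLibrary,
                         validator: DataDrivenValidator,
                         models: list[CellModel],
                         repl_log: list[dict]) -> PipelineResult:
    """Iterate cluster -> aggregate -> validate -> classify until a
    stopping rule fires; classified cells leave the pool each round."""
    remaining = list(range(data.n_cells))
    species: list[SpeciesResult] = []
    outliers: list[int] = []
    iter_log: list[dict] = []
    stop_reason = ""
    iteration = 0
    while True:
        decision = stopping_decision(len(remaining), None, len(species), config)
        if decision != "continue":
            stop_reason = decision
            outliers = list(remaining)
            break
        try:
            sub = [models[i] for i in remaining]
            clusters, code = partition_by_code(sub, library)
            agg = aggregate_cluster(sub, clusters[code], library,
                                    lambda_log=config.lambda_log)
            agg = AggregateModel(w=agg.w, code=agg.code,
                                 members=[remaining[k] for k in agg.members])
        except Exception as exc:
            raise RuntimeError(f"[cluster/aggregate] {exc}") from exc
        try:
            ve = np.array([validator.delta_v(agg.w, i) for i in remaining])
        except Exception as exc:
            raise RuntimeError(f"[validate] {exc}") from exc
        entry = {"iteration": iteration, "n_remaining": len(remaining),
                 "largest_code": code,
                 "cluster_sizes": {c: len(m) for c, m in clusters.items()}}
        if stopping_decision(len(remaining), ve, len(species), config) == "stop_threshold":
            good = ve < config.eps_gmm
            members = [c for c, g in zip(remaining, good) if g]
            species.append(SpeciesResult(
                ordinal=len(species) + 1, members=members, aggregate=agg,
                delta_v={c: float(v) for c, v in zip(remaining, ve)}))
            outliers = [c for c, g in zip(remaining, good) if not g]
            stop_reason = "stop_threshold"
            entry["species_size"] = len(members)
            iter_log.append(entry)
            break
        try:
            part = classify_gmm(ve, n_gmm=config.n_gmm,
                                seed=config.seed + 7919 * (iteration + 1))
        except Exception as exc:
            raise RuntimeError(f"[classify] {exc}") from exc
        members = [c for c, m in zip(remaining, part.species_mask) if m]
        entry.update({"gmm_means": part.means.tolist(),
                      "species_size": len(members)})
        iter_log.append(entry)
        if not members:
            # mixture failed to isolate a low-error mode; remaining cells
            # carry no further signal under any aggregate model
            stop_reason = "stop_outliers"
            outliers = list(remaining)
            break
        species.append(SpeciesResult(
            ordinal=len(species) + 1, members=members, aggregate=agg,
            delta_v={c: float(v) for c, v in zip(remaining, ve)}))
        remaining = [c for c, m in zip(remaining, part.species_mask) if not m]
        iteration += 1
        logger.info("iteration %d: species of %d cells (code %s), %d remain",
                    iteration, len(members), agg.code, len(remaining))
        if not remaining:
            stop_reason = "all_classified"
            break
    return PipelineResult(species=species, outliers=outliers, models=models,
                          stop_reason=stop_reason, replacement_log=repl_log,
                          iteration_log=iter_log, config=config)


# ----------------------------------------------------------------------
# evaluation against ground truth
# ----------------------------------------------------------------------

def force_error_grid(library: ForceLibrary, w: np.ndarray, spec: SpeciesSpec,
                     kind: str, s_max: float = 1.0, n_grid: int = 1000,
                     chunk: int = 200_000) -> float:
    """Relative L2 error of a learned force block against the true kernel.

    a-r and alignment are compared on a Cartesian grid
    (x, y) in [-2, 2]^2 with r = |(x, y)| and theta the polar angle;
    drag on (s, theta) in [0, s_max] x [0, pi].  ``n_grid`` points per
    direction.
    """
    flag = {"a-r": spec.has_ar, "align": spec.has_align,
            "drag": spec.has_drag}.get(kind)
    if flag is None:
        raise ValueError(f"unknown force kind {kind!r}")
    if not flag:
        raise ValueError(f"species {spec.name} has no {kind} force")
    if kind == "drag":
        s = np.linspace(0.0, s_max, n_grid)
        th = np.linspace(0.0, np.pi, n_grid)
        ss, tt = np.meshgrid(s, th, indexing="ij")
        a, b = ss.ravel(), tt.ravel()
    else:
        xy = np.linspace(-2.0, 2.0, n_grid)
        xx, yy = np.meshgrid(xy, xy, indexing="ij")
        a = np.hypot(xx, yy).ravel()
        b = np.arctan2(yy, xx).ravel()
    num = 0.0
    den = 0.0
    for lo in range(0, a.size, chunk):
        ac = a[lo:lo + chunk]
        bc = b[lo:lo + chunk]
        fhat = library.block_force(kind, w, ac, bc)
        ftrue = spec.force(kind, ac, bc)
        num += float(np.sum((fhat - ftrue) ** 2))
        den += float(np.sum(ftrue ** 2))
    return float(np.sqrt(num / den))


def classification_success(members: list[int], labels: np.ndarray,
                           true_species: str) -> float:
    """Fraction of true ``true_species`` cells contained in ``members``."""
    labels = np.asarray(labels).astype(str)
    total = int(np.sum(labels == true_species))
    if total == 0:
        raise ValueError(f"species {true_species!r} absent from the data")
    hit = sum(1 for c in members if labels[c] == true_species)
    return hit / total


def evaluate_result(result: PipelineResult, data,
                    specs: dict[str, SpeciesSpec] | None = None,
                    n_grid: int = 1000) -> PipelineResult:
    """Attach CS / force-error / mean-dV metrics to each species in place."""
    specs = specs if specs is not None else species_registry()
    if data.labels is None:
        raise ValueError("evaluation requires true labels")
    labels = np.asarray(data.labels).astype(str)
    library = ForceLibrary(alpha=result.config.alpha, eps_v=result.config.eps_v)
    V = finite_diff_velocity(data.positions, data.dt)
    s_max = max_speed(V)
    present = sorted(set(labels))
    for sp in result.species:
        member_labels = labels[sp.members]
        counts = {s: int(np.sum(member_labels == s)) for s in present}
        majority = max(counts, key=lambda s: counts[s]) if sp.members else None
        m = {"majority_species": majority,
             "cs": {s: classification_success(sp.members, labels, s)
                    for s in present},
             "mean_delta_v": sp.mean_delta_v,
             "delta_f": {}}
        if majority is not None:
            truth = specs[majority]
            for kind, flag in (("a-r", truth.has_ar), ("align", truth.has_align),
                               ("drag", truth.has_drag)):
                if flag:
                    m["delta_f"][kind] = force_error_grid(
                        library, sp.aggregate.w, truth, kind,
                        s_max=s_max, n_grid=n_grid)
        sp.metrics = m
    return result


def report(result: PipelineResult, data) -> dict:
    """Machine-readable summary mirroring the benchmark tables: one row
    per identified cluster in discovery order, with force errors per
    force (absent forces rendered as None / '-'), CS per true species and
    mean validation error."""
    rows = []
    for sp in result.species:
        m = sp.metrics
        rows.append({
            "cluster": sp.ordinal,
            "n_members": len(sp.members),
            "code": sp.aggregate.code,
            "delta_f_ar": m.get("delta_f", {}).get("a-r"),
            "delta_f_align": m.get("delta_f", {}).get("align"),
            "delta_f_drag": m.get("delta_f", {}).get("drag"),
            "cs": m.get("cs", {}),
            "mean_delta_v": m.get("mean_delta_v", sp.mean_delta_v),
        })
    return {"clusters": rows, "n_outliers": len(result.outliers),
            "outliers": list(result.outliers),
            "stop_reason": result.stop_reason}


def format_report(rep: dict) -> str:
    """Human-readable table of a report dictionary."""
    lines = ["cluster  size  code      dF_a-r   dF_align dF_drag  "
             "CS                        mean_dV"]
    for row in rep["clusters"]:
        def fmt(v):
            return f"{v:8.4f}" if v is not None else "   --   "
        cs = " ".join(f"{k}:{v:.3f}" for k, v in sorted(row["cs"].items()))
        lines.append(
            f"{row['cluster']:>7d}  {row['n_members']:>4d}  {row['code']}  "
            f"{fmt(row['delta_f_ar'])} {fmt(row['delta_f_align'])} "
            f"{fmt(row['delta_f_drag'])} {cs:<25s} "
            f"{row['mean_delta_v']:.4f}")
    lines.append(f"outliers: {rep['n_outliers']}  (stop: {rep['stop_reason']})")
    return "\n".join(lines)


def report_to_json(rep: dict, path) -> None:
    with open(path, "w") as f:
        json.dump(rep, f, indent=2)
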