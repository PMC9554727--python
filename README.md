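# cellswarm

Unsupervised discovery of cell–cell interaction rules from trajectory
data. Given tracked 2-D positions of a migrating cell population,
`cellswarm` learns, for every cell, a sparse anisotropic interaction
model — attraction–repulsion, velocity alignment, and drag — by
weak-form sparse regression, and then sorts the population into
*species* (subpopulations sharing one set of rules) by iterative model
clustering, aggregation, data-driven forward validation, and Gaussian
mixture classification. It is aimed at quantitative cell biologists and
modellers who want explicit, simulatable equations of motion for
heterogeneous populations rather than black-box classifiers.

## The model

Each cell obeys a second-order directional interacting-particle model

    ẍᵢ = (1/N) Σ_{j≠i} f_ar(r_ij, θ_ij)(xᵢ−xⱼ)
       + (1/N) Σ_{j≠i} f_al(r_ij, θ_ij)(vᵢ−vⱼ)
       + (1/N) Σ_{j≠i} f_dr(|vᵢ|, θ_ij) vᵢ,

with θ_ij the angle between vᵢ and xⱼ−xᵢ and angular dependence
restricted to {1, cos θ, cos 2θ}. Each force is expanded in a dedicated
basis (weighted Laguerre polynomials for f_ar, exponentials for f_al,
monomials in speed for f_dr; 88 terms in total), subject to sign
constraints: near-field repulsion and far-field attraction for f_ar,
non-positive f_al and f_dr. Coefficients are found per cell by testing
the dynamics against compactly supported C² bumps (so no accelerations
are ever differenced from data) and solving a constrained
sequential-thresholding sparse regression with a swept threshold.
Models are then cross-pollinated between statistically similar cells,
clustered by their 8-bit force-mode code, averaged, and validated by
simulating each cell forward against its recorded neighbours; the
low-error mode of the validation-error distribution becomes the next
identified species.

A synthetic population simulator with three benchmark species
(A: all three forces, B: attraction–repulsion + drag, C: alignment +
drag) generates test data by RK4 integration of the ground-truth
kernels.

## Worked example

```python
from cellswarm import SimulationConfig, simulate_population, PipelineConfig
from cellswarm.pipeline import run_pipeline, evaluate_result, report, format_report

# a 50/50 mixture of species A and C, 200 cells, 200 frames
data = simulate_population(SimulationConfig(
    n_tot=200, proportions={"A": 0.5, "C": 0.5}, n_frames=200, seed=11))
result = run_pipeline(data, PipelineConfig(seed=1))
evaluate_result(result, data)
print(format_report(report(result, data)))
```

prints (about 3 minutes on one core):

```
cluster  size  code      dF_a-r   dF_align dF_drag  CS                        mean_dV
      1   100  00011010     --      0.0003   0.0014 A:0.000 C:1.000           0.0000
      2   100  10111010    0.1081   0.0061   0.0104 A:1.000 C:0.000           0.0000
outliers: 0  (stop: stop_threshold)
```

Reading the table: the pipeline first isolates a species with force-mode
code `00011010` (alignment modes 0–1 + drag mode 0) containing 100 % of
the true species-C cells (`CS`), whose aggregate alignment kernel is
within 0.03 % relative L² error of the generating kernel (`dF_align`)
and whose trajectories are reproduced to well under 0.01 % relative
velocity error (`mean_dV`); the second cluster captures all species-A
cells with code `10111010`, with the alignment and drag kernels within
~1 % and the harder attraction–repulsion kernel within ~11 %. Dashes
mark forces absent from that species' ground truth.

The same pipeline is available from the shell:

```
cellswarm simulate --config sim.yaml --seed 11 --out traj.csv
cellswarm run-all --data traj.csv --seed 1 --out species.json
```

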