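"""Hyperparameter bundle for the learning and classification pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np


@dataclass
class PipelineConfig:
    """All pipeline hyperparameters with their benchmark defaults.

    p_nf : probability defining the near-field radius r_nf
    r_ff : far-field radius beyond which f_ar must be attractive
    alpha : Laguerre scale of the a-r basis (e^{-alpha r_max / 2} ~ eps_mach)
    m, p : test-function half-width (frames) and smoothness exponent
    lambda grid : sweep of sparsity thresholds, log-spaced
    K : validation-neighbourhood size for model replacement
    tol : replacement acceptance threshold on validation error
    lambda_log : aggregate re-threshold, drop |w| < 10^-lambda_log max|w|
    substep : validation simulations run at dt' = dt / substep
    l_prime_frac : fraction of the series scored by the validation error
    eps_gmm, delta_gmm : early-stop when P(VE < eps_gmm) >= 1 - delta_gmm
    n_min : minimum unclassified cells to keep iterating
    n_gmm : number of random-restart GMM fits averaged per classification
    s_max_species : maximum number of species to identify
    """

    p_nf: float = 0.001
    r_ff: float = 1.0
    alpha: float = 36.0
    m: int = 35
    p: int = 9
    n_lambda: int = 40
    lambda_min: float = 1e-4
    lambda_max: float = 1.0
    K: int = 32
    tol: float = 0.25
    lambda_log: float = 4.0
    substep: int = 32
    l_prime_frac: float = 0.25
    eps_gmm: float = 0.05
    delta_gmm: float = 0.01
    n_min: int = 2
    n_gmm: int = 20
    s_max_species: int = 10
    eps_v: float = 1e-12
    n_colloc_radii: int = 30
    n_colloc_angles: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_nf < 1:
            raise ValueError("p_nf must lie in (0, 1)")
        if self.p < 3:
            raise ValueError("p >= 3 required")
        if not 0 < self.lambda_min <= self.lambda_max <= 1:
            raise ValueError("lambda grid must satisfy 0 < min <= max <= 1")
        if self.l_prime_frac <= 0 or self.l_prime_frac > 1:
            raise ValueError("l_prime_frac must lie in (0, 1]")

    @property
    def lambda_grid(self) -> np.ndarray:
        return np.logspace(np.log10(self.lambda_min),
                           np.log10(self.lambda_max), self.n_lambda)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)
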