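"""Constrained sparse regression: thresholding, LSI solver, sweep."""

import numpy as np
import pytest

from cellswarm.library import ForceLibrary
from cellswarm.regression import (build_constraint_system, constrained_lstsq,
                                  lambda_sweep, mstls_solve,
                                  threshold_operator)
from cellswarm.weakform import WeakSystem


def make_system(G, b, focal=0):
    return WeakSystem(G=G, b=b, focal=focal,
                      col_norms=np.linalg.norm(G, axis=0),
                      b_norm=float(np.linalg.norm(b)))


class TestThresholdOperator:
    @pytest.mark.parametrize("ratio,lam,kept", [
        (1e-5, 1e-3, False),   # below lambda
        (1e4, 1e-3, False),    # above 1/lambda: the upper cut is real
        (0.5, 1e-3, True),
        (1e-3, 1e-3, True),    # boundary inclusive
        (1e3, 1e-3, True),
    ])
    def test_truth_table(self, ratio, lam, kept):
        b_norm = 2.0
        col = np.array([4.0])
        w = np.array([ratio * b_norm / col[0]])
        out = threshold_operator(w, col, b_norm, lam)
        assert (out[0] != 0.0) == kept

    def test_zero_response_zeroes_everything(self):
        w = np.array([1.0, -2.0])
        out = threshold_operator(w, np.ones(2), 0.0, 0.1)
        assert np.all(out == 0.0)

    def test_invalid_lambda(self):
        with pytest.raises(ValueError):
            threshold_operator(np.ones(1), np.ones(1), 1.0, 0.0)


class TestConstrainedLstsq:
    def test_unconstrained_when_feasible(self):
        rng = np.random.default_rng(0)
        G = rng.normal(size=(30, 4))
        w_true = np.array([1.0, -2.0, 0.5, 3.0])
        b = G @ w_true
        C = np.zeros((1, 4))
        w = constrained_lstsq(G, b, C, np.zeros(1))
        assert np.allclose(w, w_true, atol=1e-10)

    def test_sign_constraint_enforced(self):
        rng = np.random.default_rng(1)
        G = rng.normal(size=(40, 3))
        b = G @ np.array([1.0, 2.0, -1.0])   # unconstrained optimum has w1 > 0
        C = np.array([[0.0, 1.0, 0.0]])      # require w1 <= 0
        w = constrained_lstsq(G, b, C, np.zeros(1))
        assert w[1] <= 1e-8
        # solution is the constrained optimum: better than any feasible rival
        for trial in ([1.0, 0.0, -1.0], [0.5, -0.1, -0.9]):
            assert (np.linalg.norm(G @ w - b)
                    <= np.linalg.norm(G @ np.array(trial) - b) + 1e-10)

    def test_matches_scipy_qp_oracle(self):
        from scipy.optimize import lsq_linear, minimize
        rng = np.random.default_rng(2)
        G = rng.normal(size=(25, 5))
        b = rng.normal(size=25)
        C = rng.normal(size=(4, 5))
        d = np.zeros(4)
        w = constrained_lstsq(G, b, C, d)
        ref = minimize(lambda x: 0.5 * np.sum((G @ x - b) ** 2),
                       np.zeros(5), jac=lambda x: G.T @ (G @ x - b),
                       constraints=[{"type": "ineq", "fun": lambda x: d - C @ x}],
                       method="SLSQP", options={"maxiter": 200, "ftol": 1e-14})
        assert np.linalg.norm(G @ w - b) <= np.linalg.norm(G @ ref.x - b) + 1e-6


class TestMstlsAndSweep:
    def _library_constraints(self, library):
        return build_constraint_system(library, r_nf=0.02, r_ff=1.0, r_max=2.0)

    def test_zero_response_gives_zero_model(self, library):
        rng = np.random.default_rng(3)
        G = rng.normal(size=(50, 88))
        sys_ = make_system(G, np.zeros(50))
        w = mstls_solve(sys_, self._library_constraints(library), 0.01)
        assert np.all(w == 0.0)

    def test_manufactured_three_term_recovery(self, library):
        # noiseless data from 3 feasible library terms: exact support back
        rng = np.random.default_rng(4)
        cons = self._library_constraints(library)
        G = rng.normal(size=(300, 88))
        w_true = np.zeros(88)
        w_true[library.index_of("a-r", 0, 1)] = 3.0
        w_true[library.index_of("align", 1, 3)] = -4.0
        w_true[library.index_of("drag", 0, 1)] = -2.5
        b = G @ w_true
        sys_ = make_system(G, b)
        w, lam = lambda_sweep(sys_, cons, np.logspace(-4, 0, 40))
        assert set(np.flatnonzero(w)) == set(np.flatnonzero(w_true))
        assert np.linalg.norm(w - w_true) / np.linalg.norm(w_true) < 1e-3

    def test_feasibility_when_ls_violates(self, library):
        # data manufactured with a positive alignment coefficient: the
        # returned model must still satisfy the sign constraints
        rng = np.random.default_rng(5)
        cons = self._library_constraints(library)
        G = rng.normal(size=(300, 88))
        w_bad = np.zeros(88)
        w_bad[library.index_of("align", 0, 2)] = +2.0
        w_bad[library.index_of("drag", 0, 1)] = -1.0
        sys_ = make_system(G, G @ w_bad)
        w = mstls_solve(sys_, cons, 1e-3)
        assert cons.is_feasible(w, tol=1e-6)

    def test_single_lambda_grid(self, library):
        rng = np.random.default_rng(6)
        G = rng.normal(size=(100, 88))
        w_true = np.zeros(88)
        w_true[library.index_of("drag", 0, 1)] = -2.0
        sys_ = make_system(G, G @ w_true)
        cons = self._library_constraints(library)
        w1 = mstls_solve(sys_, cons, 0.01)
        w2, lam = lambda_sweep(sys_, cons, np.array([0.01]))
        assert lam == 0.01
        assert np.allclose(w1, w2)

    def test_pure_noise_returns_empty_model(self, library):
        # when no candidate beats the trivial relative residual of 1,
        # the sweep returns w = 0
        rng = np.random.default_rng(7)
        G = rng.normal(size=(300, 88))
        b = rng.normal(size=300)
        b -= G @ np.linalg.lstsq(G, b, rcond=None)[0]  # orthogonal to span
        sys_ = make_system(G, b)
        w, _ = lambda_sweep(sys_, self._library_constraints(library),
                            np.logspace(-4, 0, 10))
        assert np.all(w == 0.0)

    def test_random_feasible_models_support_recovery(self, library):
        # property: ten random constraint-feasible in-library models are
        # recovered exactly from noiseless synthetic systems
        rng = np.random.default_rng(8)
        cons = self._library_constraints(library)
        n_ok = 0
        for trial in range(10):
            w_true = np.zeros(88)
            # negative coefficients on align/drag are always feasible;
            # a-r uses the near-repulsive/far-attractive p_1 direction
            w_true[library.index_of("a-r", 0, 1)] = rng.uniform(1.0, 5.0)
            al = library.index_of("align", rng.integers(0, 3),
                                  int(rng.integers(0, 6)))
            w_true[al] = -rng.uniform(1.0, 6.0)
            dr = library.index_of("drag", int(rng.integers(0, 2)),
                                  int(rng.integers(0, 5)))
            w_true[dr] = -rng.uniform(0.5, 4.0)
            if not cons.is_feasible(w_true):
                continue
            G = rng.normal(size=(300, 88))
            sys_ = make_system(G, G @ w_true)
            w, _ = lambda_sweep(sys_, cons, np.logspace(-4, 0, 40))
            assert set(np.flatnonzero(w)) == set(np.flatnonzero(w_true))
            assert np.linalg.norm(w - w_true) / np.linalg.norm(w_true) < 1e-2
            n_ok += 1
        assert n_ok >= 8  # nearly all random draws are feasible
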