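"""Test functions, finite differences, weak-system assembly, r_nf."""

import numpy as np
import pytest

from cellswarm.library import ForceLibrary
from cellswarm.weakform import (assemble_weak_system, build_test_functions,
                                compute_near_field_radius,
                                finite_diff_velocity)


class TestFiniteDiffVelocity:
    def test_exact_for_affine(self):
        t = 0.05 * np.arange(10)
        x = np.stack([2.0 + 3.0 * t, -1.0 + 0.5 * t], axis=1)
        v = finite_diff_velocity(x, 0.05)
        assert np.allclose(v, [[3.0, 0.5]] * 10, atol=1e-12)

    def test_centred_exact_for_quadratic(self):
        t = 0.1 * np.arange(8)
        x = np.stack([t ** 2, t ** 2], axis=1)
        v = finite_diff_velocity(x, 0.1)
        assert np.allclose(v[1:-1], np.stack([2 * t, 2 * t], axis=1)[1:-1], atol=1e-12)

    def test_second_order_convergence(self):
        errs = []
        for dt in (0.02, 0.01):
            t = dt * np.arange(101)
            x = np.stack([np.sin(t), np.cos(t)], axis=1)
            v = finite_diff_velocity(x, dt)
            vt = np.stack([np.cos(t), -np.sin(t)], axis=1)
            errs.append(np.max(np.abs(v - vt)[1:-1]))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.2)

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            finite_diff_velocity(np.zeros((2, 2)), 0.1)


class TestTestFunctions:
    def test_count_and_interpolation_properties(self):
        basis = build_test_functions(200, 0.1, 35, 9)
        assert basis.n_test == 130  # Q = L - 2m
        q = 10
        k = int(round(basis.centers[q] / 0.1))
        assert basis.phi[q, k] == pytest.approx(1.0)
        assert basis.phi[q, k - 35] == 0.0
        assert basis.phi[q, k + 35] == 0.0

    def test_second_derivative_integrates_to_zero(self):
        basis = build_test_functions(150, 0.05, 31, 8)
        t = 0.05 * np.arange(150)
        for q in (0, 40, 87):
            # int phi'' = 0 and int phi'' t = 0 (by parts, compact support)
            assert np.trapezoid(basis.ddphi[q], t) == pytest.approx(0.0, abs=1e-8)
            assert np.trapezoid(basis.ddphi[q] * t, t) == pytest.approx(0.0, abs=1e-7)

    def test_analytic_second_derivative_matches_numerical(self):
        basis = build_test_functions(400, 0.01, 38, 9)
        t = 0.01 * np.arange(400)
        q = 100
        k = int(round(basis.centers[q] / 0.01))
        num = np.gradient(np.gradient(basis.phi[q], t), t)
        inner = slice(k - 25, k + 25)  # well inside the support
        # double np.gradient is itself only O(dt^2) accurate on these bumps
        assert np.allclose(basis.ddphi[q][inner], num[inner],
                           atol=2e-2 * np.max(np.abs(basis.ddphi[q])))

    def test_support_too_wide_rejected(self):
        with pytest.raises(ValueError):
            build_test_functions(60, 0.1, 31, 9)
        with pytest.raises(ValueError):
            build_test_functions(200, 0.1, 35, 2)


class TestWeakSystem:
    @pytest.mark.parametrize("m,p", [(31, 8), (35, 9), (38, 8), (38, 9)])
    def test_affine_trajectory_has_null_response(self, m, p):
        # <phi'', a + b t> = 0: force-free motion produces b ~ 0
        L, dt = 200, 0.05
        t = dt * np.arange(L)
        x = np.stack([1.0 + 2.0 * t, -0.3 + 0.1 * t], axis=1)
        basis = build_test_functions(L, dt, m, p)
        theta = np.ones((L, 2, 3))
        sys_ = assemble_weak_system(x, theta, basis, dt)
        assert sys_.b_norm <= 1e-8 * np.linalg.norm(x)

    def test_entry_matches_independent_quadrature(self, library):
        rng = np.random.default_rng(3)
        L, dt = 80, 0.1
        basis = build_test_functions(L, dt, 20, 9)
        theta = rng.normal(size=(L, 2, 5))
        x = rng.normal(size=(L, 2))
        sys_ = assemble_weak_system(x, theta, basis, dt)
        t = dt * np.arange(L)
        q, j, d = 7, 3, 1
        ref = np.trapezoid(basis.phi[q] * theta[:, d, j], t)
        assert sys_.G[q + d * basis.n_test, j] == pytest.approx(ref, rel=1e-12)
        refb = np.trapezoid(basis.ddphi[q] * x[:, d], t)
        assert sys_.b[q + d * basis.n_test] == pytest.approx(refb, rel=1e-12)

    def test_manufactured_single_column_recovery(self, library):
        # data whose acceleration equals 2.5 x one feature column
        L, dt = 240, 0.02
        t = dt * np.arange(L)
        c = 2.5
        # x'' = c * (sin t, cos t) with x(0) = 0, x'(0) chosen freely
        x = np.stack([-c * np.sin(t) + t, -c * np.cos(t)], axis=1)
        theta = np.zeros((L, 2, 4))
        theta[:, 0, 2] = np.sin(t)
        theta[:, 1, 2] = np.cos(t)
        theta[:, :, 0] = 1.0  # distractor column
        basis = build_test_functions(L, dt, 35, 9)
        sys_ = assemble_weak_system(x, theta, basis, dt)
        w, *_ = np.linalg.lstsq(sys_.G, sys_.b, rcond=None)
        assert w[2] == pytest.approx(c, abs=1e-3)


class TestNearFieldRadius:
    def test_degenerate_equal_distances(self):
        pos = np.zeros((2, 3, 2))
        pos[1, :, 0] = 0.7
        assert compute_near_field_radius(pos, 0.01) == pytest.approx(0.7)

    def test_quantile_of_uniform_cloud(self):
        rng = np.random.default_rng(0)
        # distances of a dense 1-D arrangement: empirical quantile sanity
        n = 400
        pos = np.zeros((n, 2, 2))
        pos[:, :, 0] = rng.uniform(0, 1, size=(n, 1))
        r = compute_near_field_radius(pos, 0.001)
        assert 0.0 < r < 0.02  # 0.1% quantile of |U - U'| is tiny

    def test_floor_is_min_distance(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(size=(6, 2, 2))
        from scipy.spatial.distance import pdist
        dmin = min(pdist(pos[:, k, :]).min() for k in range(2))
        assert compute_near_field_radius(pos, 1e-6) == pytest.approx(dmin)

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            compute_near_field_radius(np.zeros((3, 2, 2)), 1.5)
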