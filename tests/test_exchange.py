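"""Cell statistics, KL divergences, validation neighbourhoods, replacement."""

import numpy as np
import pytest

from cellswarm.exchange import (compute_population_statistics, kl_cost_matrix,
                                kl_divergence, replacement_pass,
                                select_validation_cells)


class FakeModel:
    def __init__(self, name, focal):
        self.name = name
        self.focal = focal
        self.provenance = "learned"

    def copy_as_replacement(self, target):
        m = FakeModel(self.name, target)
        m.provenance = f"replaced_from:{self.focal}"
        return m


class TestStatistics:
    def test_constant_distance_pair(self):
        pos = np.zeros((2, 4, 2))
        pos[1, :, 0] = 0.7
        vel = np.zeros((2, 4, 2))
        vel[0, :, 0] = 0.1  # keep speeds nonzero for a meaningful edge set
        stats = compute_population_statistics(pos, vel)
        k = np.argmax(stats[0].rho_rr)
        assert stats[0].edges_rr[k] <= 0.7 <= stats[0].edges_rr[k + 1] + 1e-12
        assert stats[0].rho_rr[k] == pytest.approx(1.0)

    def test_stationary_cell_speed_mass_in_first_bin(self):
        rng = np.random.default_rng(0)
        pos = rng.normal(size=(3, 5, 2))
        vel = rng.normal(size=(3, 5, 2))
        vel[2] = 0.0
        stats = compute_population_statistics(pos, vel)
        assert stats[2].rho_v[0] == pytest.approx(1.0)

    def test_histograms_normalized(self):
        rng = np.random.default_rng(1)
        pos = rng.normal(size=(6, 8, 2))
        vel = rng.normal(size=(6, 8, 2))
        for s in compute_population_statistics(pos, vel):
            for h in (s.rho_rr, s.rho_vv, s.rho_v):
                assert h.sum() == pytest.approx(1.0, abs=1e-12)
                assert np.all(h >= 0)


class TestKL:
    def test_identical_histograms_zero(self):
        rho = np.array([0.2, 0.3, 0.5])
        assert kl_divergence(rho, rho) == pytest.approx(0.0, abs=1e-8)

    def test_hand_computed_value(self):
        rho = np.array([0.5, 0.5])
        nu = np.array([0.9, 0.1])
        expect = 0.5 * np.log(0.5 / 0.9) + 0.5 * np.log(0.5 / 0.1)
        assert kl_divergence(rho, nu) == pytest.approx(expect, abs=1e-8)
        assert expect == pytest.approx(0.5108, abs=5e-4)

    def test_asymmetry(self):
        rho = np.array([0.5, 0.5])
        nu = np.array([0.9, 0.1])
        assert kl_divergence(rho, nu) != pytest.approx(kl_divergence(nu, rho))

    def test_mismatched_edges_rejected(self):
        with pytest.raises(ValueError):
            kl_divergence(np.array([1.0]), np.array([1.0]),
                          edges_rho=np.array([0.0, 1.0]),
                          edges_nu=np.array([0.0, 2.0]))


class TestValidationCells:
    def test_all_identical_tie_break_by_id(self):
        costs = np.zeros(6)
        assert list(select_validation_cells(2, costs, 3)) == [0, 1, 3]

    def test_k_clamped(self):
        costs = np.arange(4.0)
        assert len(select_validation_cells(0, costs, 99)) == 3

    def test_matches_brute_force_ranking(self):
        rng = np.random.default_rng(2)
        costs = rng.uniform(size=20)
        got = list(select_validation_cells(7, costs, 5))
        ref = sorted((j for j in range(20) if j != 7),
                     key=lambda j: (costs[j], j))[:5]
        assert got == ref

    def test_cost_matrix_diagonal_zero_and_nonneg(self):
        rng = np.random.default_rng(3)
        pos = rng.normal(size=(5, 10, 2))
        vel = rng.normal(size=(5, 10, 2))
        stats = compute_population_statistics(pos, vel)
        cost = kl_cost_matrix(stats)
        assert np.allclose(np.diag(cost), 0.0, atol=1e-10)
        assert np.all(cost >= -1e-12)


class TestReplacementPass:
    def _uniform_costs(self, n):
        # all cells mutually similar: validation sets are the K lowest ids
        return np.zeros((n, n))

    def test_identical_models_no_replacement(self):
        n = 5
        models = [FakeModel("m", i) for i in range(n)]
        dv = {(i, j): 0.1 for i in range(n) for j in range(n)}
        new, log = replacement_pass(models, self._uniform_costs(n),
                                    lambda m, c, cap: 0.1, K=4, tol=0.25)
        assert log == []
        assert all(new[i] is models[i] for i in range(n))

    def test_constructed_pair_replaces(self):
        # dV(i->i)=0.5, dV(j->i)=0.1, dV(i->j)=0.5, dV(j->j)=0.1, tol=0.25
        models = [FakeModel("m0", 0), FakeModel("m1", 1)]
        table = {("m0", 0): 0.5, ("m1", 0): 0.1, ("m0", 1): 0.5, ("m1", 1): 0.1}
        new, log = replacement_pass(models, self._uniform_costs(2),
                                    lambda m, c, cap: table[(m.name, c)],
                                    K=1, tol=0.25)
        assert new[0].name == "m1"
        assert new[0].provenance == "replaced_from:1"
        assert new[1].name == "m1"
        assert log[0]["cell_id"] == 0
        assert log[0]["dV_after"] <= log[0]["dV_before"]

    def test_condition_tol_blocks_replacement(self):
        models = [FakeModel("m0", 0), FakeModel("m1", 1)]
        table = {("m0", 0): 0.9, ("m1", 0): 0.4, ("m0", 1): 0.9, ("m1", 1): 0.3}
        new, log = replacement_pass(models, self._uniform_costs(2),
                                    lambda m, c, cap: table[(m.name, c)],
                                    K=1, tol=0.25)
        assert log == []  # max(dV_{j->i}, dV_{j->j}) = 0.4 >= tol

    def test_chain_transitive_closure(self):
        # k -> j -> i: cell i must end with model k
        models = [FakeModel(f"m{i}", i) for i in range(3)]
        dv = {
            ("m0", 0): 0.20, ("m1", 0): 0.10, ("m2", 0): 0.28,
            ("m0", 1): 0.30, ("m1", 1): 0.20, ("m2", 1): 0.05,
            ("m0", 2): 0.30, ("m1", 2): 0.30, ("m2", 2): 0.01,
        }
        new, log = replacement_pass(models, self._uniform_costs(3),
                                    lambda m, c, cap: dv[(m.name, c)],
                                    K=2, tol=0.25)
        assert new[0].name == "m2"   # via the chain 2 -> 1 -> 0
        assert new[1].name == "m2"

    def test_idempotent_on_stable_table(self):
        models = [FakeModel("m0", 0), FakeModel("m1", 1), FakeModel("m2", 2)]
        table = {("m0", c): 0.01 for c in range(3)}
        table.update({("m1", c): 0.02 for c in range(3)})
        table.update({("m2", c): 0.03 for c in range(3)})
        v = lambda m, c, cap: table[(m.name, c)]
        costs = self._uniform_costs(3)
        new1, log1 = replacement_pass(models, costs, v, K=2, tol=0.25)
        new2, log2 = replacement_pass(new1, costs, v, K=2, tol=0.25)
        assert [m.name for m in new1] == [m.name for m in new2]
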