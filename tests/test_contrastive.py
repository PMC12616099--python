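"""Adaptive-neighbourhood contrastive loss: oracles, invariants, gradients."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mechage as mg
from mechage.contrastive import adaptnn_loss_and_grad


def triple_loop_loss(V, ages, epoch, kcfg, schedule):
    """Scalar reference implementation, written independently of the
    vectorised path: explicit loops over i, k and the neighbourhood."""
    n = len(ages)
    W = [[math.exp(-((ages[i] - ages[k]) ** 2)
                   / (2 * kcfg.bandwidth_sigma ** 2)) for k in range(n)]
         for i in range(n)]
    if kcfg.similarity == "cosine":
        U = [v / np.linalg.norm(v) for v in V]
    else:
        U = list(V)
    S = [[float(np.dot(U[i], U[k])) / kcfg.temperature_tau for k in range(n)]
         for i in range(n)]
    nn = mg.select_neighbourhoods(ages, epoch, schedule)
    total = 0.0
    for i in range(n):
        wsum = sum(W[i][t] for t in range(n) if t != i)
        for k in range(n):
            if k == i:
                continue
            Z = sum(math.exp(S[i][t] * (1 - W[i][t])) for t in nn[i])
            total -= W[i][k] / wsum * math.log(math.exp(S[i][k]) / Z)
    return total


class TestAgeKernel:
    def test_equal_ages_give_unit_weights(self):
        W = mg.age_kernel_matrix(np.full(4, 33.0), mg.KernelConfig())
        assert np.allclose(W, 1.0)

    def test_half_weight_at_half_width(self):
        sigma = 2.0
        ages = np.array([20.0, 20.0 + sigma * math.sqrt(2 * math.log(2))])
        W = mg.age_kernel_matrix(ages, mg.KernelConfig(bandwidth_sigma=sigma))
        assert W[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_matches_scalar_evaluation(self):
        ages = np.array([20.0, 25.0, 80.0])
        kcfg = mg.KernelConfig(bandwidth_sigma=5.0)
        W = mg.age_kernel_matrix(ages, kcfg)
        for i in range(3):
            for k in range(3):
                expect = math.exp(-((ages[i] - ages[k]) ** 2) / (2 * 25.0))
                assert W[i, k] == pytest.approx(expect, abs=1e-12)

    def test_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(14, 90, 20)
        W = mg.age_kernel_matrix(ages, mg.KernelConfig())
        assert np.allclose(W, W.T)
        assert np.allclose(np.diag(W), 1.0)
        assert np.all((W > 0) & (W <= 1))

    def test_nonfinite_ages_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            mg.age_kernel_matrix(np.array([20.0, np.nan]), mg.KernelConfig())


class TestSimilarity:
    def test_identical_unit_vectors(self):
        V = np.array([[1.0, 0.0], [1.0, 0.0]])
        S = mg.similarity_matrix(V, mg.KernelConfig(temperature_tau=0.1))
        assert S[0, 1] == pytest.approx(10.0)

    def test_orthogonal_vectors(self):
        V = np.array([[1.0, 0.0], [0.0, 1.0]])
        S = mg.similarity_matrix(V, mg.KernelConfig())
        assert S[0, 1] == pytest.approx(0.0)

    def test_matches_pairwise_loop(self):
        rng = np.random.default_rng(1)
        V = rng.normal(size=(5, 3))
        kcfg = mg.KernelConfig(temperature_tau=0.3)
        S = mg.similarity_matrix(V, kcfg)
        U = V / np.linalg.norm(V, axis=1, keepdims=True)
        for i in range(5):
            for k in range(5):
                assert S[i, k] == pytest.approx(np.dot(U[i], U[k]) / 0.3,
                                                abs=1e-9)

    def test_zero_norm_rejected_under_cosine(self):
        V = np.array([[0.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="zero-norm"):
            mg.similarity_matrix(V, mg.KernelConfig())


class TestNeighbourhoods:
    def test_first_epoch_keeps_everyone(self):
        ages = np.arange(6, dtype=float)
        sch = mg.NeighbourhoodSchedule(total_epochs=10)
        sets = mg.select_neighbourhoods(ages, 0, sch)
        assert all(len(s) == 5 for s in sets)

    def test_final_epoch_ceiling_size(self):
        ages = np.arange(9, dtype=float)
        sch = mg.NeighbourhoodSchedule(total_epochs=10, rho_end=0.25)
        sets = mg.select_neighbourhoods(ages, 9, sch)
        assert all(len(s) == 2 for s in sets)  # ceil(0.25 * 8)

    def test_age_nearest_retained(self):
        ages = np.array([10.0, 11.0, 50.0])
        sch = mg.NeighbourhoodSchedule(total_epochs=3, rho_start=0.5,
                                       rho_end=0.5)
        sets = mg.select_neighbourhoods(ages, 1, sch)  # keep ceil(0.5*2)=1
        assert list(sets[0]) == [1]
        assert list(sets[2]) == [1]  # 50 is nearer to 11 than to 10

    def test_sizes_monotone_nonincreasing_over_epochs(self):
        rng = np.random.default_rng(2)
        ages = rng.uniform(14, 90, 13)
        sch = mg.NeighbourhoodSchedule(total_epochs=8)
        sizes = [len(mg.select_neighbourhoods(ages, e, sch)[0])
                 for e in range(8)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestAdaptNNLoss:
    KC = mg.KernelConfig()
    SCH = mg.NeighbourhoodSchedule(total_epochs=10)

    def test_two_samples_equal_age_orthogonal_embeddings_zero_loss(self):
        """w=1 kills the denominator exponent and s=0 the numerator: ratio 1."""
        V = np.array([[1.0, 0.0], [0.0, 1.0]])
        loss = mg.adaptnn_loss(V, np.array([40.0, 40.0]), 0, self.KC, self.SCH)
        assert loss == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 17))
        D = int(rng.integers(2, 9))
        V = rng.normal(size=(n, D))
        ages = rng.uniform(14, 90, n)
        epoch = int(rng.integers(0, 10))
        expect = triple_loop_loss(V, ages, epoch, self.KC, self.SCH)
        got = mg.adaptnn_loss(V, ages, epoch, self.KC, self.SCH)
        assert got == pytest.approx(expect, abs=1e-6)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        V = rng.normal(size=(8, 4))
        ages = rng.uniform(14, 90, 8)
        perm = rng.permutation(8)
        a = mg.adaptnn_loss(V, ages, 2, self.KC, self.SCH)
        b = mg.adaptnn_loss(V[perm], ages[perm], 2, self.KC, self.SCH)
        assert a == pytest.approx(b, abs=1e-9)

    @pytest.mark.parametrize("similarity", ["cosine", "dot"])
    def test_gradient_matches_finite_differences(self, similarity):
        rng = np.random.default_rng(4)
        kcfg = mg.KernelConfig(similarity=similarity)
        V = rng.normal(size=(6, 3))
        ages = rng.uniform(14, 90, 6)
        loss, grad = adaptnn_loss_and_grad(V, ages, 1, kcfg, self.SCH)
        eps = 1e-6
        for idx in [(0, 0), (2, 1), (5, 2)]:
            Vp, Vm = V.copy(), V.copy()
            Vp[idx] += eps
            Vm[idx] -= eps
            fd = (mg.adaptnn_loss(Vp, ages, 1, kcfg, self.SCH)
                  - mg.adaptnn_loss(Vm, ages, 1, kcfg, self.SCH)) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 5, 7])
    def test_descent_orders_embeddings_by_age(self, seed):
        """Gradient descent on free 2D embeddings realises the qualitative
        contract that similar ages end up closer together: pairwise embedding
        distances rank-correlate with pairwise age differences. The kernel
        bandwidth is set to the order of the age spacing in the batch so
        that attraction is graded over the whole range."""
        from scipy.spatial.distance import pdist
        from scipy.stats import spearmanr
        n = 16
        V = np.random.default_rng(seed).normal(size=(n, 2))
        ages = np.linspace(14, 90, n)
        sch = mg.NeighbourhoodSchedule(total_epochs=200)
        kcfg = mg.KernelConfig(bandwidth_sigma=10.0)
        for step in range(200):
            _, g = adaptnn_loss_and_grad(V, ages, step, kcfg, sch)
            V -= 0.05 * g
        U = V / np.linalg.norm(V, axis=1, keepdims=True)
        rho = spearmanr(pdist(ages[:, None]), pdist(U)).statistic
        assert rho > 0.9
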