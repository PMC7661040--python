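"""Signed adjacency, topological overlap, consensus calibration, tree cut,
eigengenes, and kME pruning."""

import numpy as np
import pandas as pd
import pytest

import methclock as mc
from methclock.network import (GREY, NetworkConfig, consensus_tom, cut_modules,
                               kme_prune, module_eigengene, signed_adjacency, tom)

from conftest import toy_matrix


def tom_oracle(A):
    """Triple-loop re-statement of the topological overlap formula."""
    A = np.asarray(A, float).copy()
    np.fill_diagonal(A, 0.0)
    n = A.shape[0]
    W = np.eye(n)
    k = A.sum(axis=1)
    for i in range(n):
        for j in range(i + 1, n):
            l_ij = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            w = (l_ij + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
            W[i, j] = W[j, i] = w
    return W


def _matrix_with_cor(cor_pattern):
    """3-sample matrix whose site pairs have exactly the requested cors."""
    x = np.array([1.0, 0.0, -1.0])
    y = np.array([1.0, -2.0, 1.0])  # orthogonal to x
    rows = {"x": x, "negx": -x, "y": y}
    return np.vstack([rows[name] for name in cor_pattern])


class TestSignedAdjacency:
    def test_correlation_endpoints(self):
        V = _matrix_with_cor(["x", "x", "negx", "y"])
        A = signed_adjacency(V, power=1.0)
        assert A[0, 1] == pytest.approx(1.0)     # cor +1
        assert A[0, 2] == pytest.approx(0.0)     # cor -1
        assert A[0, 3] == pytest.approx(0.5)     # cor 0

    def test_power_two_arithmetic(self):
        # cor exactly 0.5 between [1,0,-1,0] and its quarter-phase shift
        a = np.array([1.0, 1.0, -1.0, -1.0])
        b = np.array([1.0, -1.0, -1.0, 1.0])
        V = np.vstack([a, (a + b) / np.sqrt(2)])
        A = signed_adjacency(V, power=2.0)
        cor = np.corrcoef(V)[0, 1]
        assert cor == pytest.approx(np.sqrt(0.5))
        assert A[0, 1] == pytest.approx(((1 + cor) / 2) ** 2)

    def test_full_grid_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        V = rng.uniform(size=(5, 12))
        A = signed_adjacency(V, power=1.0)
        C = np.corrcoef(V)
        np.testing.assert_allclose(A, (1 + C) / 2, atol=1e-12)

    def test_constant_cpg_zeroed(self):
        V = np.vstack([np.full(6, 0.5), np.random.default_rng(1).uniform(size=6)])
        A = signed_adjacency(V)
        assert A[0, 1] == pytest.approx(0.5)  # cor treated as 0
        assert A[0, 0] == 1.0

    def test_bicor_option_matches_pairwise_bicor(self):
        rng = np.random.default_rng(2)
        V = rng.uniform(size=(4, 15))
        A = signed_adjacency(V, corr_method="bicor")
        for i in range(4):
            for j in range(i + 1, 4):
                expected = (1 + mc.bicor(V[i], V[j])) / 2
                assert A[i, j] == pytest.approx(expected, abs=1e-10)


class TestTOM:
    def test_complete_graph_is_all_ones(self):
        A = np.ones((5, 5))
        np.testing.assert_allclose(tom(A), np.ones((5, 5)), atol=1e-12)

    def test_three_node_hand_value(self):
        A = np.full((3, 3), 0.5)
        np.fill_diagonal(A, 1.0)
        W = tom(A)
        # l = 0.25, k = 1 -> (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
        assert W[0, 1] == pytest.approx(0.5)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(3)
        for n in (6, 8, 10):
            A = rng.uniform(size=(n, n))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 1.0)
            np.testing.assert_allclose(tom(A), tom_oracle(A), atol=1e-12)

    def test_oracle_equivalence_many_draws(self):
        """Property: TOM equals the exhaustive oracle on random instances."""
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = int(rng.integers(6, 11))
            A = rng.uniform(size=(n, n))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 1.0)
            np.testing.assert_allclose(tom(A), tom_oracle(A), atol=1e-12)

    def test_asymmetric_adjacency_rejected(self):
        A = np.ones((3, 3)); A[0, 1] = 0.2
        with pytest.raises(ValueError, match="symmetric"):
            tom(A)


class TestConsensusTOM:
    def test_identical_inputs_idempotent(self):
        rng = np.random.default_rng(5)
        T = rng.uniform(size=(6, 6)); T = (T + T.T) / 2; np.fill_diagonal(T, 1)
        np.testing.assert_allclose(consensus_tom([T, T]), T, atol=1e-12)

    def test_zero_matrix_dominates(self):
        rng = np.random.default_rng(6)
        T = rng.uniform(0.2, 0.9, size=(5, 5)); T = (T + T.T) / 2
        np.fill_diagonal(T, 1)
        Z = np.eye(5)
        cons = consensus_tom([T, Z])
        off = ~np.eye(5, dtype=bool)
        assert np.all(cons[off] == 0)

    def test_matches_quantile_scale_then_min_oracle(self):
        rng = np.random.default_rng(7)
        def rand_tom(n):
            T = rng.uniform(size=(n, n)); T = (T + T.T) / 2
            np.fill_diagonal(T, 1)
            return T
        A, B = rand_tom(8), rand_tom(8)
        q = 0.95
        off = ~np.eye(8, dtype=bool)
        factor = np.quantile(A[off], q) / np.quantile(B[off], q)
        expected = np.minimum(A, np.clip(B * factor, None, None))
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(consensus_tom([A, B], q),
                                   np.clip(expected, 0, 1), atol=1e-12)

    def test_commutative_after_common_reference(self):
        # calibrating both inputs to a fixed first reference makes the
        # operation order-free in the remaining arguments
        rng = np.random.default_rng(8)
        def rand_tom(n):
            T = rng.uniform(size=(n, n)); T = (T + T.T) / 2
            np.fill_diagonal(T, 1)
            return T
        R, A, B = rand_tom(7), rand_tom(7), rand_tom(7)
        np.testing.assert_allclose(consensus_tom([R, A, B]),
                                   consensus_tom([R, B, A]), atol=1e-12)

    def test_site_mismatch_rejected(self):
        with pytest.raises(ValueError):
            consensus_tom([np.eye(4), np.eye(5)])


def _planted_blocks(rng, block_sizes, n_noise, n_samples, within_cor=0.9):
    """Sites x samples matrix with independent correlated blocks + noise."""
    rows = []
    sigma = 0.05
    s = sigma * np.sqrt(within_cor / (1 - within_cor))
    for size in block_sizes:
        latent = rng.normal(size=n_samples)
        block = 0.5 + s * latent[None, :] + rng.normal(0, sigma, (size, n_samples))
        rows.append(block)
    rows.append(0.5 + rng.normal(0, sigma, (n_noise, n_samples)))
    return np.clip(np.vstack(rows), 0, 1)


class TestCutModules:
    def test_two_planted_blocks_recovered_exactly(self):
        rng = np.random.default_rng(9)
        V = _planted_blocks(rng, [30, 30], 140, 50)
        W = tom(signed_adjacency(V))
        labels = cut_modules(W, NetworkConfig())
        first, second = labels.iloc[:30], labels.iloc[30:60]
        assert first.nunique() == 1 and first.iloc[0] != GREY
        assert second.nunique() == 1 and second.iloc[0] != GREY
        assert first.iloc[0] != second.iloc[0]
        assert (labels.iloc[60:] == GREY).mean() > 0.95

    def test_undersized_block_stays_grey(self):
        rng = np.random.default_rng(10)
        V = _planted_blocks(rng, [10], 120, 40)
        W = tom(signed_adjacency(V))
        labels = cut_modules(W, NetworkConfig(min_module_size=25))
        assert (labels == GREY).all()

    def test_planted_recovery_across_seeds(self):
        """Adjusted Rand >= 0.9 between detected and planted modules."""
        from sklearn.metrics import adjusted_rand_score
        for seed in range(5):
            rng = np.random.default_rng(seed)
            V = _planted_blocks(rng, [30, 28], 150, 60)
            W = tom(signed_adjacency(V))
            labels = cut_modules(W, NetworkConfig())
            truth = np.array(["a"] * 30 + ["b"] * 28 + [GREY] * 150)
            ari = adjusted_rand_score(truth, labels.to_numpy())
            assert ari >= 0.9, f"seed {seed}: ARI {ari:.3f}"

    def test_too_few_sites_error(self):
        with pytest.raises(ValueError):
            cut_modules(np.eye(10), NetworkConfig(min_module_size=25))


class TestEigengene:
    def _labelled(self, V, sizes):
        m = toy_matrix(V)
        labels = pd.Series(GREY, index=m.site_ids, dtype=object)
        start = 0
        for name, size in sizes.items():
            labels.iloc[start:start + size] = name
            start += size
        return m, labels

    def test_identical_members_have_kme_one(self):
        row = np.random.default_rng(11).uniform(size=10)
        V = np.vstack([row, row, row, np.random.default_rng(12).uniform(size=10)])
        m, labels = self._labelled(V, {"mod": 3})
        eg = module_eigengene(m, labels, "mod")
        np.testing.assert_allclose(eg.kme.iloc[:3], 1.0, atol=1e-10)
        assert eg.scores.mean() == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_pair_opposite_kme(self):
        row = np.linspace(0.1, 0.9, 8)
        V = np.vstack([row, 1 - row])
        m, labels = self._labelled(V, {"mod": 2})
        eg = module_eigengene(m, labels, "mod")
        assert abs(eg.kme.iloc[0]) == pytest.approx(1.0, abs=1e-10)
        assert eg.kme.iloc[0] == pytest.approx(-eg.kme.iloc[1], abs=1e-10)

    def test_matches_dense_eigensolver_up_to_sign(self):
        rng = np.random.default_rng(13)
        latent = rng.normal(size=15)
        V = np.clip(0.5 + 0.15 * latent[None, :] +
                    rng.normal(0, 0.05, (20, 15)), 0, 1)
        m, labels = self._labelled(V, {"mod": 20})
        eg = module_eigengene(m, labels, "mod")
        centred = V - V.mean(axis=1, keepdims=True)
        evals, evecs = np.linalg.eigh(centred.T @ centred)
        pc1 = evecs[:, -1]
        pc1 -= pc1.mean()
        cor = np.corrcoef(eg.scores, pc1)[0, 1]
        assert abs(cor) == pytest.approx(1.0, abs=1e-8)


class TestKMEPrune:
    def test_strong_module_unchanged(self):
        rng = np.random.default_rng(14)
        latent = rng.normal(size=12)
        V = np.clip(0.5 + 0.2 * latent[None, :] + rng.normal(0, 0.04, (30, 12)), 0, 1)
        m = toy_matrix(V)
        labels = pd.Series("mod", index=m.site_ids, dtype=object)
        pruned = kme_prune(m, labels, NetworkConfig(min_kme=0.4))
        assert (pruned == "mod").all()

    def test_planted_outlier_moved_to_grey(self):
        rng = np.random.default_rng(15)
        latent = rng.normal(size=12)
        V = np.clip(0.5 + 0.2 * latent[None, :] + rng.normal(0, 0.04, (30, 12)), 0, 1)
        V[7] = rng.uniform(size=12)  # uncorrelated impostor inside the block
        m = toy_matrix(V)
        labels = pd.Series("mod", index=m.site_ids, dtype=object)
        pruned = kme_prune(m, labels, NetworkConfig(min_kme=0.4))
        assert pruned.iloc[7] == GREY
        assert (pruned.drop(pruned.index[7]) == "mod").all()

    def test_module_dissolved_below_min_size(self):
        rng = np.random.default_rng(16)
        latent = rng.normal(size=12)
        V = np.clip(0.5 + 0.2 * latent[None, :] + rng.normal(0, 0.04, (26, 12)), 0, 1)
        V[24] = rng.uniform(size=12)
        V[25] = rng.uniform(size=12)
        m = toy_matrix(V)
        labels = pd.Series("mod", index=m.site_ids, dtype=object)
        pruned = kme_prune(m, labels, NetworkConfig(min_kme=0.4, min_module_size=25))
        assert (pruned == GREY).all()   # 26 -> 24 members -> dissolved

    def test_consensus_uses_minimum_across_datasets(self):
        rng = np.random.default_rng(17)
        latent = rng.normal(size=12)
        V1 = np.clip(0.5 + 0.2 * latent[None, :] + rng.normal(0, 0.04, (30, 12)), 0, 1)
        V2 = np.clip(0.5 + rng.normal(0, 0.1, (30, 12)), 0, 1)  # no shared latent
        m1, m2 = toy_matrix(V1), toy_matrix(V2)
        labels = pd.Series("mod", index=m1.site_ids, dtype=object)
        pruned = kme_prune([m1, m2], labels, NetworkConfig(min_kme=0.4))
        assert (pruned == GREY).all()


class TestModuleClock:
    def test_module_of_all_sites_equals_global_clock(self, rat_matrix, sample_frames):
        rats, _ = sample_frames
        plan = mc.split_by_age(rats)
        ages = rats.set_index("sample_id")["age_months"]
        labels = pd.Series("all", index=rat_matrix.site_ids, dtype=object)
        modular = mc.module_clock(rat_matrix, plan.train_ids,
                                  ages[list(plan.train_ids)].to_numpy(),
                                  labels, "all")
        train = rat_matrix.subset_samples(list(plan.train_ids))
        global_clock = mc.fit_pc_clock(train.X, ages[list(plan.train_ids)].to_numpy(),
                                       sites=train.site_ids)
        test = rat_matrix.subset_samples(list(plan.test_ids))
        np.testing.assert_allclose(mc.predict_age(modular, test),
                                   mc.predict_age(global_clock, test), atol=1e-8)

    def test_permuted_ages_give_null_correlations(self):
        """Module clock on permuted training ages: bicor centred at zero."""
        rng = np.random.default_rng(18)
        latent = rng.normal(size=40)
        V = np.clip(0.5 + 0.15 * latent[None, :] + rng.normal(0, 0.05, (30, 40)), 0, 1)
        m = toy_matrix(V)
        labels = pd.Series("mod", index=m.site_ids, dtype=object)
        ages = np.linspace(1, 27, 40)
        train_ids = m.samples[:30]
        test = m.subset_samples(m.samples[30:])
        cors = []
        for _ in range(50):
            perm = rng.permutation(ages[:30])
            clock = mc.module_clock(m, train_ids, perm, labels, "mod")
            cors.append(mc.bicor(mc.predict_age(clock, test).to_numpy(), ages[30:]))
        assert abs(np.mean(cors)) < 0.15
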