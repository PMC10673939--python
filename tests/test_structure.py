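"""PCA, cluster inference, Weir-Cockerham Fst and AMOVA."""

import numpy as np
import pandas as pd
import pytest

from landgea import structure, synthdata
from landgea.structure import PCAResult
from conftest import toy_matrix


class TestGenotypePCA:
    def test_rank_one_structure_on_pc1(self):
        # two antipodal groups replicated across loci -> PC1 separates them
        rng = np.random.default_rng(0)
        block = np.repeat([[0.0], [2.0]], [15, 15], axis=0)
        d = np.tile(block, (1, 80))
        flip = rng.random(d.shape) < 0.02  # break exact degeneracy
        d[flip] = 1.0
        pca = structure.genotype_pca(toy_matrix(d), scaling="unit")
        labels = (np.arange(30) >= 15).astype(int)
        side = np.sign(pca.scores[:, 0])
        assert len(set(side[labels == 0])) == 1
        assert len(set(side[labels == 1])) == 1
        assert pca.explained_fraction[0] > 0.9

    def test_deterministic_up_to_sign(self, small_dataset):
        _, g, _, _ = small_dataset
        from landgea.genio import impute_modal

        gi = impute_modal(g)
        a = structure.genotype_pca(gi)
        b = structure.genotype_pca(gi)
        np.testing.assert_allclose(a.scores, b.scores)

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, (10, 20)).astype(float)
        d[:, d.std(axis=0) == 0] += rng.integers(0, 2, 10)[:, None]
        pca = structure.genotype_pca(toy_matrix(d), scaling="patterson")
        # independent oracle: eigendecomposition of the standardized covariance
        p = d.mean(axis=0) / 2
        keep = (p > 0) & (p < 1)
        X = (d[:, keep] - 2 * p[keep]) / np.sqrt(p[keep] * (1 - p[keep]))
        C = X @ X.T
        w, v = np.linalg.eigh(C)
        w, v = w[::-1], v[:, ::-1]
        k = min(pca.scores.shape[1], np.sum(w > 1e-9))
        for i in range(k):
            got = pca.scores[:, i]
            exp = v[:, i] * np.sqrt(w[i])
            assert min(
                np.abs(got - exp).max(), np.abs(got + exp).max()
            ) < 1e-10
        np.testing.assert_allclose(
            pca.explained_fraction[:k], w[:k] / w.sum(), atol=1e-10
        )

    def test_explained_fractions_non_increasing_and_sum_le_one(self, small_dataset):
        _, g, _, _ = small_dataset
        from landgea.genio import impute_modal

        pca = structure.genotype_pca(impute_modal(g))
        ef = pca.explained_fraction
        assert np.all(np.diff(ef) <= 1e-12)
        assert ef.sum() <= 1 + 1e-9
        # loadings columns orthonormal
        L = pca.loadings
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)


class TestInferClusters:
    def test_two_separated_blobs_give_k2(self):
        rng = np.random.default_rng(1)
        X = np.vstack(
            [rng.normal(0, 1, (50, 2)), rng.normal([10, 0], 1, (50, 2))]
        )
        pca = PCAResult(scores=X, loadings=np.eye(2), explained_fraction=np.array([0.5, 0.5]))
        ca = structure.infer_clusters(pca, k_max=6, n_axes=2, seed=0)
        assert ca.k == 2
        labels = ca.labels
        assert len(set(labels[:50])) == 1 and len(set(labels[50:])) == 1

    def test_k1_forced_gives_identical_labels(self):
        rng = np.random.default_rng(2)
        pca = PCAResult(
            scores=rng.normal(size=(30, 3)), loadings=np.eye(3),
            explained_fraction=np.ones(3) / 3,
        )
        ca = structure.infer_clusters(pca, k_max=1, n_axes=3, seed=0)
        assert ca.k == 1 and len(set(ca.labels)) == 1

    def test_bic_vector_covers_scanned_range(self):
        rng = np.random.default_rng(3)
        pca = PCAResult(
            scores=rng.normal(size=(40, 4)), loadings=np.eye(4),
            explained_fraction=np.ones(4) / 4,
        )
        ca = structure.infer_clusters(pca, k_max=5, n_axes=4, seed=0)
        assert len(ca.bic) == 5

    def test_k_max_too_large_raises(self):
        pca = PCAResult(
            scores=np.zeros((5, 2)), loadings=np.eye(2),
            explained_fraction=np.array([0.5, 0.5]),
        )
        with pytest.raises(ValueError):
            structure.infer_clusters(pca, k_max=5, n_axes=2)

    def test_four_group_fixture_recovers_k4(self, recovery_fixture):
        ca = structure.infer_clusters(recovery_fixture["pca"], k_max=8, seed=0)
        assert ca.k == 4
        # labels agree with the simulated groups up to relabeling
        truth_groups = recovery_fixture["env"]["group"].to_numpy()
        tab = pd.crosstab(truth_groups, ca.labels)
        assert (tab.max(axis=1) / tab.sum(axis=1)).min() > 0.95


def _wc_hand_oracle(d1, d2):
    """Direct per-locus evaluation of the Weir-Cockerham a, b, c components,
    written independently with explicit scalar loops."""
    import math

    L = d1.shape[1]
    a_sum = bc_sum = 0.0
    for l in range(L):
        x1, x2 = d1[:, l], d2[:, l]
        n1, n2 = len(x1), len(x2)
        p1, p2 = x1.sum() / (2 * n1), x2.sum() / (2 * n2)
        h1 = np.mean(x1 == 1)
        h2 = np.mean(x2 == 1)
        r = 2
        nbar = (n1 + n2) / 2
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 / 2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_sum += a
        bc_sum += a + b + c
    return a_sum / bc_sum


class TestPairwiseFst:
    def test_identical_frequencies_give_near_zero(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.2, 0.8, 500)
        d = np.vstack([
            2.0 * (rng.random((20, 500)) < p),
            2.0 * (rng.random((20, 500)) < p),
        ])
        g = toy_matrix(d)
        labels = np.repeat([0, 1], 20)
        theta = structure.weir_cockerham_fst(g, labels, 0, 1)
        assert abs(theta) < 0.02

    def test_fixed_difference_gives_one(self):
        d = np.vstack([np.zeros((10, 5)), np.full((10, 5), 2.0)])
        g = toy_matrix(d)
        theta = structure.weir_cockerham_fst(g, np.repeat([0, 1], 10), 0, 1)
        assert theta == pytest.approx(1.0)

    def test_matches_hand_component_oracle(self):
        # two pops of 10, three loci at frequencies {0.2,0.8},{0.5,0.5},{0.1,0.9}
        def pop(freqs, n=10):
            cols = []
            for f in freqs:
                n_alt = int(round(f * 2 * n))
                calls = [2] * (n_alt // 2) + [1] * (n_alt % 2)
                calls += [0] * (n - len(calls))
                cols.append(calls)
            return np.array(cols, dtype=float).T

        d1 = pop([0.2, 0.5, 0.1])
        d2 = pop([0.8, 0.5, 0.9])
        g = toy_matrix(np.vstack([d1, d2]))
        got = structure.weir_cockerham_fst(g, np.repeat([0, 1], 10), 0, 1)
        assert got == pytest.approx(_wc_hand_oracle(d1, d2), abs=1e-12)

    def test_matrix_symmetric_zero_diagonal(self, small_dataset):
        _, g, env, _ = small_dataset
        labels = env["group"].to_numpy()
        mat = structure.pairwise_fst(g, labels)
        np.testing.assert_allclose(mat.to_numpy(), mat.to_numpy().T)
        assert np.all(np.diag(mat.to_numpy()) == 0)

    def test_small_group_raises(self):
        g = toy_matrix(np.zeros((4, 3)))
        with pytest.raises(ValueError):
            structure.weir_cockerham_fst(g, np.array([0, 0, 0, 1]), 0, 1)


class TestAmova:
    def test_percentages_sum_to_100(self, small_dataset):
        _, g, env, _ = small_dataset
        res = structure.amova(g, env["group"].to_numpy(), n_permutations=49, seed=0)
        assert res["pct_among"] + res["pct_within"] == pytest.approx(100.0)

    def test_random_labels_on_unstructured_data(self):
        rng = np.random.default_rng(6)
        d = rng.integers(0, 3, (40, 200)).astype(float)
        g = toy_matrix(d)
        labels = rng.integers(0, 2, 40)
        res = structure.amova(g, labels, n_permutations=199, seed=1)
        assert res["pct_among"] < 5
        assert res["p_perm"] > 1 / 100  # not in the extreme tail

    def test_phi_consistent_with_fst_on_structured_simulation(self):
        cfg = synthdata.LandscapeConfig(
            n_groups=2, fst_groups=0.3, n_loci=1000, n_individuals=120,
            n_adaptive=0, missing_rate=0.0, seed=8,
        )
        env = synthdata.simulate_sites_env(cfg)
        g, _ = synthdata.simulate_genotypes(cfg, env)
        labels = env["group"].to_numpy()
        res = structure.amova(g, labels, n_permutations=99, seed=0)
        fst = structure.weir_cockerham_fst(g, labels, 0, 1)
        assert res["pct_within"] < 100
        assert res["phi_st"] == pytest.approx(fst, abs=0.07)

    def test_permutation_p_in_valid_range(self, small_dataset):
        _, g, env, _ = small_dataset
        res = structure.amova(g, env["group"].to_numpy(), n_permutations=49, seed=0)
        assert 1 / 50 <= res["p_perm"] <= 1.0
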