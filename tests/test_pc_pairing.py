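import itertools

import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from pcafe.pca_fe import DegenerateInputError, embed_features
from pcafe.pc_pairing import (
    LoadingCorrelation,
    PCPair,
    find_coincident_pairs,
    loading_correlation,
    loo_stability,
    mutual_nearest_pairs,
    relabel_components,
    standardize_loadings,
    upgma,
)
from pcafe.synthetic import SyntheticConfig, generate

from conftest import make_matrix


def brute_force_upgma(labels, D):
    """Reference agglomeration recomputing every cluster distance as the
    plain mean over all inter-cluster leaf pairs (no running update)."""
    idx = {l: i for i, l in enumerate(labels)}
    clusters = [frozenset([l]) for l in labels]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters, key=min), 2):
            d = np.mean([D[idx[x], idx[y]] for x in a for y in b])
            key = (d, min(min(a), min(b)), max(min(a), min(b)))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        if min(b) < min(a):
            a, b = b, a
        merges.append((a, b, best[0][0]))
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return merges


class TestStandardize:
    def test_fixed_point_and_hand_example(self):
        z = standardize_loadings(np.array([[1.0, 2.0], [-1.0, 0.0]]))
        assert np.allclose(z, [[1.0, 1.0], [-1.0, -1.0]])

    def test_population_divisor(self):
        col = np.array([[2.0], [0.0], [1.0]])
        z = standardize_loadings(col)
        # mean 1, population sd sqrt(2/3)
        assert np.allclose(z[:, 0], (col[:, 0] - 1.0) / np.sqrt(2.0 / 3.0))
        assert abs(z[:, 0].mean()) < 1e-10
        assert abs((z[:, 0] ** 2).mean() - 1.0) < 1e-10

    def test_constant_column_rejected(self):
        with pytest.raises(DegenerateInputError):
            standardize_loadings(np.array([[3.0], [3.0]]))


class TestLoadingCorrelation:
    def make_decs(self, seed=0, I=50, J=12, K=4):
        rng = np.random.default_rng(seed)
        de = embed_features(make_matrix(rng.standard_normal((I, J))), K)
        dm = embed_features(
            make_matrix(rng.standard_normal((I, J)), modality="methylation"), K
        )
        return de, dm

    def test_identical_columns_give_unit_rho(self):
        de, _ = self.make_decs()
        rho = loading_correlation(de, de, 3)
        for k in range(3):
            assert rho.value(f"PC{k+1}", f"PC{k+1}M") == pytest.approx(1.0)

    def test_matches_textbook_correlation_oracle(self):
        de, dm = self.make_decs(seed=7, J=24)
        rho = loading_correlation(de, dm, 4)
        for i in range(4):
            for j in range(4):
                expected = np.corrcoef(de.loadings[:, i], dm.loadings[:, j])[0, 1]
                assert rho.value(f"PC{i+1}", f"PC{j+1}M") == pytest.approx(
                    expected, abs=1e-10
                )

    def test_symmetry_bounds_and_labels(self):
        de, dm = self.make_decs(seed=3)
        rho = loading_correlation(de, dm, 4)
        assert np.allclose(rho.rho, rho.rho.T)
        assert np.all(np.abs(rho.rho) <= 1 + 1e-12)
        assert np.allclose(np.diag(rho.rho), 1.0)
        assert rho.labels[:4] == ["PC1", "PC2", "PC3", "PC4"]
        assert rho.labels[4:] == ["PC1M", "PC2M", "PC3M", "PC4M"]

    def test_sign_flip_invariance_of_abs_rho(self):
        de, dm = self.make_decs(seed=9)
        rho1 = loading_correlation(de, dm, 4)
        dm.loadings[:, 1] *= -1
        rho2 = loading_correlation(de, dm, 4)
        assert np.allclose(np.abs(rho1.rho), np.abs(rho2.rho))

    def test_sample_mismatch_rejected(self):
        de, _ = self.make_decs(J=12)
        _, dm = self.make_decs(J=10)
        from pcafe.data_io import AlignmentError

        with pytest.raises(AlignmentError):
            loading_correlation(de, dm, 3)


class TestUpgma:
    def test_three_leaf_hand_example(self):
        D = np.array(
            [[0.0, -0.9, -0.2], [-0.9, 0.0, -0.1], [-0.2, -0.1, 0.0]]
        )
        tree = upgma(["A", "B", "C"], D)
        assert len(tree.merges) == 2
        m1, m2 = tree.merges
        assert m1.members == {"A", "B"} and m1.height == pytest.approx(-0.9)
        assert m2.members == {"A", "B", "C"} and m2.height == pytest.approx(-0.15)

    def test_two_leaves(self):
        tree = upgma(["X", "Y"], np.array([[0.0, -0.4], [-0.4, 0.0]]))
        assert tree.merges[0].height == pytest.approx(-0.4)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            upgma(["A", "B"], np.array([[0.0, -0.1], [-0.2, 0.0]]))

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(3, 7))
            labels = [f"L{i}" for i in range(n)]
            v = -rng.uniform(0, 1, size=(n, n))
            D = np.triu(v, 1) + np.triu(v, 1).T
            tree = upgma(labels, D)
            ref = brute_force_upgma(labels, D)
            assert len(tree.merges) == len(ref)
            for got, (a, b, h) in zip(tree.merges, ref):
                assert (got.left, got.right) == (a, b)
                assert got.height == pytest.approx(h, abs=1e-12)

    def test_matches_scipy_average_linkage_heights(self):
        rng = np.random.default_rng(4)
        n = 8
        v = -rng.uniform(0, 1, size=(n, n))
        D = np.triu(v, 1) + np.triu(v, 1).T
        # shift off-diagonals to non-negative for scipy, shift back after
        Dpos = D + 1.0
        np.fill_diagonal(Dpos, 0.0)
        Z = hierarchy.linkage(squareform(Dpos), method="average")
        tree = upgma([f"L{i}" for i in range(n)], D)
        assert np.allclose(sorted(m.height for m in tree.merges), Z[:, 2] - 1.0)

    def test_merge_heights_monotone(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(3, 10))
            v = -rng.uniform(0, 1, size=(n, n))
            D = np.triu(v, 1) + np.triu(v, 1).T
            heights = [m.height for m in upgma([f"L{i}" for i in range(n)], D).merges]
            assert np.all(np.diff(heights) >= -1e-12)


def make_rho(labels, modalities, matrix):
    return LoadingCorrelation(
        labels=labels,
        modalities=modalities,
        rho=np.asarray(matrix, float),
        std_loadings=np.zeros((2, len(labels))),
    )


class TestCoincidentPairs:
    def test_cross_modality_siblings_ordered_by_height(self):
        labels = ["PC3", "PC4", "PC3M", "PC4M"]
        mods = ["expression", "expression", "methylation", "methylation"]
        R = np.eye(4)
        R[0, 2] = R[2, 0] = 0.95
        R[1, 3] = R[3, 1] = 0.80
        rho = make_rho(labels, mods, R)
        tree = upgma(labels, -np.abs(R))
        pairs = find_coincident_pairs(tree, rho)
        assert [(p.expression_pc, p.methylation_pc) for p in pairs] == [
            ("PC3", "PC3M"),
            ("PC4", "PC4M"),
        ]
        assert pairs[0].rho == pytest.approx(0.95)

    def test_same_modality_siblings_excluded(self):
        labels = ["PC1", "PC2", "PC1M", "PC2M"]
        mods = ["expression", "expression", "methylation", "methylation"]
        R = np.eye(4)
        R[0, 1] = R[1, 0] = 0.9  # expression pair clusters first
        rho = make_rho(labels, mods, R)
        tree = upgma(labels, -np.abs(R))
        pairs = find_coincident_pairs(tree, rho)
        assert all(
            {rho.modality_of(p.expression_pc), rho.modality_of(p.methylation_pc)}
            == {"expression", "methylation"}
            for p in pairs
        )
        assert not any(
            {p.expression_pc, p.methylation_pc} == {"PC1", "PC2"} for p in pairs
        )

    def test_mutual_nearest_agrees_on_clean_structure(self):
        labels = ["PC3", "PC4", "PC3M", "PC4M"]
        mods = ["expression", "expression", "methylation", "methylation"]
        R = np.eye(4)
        R[0, 2] = R[2, 0] = -0.95
        rho = make_rho(labels, mods, R)
        top = mutual_nearest_pairs(rho)[0]
        assert (top.expression_pc, top.methylation_pc) == ("PC3", "PC3M")
        assert top.rho == pytest.approx(-0.95)


class TestRelabelAndStability:
    def test_relabeling_is_a_bijection(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            full = rng.standard_normal((10, 4))
            perm = rng.permutation(4)
            reduced = full[:, perm] + rng.normal(0, 0.05, size=(10, 4))
            labels = [f"PC{k+1}" for k in range(4)]
            names = relabel_components(reduced, full, labels)
            assert sorted(names) == labels
            # small perturbation of a permuted copy recovers the permutation
            assert names == [labels[p] for p in perm]

    def test_empty_targets_are_vacuously_conserved(self, small_paired):
        _, expr, meth, _ = small_paired
        count, outcomes = loo_stability(expr, meth, [], 5)
        assert count == expr.n_samples and all(outcomes)

    def test_k_too_large_rejected(self, small_paired):
        _, expr, meth, _ = small_paired
        with pytest.raises(ValueError):
            loo_stability(expr, meth, [PCPair("PC1", "PC1M", 1.0)], expr.n_samples)

    def test_noise_free_planted_factor_fully_conserved(self):
        cfg = SyntheticConfig(seed=5, n_probes=800, n_planted=25, noise_sd=0.0)
        expr, meth, _ = generate(cfg)
        de = embed_features(expr, 5)
        dm = embed_features(meth, 5)
        rho = loading_correlation(de, dm, 5)
        tree = upgma(rho.labels, -np.abs(rho.rho))
        pairs = find_coincident_pairs(tree, rho)[:1]
        count, _ = loo_stability(expr, meth, pairs, 5)
        assert count == expr.n_samples

    def test_moderate_noise_conservation_median(self):
        counts = []
        for seed in range(10):
            cfg = SyntheticConfig(seed=seed, n_probes=1500, n_planted=40)
            expr, meth, _ = generate(cfg)
            de = embed_features(expr, 5)
            dm = embed_features(meth, 5)
            rho = loading_correlation(de, dm, 5)
            tree = upgma(rho.labels, -np.abs(rho.rho))
            pairs = find_coincident_pairs(tree, rho)[:1]
            count, _ = loo_stability(expr, meth, pairs, 5)
            counts.append(count)
        assert np.median(counts) >= 20
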