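"""Connectivity similarity, degree-preserving nulls, and embeddings."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from primacyhull.connectivity import (
    ConnectivityMatrix,
    ShuffleEnsemble,
    binarize,
    build_shuffle_ensemble,
    dimension_significance,
    embedding_rmsd,
    glom_similarity,
    isomap_embed,
    offdiag_correlation,
    pca_embed,
    shuffle_degree_preserving,
)


def _conn(binary):
    binary = np.asarray(binary, dtype=bool)
    nk, ng = binary.shape
    return ConnectivityMatrix(binary, [f"KC{i}" for i in range(nk)], [f"G{j}" for j in range(ng)])


def _random_conn(rng, nk=30, ng=8, density=0.3):
    binary = rng.random((nk, ng)) < density
    binary[binary.sum(axis=1) == 0, 0] = True
    binary[0, binary.sum(axis=0) == 0] = True
    return _conn(binary)


class TestBinarize:
    def test_threshold_one(self):
        C = binarize(np.array([[3, 0], [1, 2]]), ["a", "b"], ["x", "y"])
        assert np.array_equal(C.binary, [[1, 0], [1, 1]])

    def test_threshold_two(self):
        C = binarize(np.array([[3, 0], [1, 2]]), ["a", "b"], ["x", "y"], threshold=2)
        assert np.array_equal(C.binary, [[1, 0], [0, 1]])

    def test_threshold_above_max_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            binarize(np.array([[1, 1]]), ["a"], ["x", "y"], threshold=5)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.array([[-1, 2]]), ["a"], ["x", "y"])

    def test_empty_rows_and_columns_dropped(self):
        C = binarize(np.array([[2, 0, 1], [0, 0, 0], [1, 0, 3]]), list("abc"), list("xyz"))
        assert C.kc_labels == ["a", "c"] and C.glom_labels == ["x", "z"]


class TestGlomSimilarity:
    def test_identical_columns_correlate_perfectly(self):
        C = _conn([[1, 1, 0], [0, 0, 1], [1, 1, 0], [0, 0, 0]])
        S = glom_similarity(C)
        assert S.values[0, 1] == pytest.approx(1.0)

    def test_complementary_columns_anticorrelate(self):
        S = glom_similarity(_conn([[1, 0], [0, 1]]))
        assert S.values[0, 1] == pytest.approx(-1.0)

    def test_matches_manual_pearson(self, rng):
        C = _random_conn(rng, nk=20, ng=6)
        S = glom_similarity(C)
        X = C.binary.astype(float)
        for i, li in enumerate(S.glom_labels):
            for j, lj in enumerate(S.glom_labels):
                a = X[:, C.glom_labels.index(li)]
                b = X[:, C.glom_labels.index(lj)]
                manual = np.mean((a - a.mean()) * (b - b.mean())) / (a.std() * b.std())
                assert S.values[i, j] == pytest.approx(manual, abs=1e-12)

    def test_constant_column_dropped(self):
        C = _conn([[1, 1, 0], [1, 0, 1], [1, 1, 1]])
        S = glom_similarity(C)
        assert len(S.glom_labels) == 2 and "G0" not in S.glom_labels


class TestOffdiagCorrelation:
    def test_self_correlation_is_one(self, rng):
        S = glom_similarity(_random_conn(rng))
        r, p = offdiag_correlation(S, S, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_matches_direct_formula_on_4x4(self, rng):
        S1 = glom_similarity(_random_conn(rng, nk=25, ng=4))
        S2 = glom_similarity(_random_conn(rng, nk=25, ng=4))
        S2.glom_labels = list(S1.glom_labels)
        r, _ = offdiag_correlation(S1, S2, n_perm=9, seed=0)
        iu = np.triu_indices(4, k=1)
        a, b = S1.values[iu], S2.values[iu]
        manual = np.corrcoef(a, b)[0, 1]
        assert r == pytest.approx(manual, abs=1e-12)

    def test_label_permutation_kills_expectation(self, rng):
        C = _random_conn(rng, nk=200, ng=30)
        S1 = glom_similarity(C)
        rs = []
        for _ in range(20):
            perm = rng.permutation(len(S1.glom_labels))
            S2 = type(S1)(S1.values[np.ix_(perm, perm)], S1.glom_labels)
            r, _ = offdiag_correlation(S1, S2, n_perm=9, seed=1)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.1

    def test_too_few_shared_labels(self, rng):
        S = glom_similarity(_random_conn(rng))
        S2 = type(S)(S.values[:2, :2], ["Z1", "Z2"])
        with pytest.raises(ValueError):
            offdiag_correlation(S, S2, n_perm=9)


class TestDegreePreservingShuffle:
    def test_margins_preserved(self, rng):
        for _ in range(25):
            C = _random_conn(rng, nk=15, ng=6, density=0.4)
            Cs = shuffle_degree_preserving(C, seed=rng)
            assert np.array_equal(Cs.binary.sum(axis=0), C.binary.sum(axis=0))
            assert np.array_equal(Cs.binary.sum(axis=1), C.binary.sum(axis=1))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        binary=arrays(np.bool_, (7, 5), elements=st.booleans()),
        seed=st.integers(0, 2**20),
    )
    def test_margins_preserved_property(self, binary, seed):
        if not binary.any():
            return
        C = _conn(binary)
        Cs = shuffle_degree_preserving(C, seed=seed)
        assert np.array_equal(Cs.binary.sum(axis=0), C.binary.sum(axis=0))
        assert np.array_equal(Cs.binary.sum(axis=1), C.binary.sum(axis=1))

    def test_all_ones_unchanged(self):
        C = _conn(np.ones((4, 3)))
        Cs = shuffle_degree_preserving(C, seed=0)
        assert np.array_equal(Cs.binary, C.binary)

    def test_2x2_identity_reaches_both_states(self):
        C = _conn(np.eye(2))
        seen = set()
        for seed in range(40):
            Cs = shuffle_degree_preserving(C, seed=seed)
            seen.add(tuple(Cs.binary.astype(int).ravel().tolist()))
        assert seen == {(1, 0, 0, 1), (0, 1, 1, 0)}

    def test_actually_randomizes(self, rng):
        C = _random_conn(rng, nk=50, ng=10)
        Cs = shuffle_degree_preserving(C, seed=0)
        assert not np.array_equal(Cs.binary, C.binary)


class TestPCAEmbed:
    def test_rank_two_data_fully_explained(self, rng):
        basis = rng.normal(size=(2, 8))
        coef = rng.normal(size=(8, 2))
        X = coef @ basis
        S = X @ X.T
        S = S / np.sqrt(np.outer(np.diag(S), np.diag(S)))
        from primacyhull.connectivity import GlomSimilarity

        E = pca_embed(GlomSimilarity(S, [f"G{i}" for i in range(8)]), d=4)
        assert E.variance_explained[:2].sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_eigendecomposition_oracle(self, rng):
        from primacyhull.connectivity import GlomSimilarity

        A = rng.normal(size=(10, 10))
        S = (A + A.T) / 2
        np.fill_diagonal(S, 1.0)
        G = GlomSimilarity(S, [f"G{i}" for i in range(10)])
        E = pca_embed(G, d=3)
        Xc = S - S.mean(axis=0)
        cov = Xc.T @ Xc / (10 - 1)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        expected = evals[:3] / evals.sum()
        assert np.allclose(E.variance_explained, expected, atol=1e-9)

    def test_duplicated_rows_embed_identically(self, rng):
        C = _random_conn(rng, nk=40, ng=6)
        S = glom_similarity(C)
        S.values[1] = S.values[0]
        S.values[:, 1] = S.values[:, 0]
        E = pca_embed(S, d=2)
        assert np.allclose(E.coords[0], E.coords[1], atol=1e-10)

    def test_d_too_large(self, rng):
        S = glom_similarity(_random_conn(rng, ng=5))
        with pytest.raises(ValueError):
            pca_embed(S, d=5)


class TestIsomapEmbed:
    def test_arc_is_one_dimensional(self, rng):
        """Points along a curved 1D arc in 5D: dim 1 dominates geodesically."""
        from primacyhull.connectivity import GlomSimilarity

        t = np.linspace(0, np.pi, 40)
        X = np.zeros((40, 5))
        X[:, 0], X[:, 1] = np.cos(t), np.sin(t)
        X += 0.001 * rng.normal(size=X.shape)
        S = np.corrcoef(X @ rng.normal(size=(5, 30)))
        G = GlomSimilarity((S + S.T) / 2, [f"G{i}" for i in range(40)])
        E = isomap_embed(G, d=3, k=3)
        assert E.variance_explained[0] / E.variance_explained.sum() > 0.9

    def test_complete_graph_matches_pca(self, rng):
        from scipy.linalg import orthogonal_procrustes

        S = glom_similarity(_random_conn(rng, nk=60, ng=10))
        n = len(S.glom_labels)
        Ep = pca_embed(S, d=2)
        Ei = isomap_embed(S, d=2, k=n - 1)
        R, _ = orthogonal_procrustes(Ei.coords, Ep.coords)
        resid = np.linalg.norm(Ei.coords @ R - Ep.coords)
        assert resid < 1e-6

    def test_disconnected_graph_names_smallest_k(self):
        from primacyhull.connectivity import GlomSimilarity

        # two tight, far-apart clusters: k=1 graph is disconnected
        X = np.vstack([np.zeros((3, 2)) + [[0, 0], [0.1, 0], [0, 0.1]],
                       np.zeros((3, 2)) + [[10, 10], [10.1, 10], [10, 10.1]]])
        S = np.exp(-((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        G = GlomSimilarity(S, [f"G{i}" for i in range(6)])
        with pytest.raises(ValueError, match="smallest connecting k"):
            isomap_embed(G, d=2, k=1)


class TestEmbeddingRMSD:
    def _embed_pair(self, rng, transform):
        S = glom_similarity(_random_conn(rng, nk=50, ng=8))
        E1 = pca_embed(S, d=2)
        E2 = pca_embed(S, d=2)
        E2.coords = transform(E1.coords)
        return E1, E2

    def test_rotation_gives_zero(self, rng):
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        E1, E2 = self._embed_pair(rng, lambda X: X @ R + np.array([3.0, -1.0]))
        rmsd, _, _ = embedding_rmsd(E1, E2)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_reflection_gives_zero(self, rng):
        E1, E2 = self._embed_pair(rng, lambda X: X * np.array([-1.0, 1.0]))
        rmsd, _, _ = embedding_rmsd(E1, E2)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_noise_scaling(self, rng):
        """Isotropic 2D noise of scale sigma gives RMSD ~ sigma*sqrt(2)."""
        sigma = 0.05
        rmsds = []
        for _ in range(30):
            E1, E2 = self._embed_pair(rng, lambda X: X + sigma * rng.normal(size=X.shape))
            rmsds.append(embedding_rmsd(E1, E2)[0])
        assert np.mean(rmsds) == pytest.approx(sigma * np.sqrt(2), rel=0.15)

    def test_too_few_shared_labels(self, rng):
        S = glom_similarity(_random_conn(rng, ng=8))
        E1 = pca_embed(S, d=2)
        E2 = pca_embed(S, d=2)
        E2.labels = [f"Z{i}" for i in range(len(E2.labels))]
        with pytest.raises(ValueError):
            embedding_rmsd(E1, E2)


class TestDimensionSignificance:
    def _ensemble(self, ve):
        return ShuffleEnsemble(method="pca", n_shuffles=ve.shape[0], seed=0, variance_explained=ve)

    def test_observed_at_ensemble_maximum(self, rng):
        C = _random_conn(rng, nk=40, ng=8)
        S = glom_similarity(C)
        obs = pca_embed(S, 2).variance_explained
        null = np.tile(obs * 0.5, (19, 1))
        p = dimension_significance(S, 2, self._ensemble(null))
        assert np.allclose(p, 1 / 20)

    def test_observed_below_median(self, rng):
        C = _random_conn(rng, nk=40, ng=8)
        S = glom_similarity(C)
        obs = pca_embed(S, 2).variance_explained
        null = np.tile(obs * 2.0, (19, 1))
        p = dimension_significance(S, 2, self._ensemble(null))
        assert np.all(p > 0.5)

    def test_planted_world_leading_dimensions_significant(self):
        """Connectivity sampling a low-dimensional hull shows significant
        leading embedding dimensions against the degree-preserving null."""
        from primacyhull.synth import make_world, preset

        world = make_world(preset("validation", seed=4))
        S = glom_similarity(world.connectivity)
        ens = build_shuffle_ensemble(
            world.connectivity, d_max=4, n_shuffles=50, method="pca", seed=9
        )
        p = dimension_significance(S, 4, ens)
        assert np.all(p[:2] < 0.05)

    def test_pipeline_ensemble_runs(self, rng):
        C = _random_conn(rng, nk=40, ng=8)
        ens = build_shuffle_ensemble(C, d_max=2, n_shuffles=5, method="pca", seed=1)
        assert ens.variance_explained.shape == (5, 2)
        p = dimension_significance(glom_similarity(C), 2, ens)
        assert np.all((p > 0) & (p <= 1))
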