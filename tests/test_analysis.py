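"""Eigenmaps, MDS embeddings and cluster diagnostics."""

import numpy as np
import pytest

from cogmap.analysis import (
    Embedding2D,
    cluster_purity,
    dominant_frequency_radius,
    eigenmaps_of_sr,
    embedding_stress,
    mds_embed,
    within_class_spread,
)
from cogmap.environments import build_square_room, environment_transition_matrix
from cogmap.sr import successor_matrix


class TestEigenmaps:
    def test_shapes_and_count(self, room10, room10_T):
        sr = successor_matrix(room10_T, 1.0, 10)
        maps = eigenmaps_of_sr(sr, room10, k=30)
        assert maps.maps.shape == (30, 10, 10)
        assert maps.eigenvalues.shape == (30,)

    def test_identity_sr_all_unit_eigenvalues(self, room10):
        maps = eigenmaps_of_sr(np.eye(100), room10, k=100)
        np.testing.assert_allclose(maps.eigenvalues, 1.0, atol=1e-12)

    def test_descending_order_default(self, room10, room10_T):
        sr = successor_matrix(room10_T, 1.0, 10)
        vals = eigenmaps_of_sr(sr, room10, k=10).eigenvalues
        assert (np.diff(vals) <= 1e-12).all()
        asc = eigenmaps_of_sr(sr, room10, k=10, order="ascending").eigenvalues
        assert (np.diff(asc) >= -1e-12).all()

    def test_shape_mismatch_rejected(self, room10):
        with pytest.raises(ValueError, match="lattice"):
            eigenmaps_of_sr(np.eye(99), room10, k=5)
        with pytest.raises(ValueError, match="k"):
            eigenmaps_of_sr(np.eye(100), room10, k=101)

    def test_ring_eigenvectors_are_fourier_modes(self, ring8_T):
        # circulant structure: eigenvectors must lie in the cos/sin pair
        # subspaces of the discrete Fourier basis
        n = 8
        M = successor_matrix(ring8_T, 0.9, float("inf")).M
        vals, vecs = np.linalg.eig(M)
        x = np.arange(n)
        subspaces = []
        for k in range(n // 2 + 1):
            basis = [np.cos(2 * np.pi * k * x / n)]
            if 0 < k < n / 2:
                basis.append(np.sin(2 * np.pi * k * x / n))
            Q = np.linalg.qr(np.array(basis).T)[0]
            subspaces.append(Q)
        for i in range(n):
            v = vecs[:, i].real
            v /= np.linalg.norm(v)
            best = max(np.linalg.norm(Q.T @ v) for Q in subspaces)
            assert best > 0.99

    def test_eigenvalue_consistency_with_transition_matrix(self, room10, room10_T):
        # the walk with self-moves on the open room is diagonally similar to
        # a symmetric matrix, so T and M share eigenvectors and eigenvalues
        # map through the truncated geometric sum
        gamma, h = 0.9, 10
        sr = successor_matrix(room10_T, gamma, h)
        vals_T = np.sort(np.linalg.eigvals(room10_T.T).real)[::-1]
        vals_M = np.sort(np.linalg.eigvals(sr.M).real)[::-1]
        mapped = np.sort([sum((gamma * lt) ** t for t in range(h + 1))
                          for lt in vals_T])[::-1]
        np.testing.assert_allclose(vals_M, mapped, atol=1e-8)


class TestSpatialFrequency:
    def test_constant_field_zero_frequency(self):
        assert dominant_frequency_radius(np.ones((10, 10))) == 0.0

    def test_pure_cosine_mode_radius(self):
        x = np.arange(12)
        field = np.outer(np.cos(np.pi * 3 * x / 12), np.cos(np.pi * 4 * x / 12))
        assert dominant_frequency_radius(field) == pytest.approx(np.hypot(3, 4) / 2)

    def test_mesh_size_shrinks_with_eigenvalue(self, room10, room10_T):
        # coarse-to-fine trend across the leading 30 eigenmaps
        sr = successor_matrix(room10_T, 1.0, 10)
        maps = eigenmaps_of_sr(sr, room10, k=30)
        freqs = np.array([dominant_frequency_radius(m) for m in maps.maps])
        from scipy.stats import spearmanr

        rho = spearmanr(maps.eigenvalues, freqs).statistic
        assert rho < -0.9
        deciles = [freqs[:10].mean(), freqs[10:20].mean(), freqs[20:].mean()]
        assert deciles[0] < deciles[1] < deciles[2]


class TestMds:
    def test_recovers_planar_configuration(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(12, 2))
        rows = np.hstack([pts, np.zeros((12, 38))])
        emb = mds_embed(rows)
        D0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        D1 = np.linalg.norm(emb.coords[:, None] - emb.coords[None, :], axis=-1)
        np.testing.assert_allclose(D0, D1, atol=1e-6)

    def test_identical_rows_embed_identically(self, language_T):
        labels = np.repeat(np.arange(4), 10)
        emb = mds_embed(language_T.T, labels)
        for adj in range(1, 10):
            np.testing.assert_allclose(emb.coords[adj], emb.coords[0], atol=1e-9)

    def test_degenerate_input_warns_and_returns_origin(self):
        rows = np.ones((5, 8))
        with pytest.warns(UserWarning, match="identical"):
            emb = mds_embed(rows)
        assert not emb.coords.any()

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            mds_embed(np.ones((2, 4)))

    def test_stress_refinement_never_worse_than_classical(self, language_T):
        rows = language_T.T
        classical = mds_embed(rows)
        refined = mds_embed(rows, method="stress", seed=0)
        assert embedding_stress(refined, rows) <= embedding_stress(classical, rows) + 1e-9


class TestClusterDiagnostics:
    def test_tp_rows_give_five_pure_clusters(self, grammar_fixture, language_T):
        vocab, _ = grammar_fixture
        emb = mds_embed(language_T.T, vocab.labels, method="stress", seed=0)
        assert cluster_purity(emb, 5, seed=0) == 1.0
        assert within_class_spread(emb) < 1e-9

    def test_k1_purity_is_majority_fraction(self, grammar_fixture, language_T):
        vocab, _ = grammar_fixture
        emb = mds_embed(language_T.T, vocab.labels, method="stress", seed=0)
        assert cluster_purity(emb, 1, seed=0) == 0.25

    def test_uniform_labels_always_pure(self):
        rng = np.random.default_rng(2)
        emb = Embedding2D(rng.normal(size=(12, 2)), np.zeros(12))
        for k in (1, 3, 6):
            assert cluster_purity(emb, k, seed=0) == 1.0

    def test_k_exceeding_items_rejected(self):
        emb = Embedding2D(np.zeros((4, 2)), np.arange(4))
        with pytest.raises(ValueError):
            cluster_purity(emb, 5)

    def test_sr_spread_exceeds_tp_spread(self, grammar_fixture, language_T):
        # SR rows keep each word's own-state occupancy, so same-class rows
        # differ and their embedded cloud has positive width
        vocab, _ = grammar_fixture
        sr = successor_matrix(language_T, 1.0, 2)
        etp = mds_embed(language_T.T, vocab.labels, method="stress", seed=0)
        esr = mds_embed(sr.M, vocab.labels, method="stress", seed=0)
        assert within_class_spread(esr) > within_class_spread(etp)
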