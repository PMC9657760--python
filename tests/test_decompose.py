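"""Decompositions: PCA, scree selection, NMF restarts, JADE-ICA, ComDim,
oblique coordinates and loading signatures."""

import numpy as np
import pandas as pd
import pytest

from planktofuse import (
    comdim,
    explained_variance,
    inter_axis_angle,
    jade_ica,
    loading_signature,
    nmf,
    oblique_scores,
    pca,
    scree_select,
)
from planktofuse.decompose import Decomposition
from planktofuse.preprocess import PeakWindow


class TestPCA:
    def test_rank_one_data_single_component(self, rng):
        direction = rng.normal(size=20)
        X = np.outer(rng.normal(size=10), direction)
        dec = pca(X, 2)
        assert dec.explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_loadings_orthonormal_scores_uncorrelated(self, rng):
        X = rng.normal(size=(15, 40))
        dec = pca(X, 5)
        np.testing.assert_allclose(
            dec.loadings @ dec.loadings.T, np.eye(5), atol=1e-8
        )
        gram = dec.scores.T @ dec.scores
        np.testing.assert_allclose(
            gram - np.diag(np.diag(gram)), 0.0, atol=1e-8
        )

    def test_eigenvalues_match_covariance_eigendecomposition(self, rng):
        """Oracle: dense eigendecomposition of the sample covariance."""
        X = rng.normal(size=(12, 8))
        dec = pca(X, 5)
        cov = np.cov(X, rowvar=False)
        expected = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(dec.eigenvalues[:8], expected, atol=1e-10)

    def test_full_reconstruction_exact(self, rng):
        X = rng.normal(size=(10, 30))
        dec = pca(X, 9)
        Xc = X - X.mean(axis=0)
        recon = dec.scores @ dec.loadings
        assert np.linalg.norm(Xc - recon) / np.linalg.norm(Xc) < 1e-8

    def test_sign_convention(self, rng):
        X = rng.normal(size=(10, 30))
        dec = pca(X, 3)
        for row in dec.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_errors(self, rng):
        X = rng.normal(size=(6, 10))
        with pytest.raises(ValueError):
            pca(X, 6)  # p > n-1
        with pytest.raises(ValueError, match="constant"):
            pca(np.ones((5, 4)), 2)


class TestScreeSelect:
    def test_obvious_elbow(self):
        assert scree_select([10, 9.5, 1, 0.9, 0.8]).p == 2

    def test_flat_scree_warns(self):
        with pytest.warns(UserWarning, match="flat"):
            res = scree_select([2.0, 2.0, 2.0, 2.0])
        assert res.p == 1 and res.flat

    def test_geometric_decay_picks_first_drop(self):
        eig = 10.0 * 2.0 ** -np.arange(8)
        drops = (eig[:-1] - eig[1:]) / eig[:-1]  # all equal: first wins
        assert np.allclose(drops, drops[0])
        assert scree_select(eig).p == 1

    def test_short_input_returns_count(self):
        assert scree_select([3.0, 1.0]).p == 2


class TestNMF:
    def test_exact_rank_two_recovered(self, rng):
        W = rng.uniform(0.5, 2.0, size=(12, 2))
        H = rng.uniform(0.5, 2.0, size=(2, 30))
        dec = nmf(W @ H, 2, n_restarts=10, seed=0)
        assert dec.total_ev >= 0.999
        assert np.all(dec.scores >= 0) and np.all(dec.loadings >= 0)

    def test_fixed_seed_bit_identical(self, rng):
        X = rng.uniform(0, 1, size=(10, 20))
        a = nmf(X, 3, n_restarts=3, seed=4)
        b = nmf(X, 3, n_restarts=3, seed=4)
        assert np.array_equal(a.scores, b.scores)
        assert np.array_equal(a.loadings, b.loadings)

    def test_best_of_restarts_at_least_single_run(self, rng):
        X = rng.uniform(0, 1, size=(15, 25))
        multi = nmf(X, 4, n_restarts=8, seed=1)
        single = nmf(X, 4, n_restarts=1, seed=1)
        assert multi.total_ev >= single.total_ev - 1e-12

    def test_ev_nondecreasing_in_p(self, rng):
        X = rng.uniform(0, 1, size=(12, 18))
        evs = [nmf(X, p, n_restarts=5, seed=2).total_ev for p in (1, 2, 3, 4)]
        assert all(b >= a - 1e-9 for a, b in zip(evs, evs[1:]))

    def test_negative_entries_rejected(self, rng):
        X = rng.normal(size=(8, 12))
        with pytest.raises(ValueError, match="clip"):
            nmf(X, 2)

    def test_p_zero_rejected(self, rng):
        with pytest.raises(ValueError):
            nmf(rng.uniform(size=(5, 5)), 0)


class TestExplainedVariance:
    def test_perfect_reconstruction(self, rng):
        X = rng.normal(size=(6, 9))
        assert explained_variance(X, X) == pytest.approx(1.0)

    def test_zero_reconstruction_of_centred_data(self, rng):
        X = rng.normal(size=(6, 9))
        Xc = X - X.mean(axis=0)
        assert explained_variance(Xc, np.zeros_like(X), "centered") == (
            pytest.approx(0.0)
        )

    def test_svd_truncation_matches_eigenvalue_fraction(self, rng):
        """Eckart-Young: rank-k truncation EV equals the eigenvalue ratio."""
        X = rng.normal(size=(10, 14))
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        for k in (1, 3, 5):
            recon = (U[:, :k] * s[:k]) @ Vt[:k]
            ev = explained_variance(Xc, recon, "centered")
            assert ev == pytest.approx((s[:k] ** 2).sum() / (s**2).sum())

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            explained_variance(np.zeros((3, 3)), np.zeros((3, 3)))


def _mixed_sources(rng, n=600):
    s1 = rng.uniform(-np.sqrt(3), np.sqrt(3), size=n)  # sub-Gaussian
    s2 = rng.laplace(0, 1 / np.sqrt(2), size=n)  # super-Gaussian
    S = np.column_stack([s1, s2])
    A = rng.normal(size=(2, 2)) + 2 * np.eye(2)
    return S, S @ A.T


class TestJadeICA:
    def test_blind_source_recovery(self, rng):
        S, X = _mixed_sources(rng)
        dec = jade_ica(X, 2)
        corr = np.abs(np.corrcoef(dec.scores.T, S.T)[:2, 2:])
        # each source matched by one component up to sign/permutation
        assert corr.max(axis=0).min() >= 0.99

    def test_matches_fastica_cross_check(self, rng):
        """Independent oracle: sklearn FastICA recovers the same sources."""
        from sklearn.decomposition import FastICA

        S, X = _mixed_sources(rng)
        ours = jade_ica(X, 2).scores
        theirs = FastICA(n_components=2, random_state=0, whiten="unit-variance")
        Y = theirs.fit_transform(X)
        corr = np.abs(np.corrcoef(ours.T, Y.T)[:2, 2:])
        assert corr.max(axis=0).min() >= 0.98

    def test_whitening_preserved(self, rng):
        _, X = _mixed_sources(rng, n=400)
        dec = jade_ica(X, 2)
        scatter = dec.scores.T @ dec.scores / X.shape[0]
        np.testing.assert_allclose(scatter, np.eye(2), atol=1e-8)

    def test_reconstruction_residual(self, rng):
        X = rng.normal(size=(30, 10)) @ rng.normal(size=(10, 40))
        dec = jade_ica(X, 5)
        Xc = X - X.mean(axis=0)
        recon = dec.scores @ dec.loadings
        # scores @ loadings restores the rank-p part of the centred data
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        rank_p = (U[:, :5] * s[:5]) @ Vt[:5]
        assert np.linalg.norm(recon - rank_p) / np.linalg.norm(rank_p) < 1e-8

    def test_gaussian_data_warns_but_returns(self, rng):
        # n large enough that sample kurtosis of Gaussian data stays near 0
        X = rng.normal(size=(50000, 6))
        with pytest.warns(UserWarning, match="Gaussian"):
            dec = jade_ica(X, 3)
        assert dec.meta["gaussian_warning"]
        assert dec.scores.shape == (50000, 3)

    def test_rank_excess_rejected(self, rng):
        X = np.outer(rng.normal(size=20), rng.normal(size=10))
        with pytest.raises(ValueError, match="rank"):
            jade_ica(X, 3)


class TestComDim:
    def _block(self, rng, n=10, f=25, rank=None):
        X = rng.normal(size=(n, f))
        if rank is not None:
            U, s, Vt = np.linalg.svd(X, full_matrices=False)
            X = (U[:, :rank] * s[:rank]) @ Vt[:rank]
        return X

    def test_single_block_matches_eigendecomposition(self, rng):
        """Oracle: ComDim of one block equals the eigendecomposition of its
        unit-norm cross-product matrix."""
        X = self._block(rng)
        Xs = X / np.linalg.norm(X)
        W = Xs @ Xs.T
        evals, evecs = np.linalg.eigh(W)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        res = comdim([X], 4)
        np.testing.assert_allclose(res.saliences[0], evals[:4], atol=1e-8)
        for d in range(4):
            v = evecs[:, d] * np.sign(evecs[np.argmax(np.abs(evecs[:, d])), d])
            assert (
                min(
                    np.linalg.norm(res.Q[:, d] - v),
                    np.linalg.norm(res.Q[:, d] + v),
                )
                < 1e-8
            )

    def test_identical_blocks_equal_saliences(self, rng):
        X = self._block(rng)
        res = comdim([X, X.copy()], 3)
        np.testing.assert_allclose(res.saliences[0], res.saliences[1],
                                   atol=1e-8)

    def test_q_orthonormal_and_saliences_nonnegative(self, rng):
        res = comdim([self._block(rng), self._block(rng, f=40)], 5)
        np.testing.assert_allclose(res.Q.T @ res.Q, np.eye(5), atol=1e-8)
        assert np.all(res.saliences >= -1e-12)

    def test_structured_block_outweighs_noise(self, rng):
        """Block with strong 1-D structure gets the larger first-dimension
        salience than a pure-noise block."""
        wins = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            structured = np.outer(r.normal(size=12), r.normal(size=30))
            structured += 0.05 * r.normal(size=structured.shape)
            noise = r.normal(size=(12, 30))
            res = comdim([structured, noise], 2)
            wins += res.saliences[0, 0] > res.saliences[1, 0]
        assert wins == 5

    def test_salience_conservation(self, rng):
        """Exhaustive deflation: saliences of block k sum to trace(W_k).

        Both blocks are row-centred so they share the all-ones null direction
        and p = N-1 common components span their joint column space.
        """
        n = 8
        P = np.eye(n) - np.ones((n, n)) / n
        X = P @ rng.normal(size=(n, 20))
        Y = P @ rng.normal(size=(n, 15))
        res = comdim([X, Y], n - 1)
        for k, M in enumerate([X, Y]):
            Ms = M / np.linalg.norm(M)
            assert res.saliences[k].sum() == pytest.approx(
                np.trace(Ms @ Ms.T), abs=1e-6
            )

    def test_ica_inner_method_runs(self, rng):
        X = self._block(rng, n=14, f=40)
        Y = self._block(rng, n=14, f=25)
        res = comdim([X, Y], 3, inner_method="ica")
        np.testing.assert_allclose(res.Q.T @ res.Q, np.eye(3), atol=1e-8)
        assert np.all(res.saliences >= -1e-12)

    def test_errors(self, rng):
        with pytest.raises(ValueError, match="rows|samples"):
            comdim([self._block(rng, n=5), self._block(rng, n=6)], 2)
        with pytest.raises(ValueError, match="p must"):
            comdim([self._block(rng, n=5)], 5)


class TestModelContainers:
    def test_bss_model_residual_and_validation(self, rng):
        from planktofuse import BSSModel

        S = rng.normal(size=(2, 100))
        A = rng.normal(size=(3, 2))
        model = BSSModel(mixing=A, sources=S, observations=A @ S)
        assert model.residual < 1e-12
        assert (model.n_sources, model.n_sensors) == (2, 3)
        with pytest.raises(ValueError, match="shape"):
            BSSModel(mixing=A.T, sources=S, observations=A @ S)

    def test_oblique_axes_consistency(self, rng):
        from planktofuse import ObliqueAxes

        u, v = rng.normal(size=8), rng.normal(size=8)
        axes = ObliqueAxes.from_vectors(u, v)
        assert axes.alpha == pytest.approx(inter_axis_angle(u, v))
        with pytest.raises(ValueError, match="inconsistent"):
            ObliqueAxes(u=[1.0, 0.0], v=[0.0, 1.0], alpha=45.0)


class TestObliqueCoordinates:
    @pytest.mark.parametrize(
        "u,v,expected",
        [
            ([1.0, 2.0], [1.0, 2.0], 0.0),
            ([1.0, 0.0], [0.0, 1.0], 90.0),
            ([1.0, 1.0], [1.0, 0.0], 45.0),
        ],
    )
    def test_inter_axis_angle(self, u, v, expected):
        # arccos is ill-conditioned near parallel vectors; 1e-5 deg is exact
        # to working precision there
        assert inter_axis_angle(u, v) == pytest.approx(expected, abs=1e-5)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            inter_axis_angle([0.0, 0.0], [1.0, 0.0])

    def test_right_angle_is_identity(self, rng):
        S = rng.normal(size=(7, 2))
        np.testing.assert_allclose(oblique_scores(S, 90.0), S, atol=1e-12)

    def test_sixty_degrees_closed_form(self):
        out = oblique_scores(np.array([[1.0, 1.0]]), 60.0)
        np.testing.assert_allclose(out, [[1.5, np.sqrt(3) / 2]])

    def test_plotted_basis_inner_product_is_cos_alpha(self):
        for alpha in (30.0, 60.0, 120.0):
            e1 = oblique_scores(np.array([[1.0, 0.0]]), alpha)[0]
            e2 = oblique_scores(np.array([[0.0, 1.0]]), alpha)[0]
            assert e1 @ e2 == pytest.approx(np.cos(np.radians(alpha)))

    def test_degenerate_angle_rejected(self, rng):
        with pytest.raises(ValueError):
            oblique_scores(rng.normal(size=(3, 2)), 0.0)
        with pytest.raises(ValueError):
            oblique_scores(rng.normal(size=(3, 2)), 180.0)


class TestLoadingSignature:
    def _decomposition(self, loadings):
        p, nfeat = loadings.shape
        fa = pd.DataFrame(
            {"modality": "LIBS", "position": np.linspace(0.0, 100.0, nfeat)}
        )
        return Decomposition(
            kind="pca",
            scores=np.zeros((3, p)),
            loadings=loadings,
            explained=np.ones(p) / p,
            total_ev=1.0,
            p=p,
            feature_axis=fa,
        )

    def test_single_component_is_plus_minus_one(self):
        loadings = np.vstack([np.sin(np.linspace(0, 6, 101))])
        dec = self._decomposition(loadings)
        sig = loading_signature(dec, [PeakWindow("w", 30.0, 20.0)])
        assert abs(sig.iloc[0, 0]) == pytest.approx(1.0)

    def test_zero_loading_in_window_gives_zero(self):
        loadings = np.vstack([np.ones(101), np.zeros(101)])
        loadings[0, :20] = 5.0  # structure outside the window
        dec = self._decomposition(loadings)
        sig = loading_signature(dec, [PeakWindow("w", 70.0, 10.0)])
        assert sig.iloc[1, 0] == 0.0

    def test_normalisation_closed_form(self):
        """Window integrals 2 and -4 normalise to 0.5 and -1."""
        nfeat = 101
        x = np.linspace(0.0, 100.0, nfeat)
        tri = np.clip(1.0 - np.abs(x - 50.0) / 10.0, 0.0, None)  # area 10
        dec = self._decomposition(np.vstack([0.2 * tri, -0.4 * tri]))
        sig = loading_signature(dec, [PeakWindow("w", 50.0, 25.0)])
        assert sig.iloc[0, 0] == pytest.approx(0.5, abs=1e-6)
        assert sig.iloc[1, 0] == pytest.approx(-1.0, abs=1e-6)

    def test_empty_windows_rejected(self):
        dec = self._decomposition(np.ones((1, 10)))
        with pytest.raises(ValueError):
            loading_signature(dec, [])
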