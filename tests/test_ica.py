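"""Group ICA tests: reductions, InfoMax recovery, back-projection, stability."""

import numpy as np
import pytest

from falff_prognosis import Bold4D, CohortConfig, ConfigurationError, make_cohort
from falff_prognosis.ica import (
    back_project,
    concatenate_and_reduce,
    infomax_unmix,
    reduce_subject,
    run_group_ica,
    stability_restarts,
)


def scan_from_matrix(X, subject_id="s"):
    """Wrap a (t, voxels) matrix as a flat 1-slice Bold4D."""
    t, V = X.shape
    vol = X.T.reshape(V, 1, 1, t)
    return Bold4D(vol, 2.0, np.ones((V, 1, 1), bool), subject_id)


class TestReduceSubject:
    def test_exact_rank_two_reconstruction(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 2)) @ rng.standard_normal((2, 200))
        reduced, model = reduce_subject(scan_from_matrix(X), k=2)
        Xc = X - X.mean(axis=0)
        rebuilt = model.basis @ reduced
        assert np.linalg.norm(rebuilt - Xc) / np.linalg.norm(Xc) <= 1e-8

    def test_full_rank_reduction_lossless(self):
        # after voxel-wise centering the temporal rank is t - 1, at which
        # the reduction is an identity up to rotation
        rng = np.random.default_rng(1)
        X = rng.standard_normal((10, 300))
        reduced, model = reduce_subject(scan_from_matrix(X), k=9)
        Xc = X - X.mean(axis=0)
        np.testing.assert_allclose(model.basis @ reduced, Xc, atol=1e-8)

    def test_residual_energy_equals_discarded_eigenvalues(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 500))
        scan = scan_from_matrix(X)
        reduced, model = reduce_subject(scan, k=5)
        Xc = X - X.mean(axis=0)
        # independent eigendecomposition oracle
        eig = np.linalg.eigvalsh(Xc @ Xc.T / (X.shape[1] - 1))[::-1]
        residual = np.linalg.norm(Xc - model.basis @ reduced) ** 2 / (X.shape[1] - 1)
        assert residual == pytest.approx(eig[5:].sum(), rel=1e-8)

    def test_rows_uncorrelated(self):
        rng = np.random.default_rng(3)
        reduced, _ = reduce_subject(scan_from_matrix(rng.standard_normal((20, 400))), k=6)
        gram = reduced @ reduced.T / (reduced.shape[1] - 1)
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_k_beyond_rank_raises(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 2)) @ rng.standard_normal((2, 100))
        with pytest.raises(ConfigurationError, match="achievable maximum"):
            reduce_subject(scan_from_matrix(X), k=5)


class TestConcatenateAndReduce:
    def test_whiteness(self):
        rng = np.random.default_rng(5)
        parts = [rng.standard_normal((8, 600)) for _ in range(3)]
        white, _ = concatenate_and_reduce(parts, n_components=6)
        cov = white @ white.T / (white.shape[1] - 1)
        assert np.abs(cov - np.eye(6)).max() < 1e-6

    def test_identical_subjects_same_subspace(self):
        rng = np.random.default_rng(6)
        part = rng.standard_normal((6, 500))
        single, _ = concatenate_and_reduce([part], n_components=4)
        double, _ = concatenate_and_reduce([part, part.copy()], n_components=4)
        # principal angles between row spaces ~ 0
        qa, _ = np.linalg.qr(single.T)
        qb, _ = np.linalg.qr(double.T)
        angles = np.linalg.svd(qa.T @ qb, compute_uv=False)
        np.testing.assert_allclose(angles, 1.0, atol=1e-8)

    def test_rank_guard(self):
        rng = np.random.default_rng(7)
        low_rank = rng.standard_normal((10, 3)) @ rng.standard_normal((3, 400))
        with pytest.raises(ConfigurationError, match="rank"):
            concatenate_and_reduce([low_rank], n_components=8)


def _whiten(X):
    """Symmetric (rotation-free) whitening: closest white matrix to X."""
    Xc = X - X.mean(axis=1, keepdims=True)
    cov = Xc @ Xc.T / (X.shape[1] - 1)
    vals, vecs = np.linalg.eigh(cov)
    return vecs @ np.diag(vals**-0.5) @ vecs.T @ Xc


class TestInfomax:
    def test_recovers_laplacian_sources(self):
        rng = np.random.default_rng(8)
        S = rng.laplace(size=(2, 4000))
        A = rng.standard_normal((2, 2))
        Y = _whiten(A @ S)
        W = infomax_unmix(Y, seed=3)
        U = W @ Y
        corr = np.abs(np.corrcoef(S, U)[:2, 2:])
        assert max(corr[0, 0], corr[0, 1]) > 0.99
        assert max(corr[1, 0], corr[1, 1]) > 0.99

    def test_independent_input_gives_signed_permutation(self):
        rng = np.random.default_rng(9)
        Y = _whiten(rng.laplace(size=(3, 5000)))
        W = infomax_unmix(Y, seed=4)
        Wn = W / np.linalg.norm(W, axis=1, keepdims=True)
        # each unit row is dominated by a single entry (signed permutation)
        for row in Wn:
            assert np.abs(row).max() > 0.99

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(10)
        Y = _whiten(rng.laplace(size=(3, 2000)))
        np.testing.assert_array_equal(
            infomax_unmix(Y, seed=5), infomax_unmix(Y, seed=5)
        )


class TestBackProject:
    def test_noiseless_identity(self, clean_cohort, clean_decomposition):
        for i in (0, 4, 9):
            est = clean_decomposition.subject_timecourses[i]
            truth = clean_cohort.truth_timeseries[i]
            corr = np.abs(np.corrcoef(truth.T, est.T)[:5, 5:])
            assert (corr.max(axis=1) > 0.999).all()

    def test_zero_signal_subject(self, clean_decomposition):
        V = clean_decomposition.group_maps.shape[1]
        flat = Bold4D(
            np.zeros((V, 1, 1, 10)), 2.0, np.ones((V, 1, 1), bool), "flat"
        )
        tc, maps = back_project(clean_decomposition.group_maps, flat)
        np.testing.assert_allclose(tc, 0.0, atol=1e-12)

    def test_orthonormal_maps_reduce_to_inner_products(self):
        rng = np.random.default_rng(11)
        M, _ = np.linalg.qr(rng.standard_normal((300, 4)))
        M = M.T  # orthonormal rows
        X = rng.standard_normal((20, 300))
        scan = scan_from_matrix(X)
        tc, _ = back_project(M, scan)
        Xc = X - X.mean(axis=0)
        np.testing.assert_allclose(tc, Xc @ M.T, atol=1e-10)


class TestStability:
    def test_identical_seeds_give_unit_index(self, clean_decomposition):
        idx = stability_restarts(clean_decomposition.whitened, n_restarts=4,
                                 seeds=[3, 3, 3, 3])
        np.testing.assert_allclose(idx, 1.0, atol=1e-12)

    def test_clean_sources_stable(self, clean_decomposition):
        idx = stability_restarts(clean_decomposition.whitened, n_restarts=10, base_seed=5)
        assert (idx > 0.9).all()

    def test_noise_less_stable_than_signal(self, clean_decomposition):
        rng = np.random.default_rng(12)
        noise = _whiten(rng.standard_normal(clean_decomposition.whitened.shape))
        idx_noise = stability_restarts(noise, n_restarts=6, base_seed=5)
        idx_clean = stability_restarts(clean_decomposition.whitened, n_restarts=6, base_seed=5)
        assert idx_noise.mean() < idx_clean.mean()


class TestRunGroupIca:
    def test_planted_source_recovery(self, clean_cohort, clean_decomposition, match_maps):
        matched = match_maps(
            clean_cohort.truth_sources.spatial_maps, clean_decomposition.group_maps
        )
        assert (matched >= 0.95).all()

    def test_deterministic(self, clean_cohort, clean_decomposition):
        again = run_group_ica(clean_cohort.scans, n_components=5, seed=1)
        np.testing.assert_array_equal(again.group_maps, clean_decomposition.group_maps)

    def test_rank_guard_on_group(self, clean_cohort):
        with pytest.raises(ConfigurationError):
            run_group_ica(clean_cohort.scans, n_components=20, seed=1)

    def test_recovery_degrades_with_noise(self, match_maps):
        means = []
        for noise in (0.0, 1.0, 5.0):
            coh = make_cohort(
                CohortConfig(n_subjects=6, n_sources=3, grid_dims=(10, 10, 6),
                             noise_sd=noise, seed=21)
            )
            dec = run_group_ica(coh.scans, n_components=3, seed=2)
            means.append(match_maps(coh.truth_sources.spatial_maps, dec.group_maps).mean())
        assert means[0] >= means[1] >= means[2]

    def test_subject_maps_average_to_group_maps(self, clean_decomposition):
        avg = np.mean(clean_decomposition.subject_maps, axis=0)
        for k in range(5):
            r = np.corrcoef(avg[k], clean_decomposition.group_maps[k])[0, 1]
            assert abs(r) >= 0.9
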