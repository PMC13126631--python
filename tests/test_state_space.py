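import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

from afmstate.bead_model import BeadModel, Ensemble
from afmstate.fixtures import HingeSpec, make_hinge_ensemble
from afmstate.state_space import (StateModel, cluster_gmm, fit_pca,
                                  fit_state_model, load_state_model, project,
                                  save_state_model, state_rmsd_stats,
                                  superpose)


def _model(centers):
    centers = np.asarray(centers, float)
    return BeadModel(centers, np.full(len(centers), 0.4), ["ALA"] * len(centers))


class TestSuperpose:
    def test_identical_zero_rmsd(self, rng):
        m = _model(rng.normal(size=(10, 3)))
        assert superpose(m, m)[2] == pytest.approx(0.0, abs=1e-12)

    def test_translation_removed(self, rng):
        a = _model(rng.normal(size=(10, 3)))
        b = _model(a.centers + [1.0, -2.0, 3.0])
        assert superpose(a, b)[2] == pytest.approx(0.0, abs=1e-10)

    def test_rotation_removed(self):
        a = _model([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, 0, 1]])
        rot = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], float)  # 90 deg z
        b = _model(a.centers @ rot.T)
        assert superpose(a, b)[2] == pytest.approx(0.0, abs=1e-10)

    def test_degenerate_geometry_rejected(self):
        a = _model([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError):
            superpose(a, a)


class TestPca:
    def _line_ensemble(self, n=12):
        base = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        conformers = []
        for i in range(n):
            c = base.copy()
            c[0, 0] += 0.1 * i  # single mode of variation
            conformers.append(_model(c))
        return Ensemble(conformers)

    def test_single_mode_captured_by_pc1(self):
        sm = fit_pca(self._line_ensemble(), n_pc=2, align=False)
        ratio = sm.explained_variance[0] / sm.explained_variance.sum()
        assert ratio == pytest.approx(1.0, abs=1e-9)

    def test_projection_of_mean_is_zero(self):
        ens = self._line_ensemble()
        sm = fit_pca(ens, n_pc=2)
        proj = project(sm, ens)
        np.testing.assert_allclose(proj.mean(axis=0), 0.0, atol=1e-9)

    def test_explained_variance_matches_eigendecomposition(self, rng):
        """PCA variances equal the covariance eigenvalues (full
        eigendecomposition oracle), so reconstruction error is the sum of
        the discarded eigenvalues."""
        conformers = [_model(rng.normal(size=(5, 3))) for _ in range(30)]
        ens = Ensemble(conformers)
        sm = fit_pca(ens, n_pc=4, align=False)
        x = ens.coordinates().reshape(30, -1)
        xc = x - x.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(xc.T @ xc / 29))[::-1]
        np.testing.assert_allclose(sm.explained_variance, eig[:4], atol=1e-9)


class TestClusterGmm:
    def test_two_blobs_bic_selects_two(self, rng):
        """BIC picks K=2 for two 10-sigma-separated blobs; cross-checked by
        recomputing BIC from an independently fitted mixture."""
        proj = np.concatenate([
            rng.normal(-5, 1, size=(250, 3)),
            rng.normal(+5, 1, size=(250, 3)),
        ])
        base = StateModel(pca_mean=np.zeros(3), pca_components=np.eye(3), n_pc=3)
        sm = cluster_gmm(base, proj, k_range=range(1, 5), seed=0)
        assert sm.K == 2
        # independent BIC route: -2 log L + p ln n from a fresh fit
        for k in (1, 2, 3):
            g = GaussianMixture(k, covariance_type="full", n_init=5,
                                random_state=123).fit(proj)
            n, dim = proj.shape
            p = k - 1 + k * dim + k * dim * (dim + 1) // 2
            manual = -2 * g.score(proj) * n + p * np.log(n)
            assert manual == pytest.approx(g.bic(proj), rel=1e-9)

    def test_labels_ordered_by_mean_pc1(self, rng):
        proj = np.concatenate([
            rng.normal(+5, 0.5, size=(100, 2)),   # generated out of order
            rng.normal(-5, 0.5, size=(100, 2)),
        ])
        base = StateModel(pca_mean=np.zeros(2), pca_components=np.eye(2), n_pc=2)
        sm = cluster_gmm(base, proj, k_range=[2], seed=0)
        assert np.all(sm.labels[:100] == 2) and np.all(sm.labels[100:] == 1)
        assert np.all(np.diff(sm.order_key) >= 0)

    def test_center_is_nearest_to_cluster_mean(self, rng):
        proj = np.concatenate([
            rng.normal(-5, 1, size=(200, 2)),
            rng.normal(+5, 1, size=(200, 2)),
        ])
        base = StateModel(pca_mean=np.zeros(2), pca_components=np.eye(2), n_pc=2)
        sm = cluster_gmm(base, proj, k_range=[2], seed=0)
        for k in range(1, 3):
            members = np.nonzero(sm.labels == k)[0]
            mean = proj[members].mean(axis=0)
            brute = members[np.argmin(np.linalg.norm(proj[members] - mean, axis=1))]
            assert sm.centers[k - 1] == brute

    def test_relabelling_preserves_partition(self, hinge_world):
        spec, ens, planted, sm = hinge_world
        assert adjusted_rand_score(planted, sm.labels) >= 0.95

    def test_no_admissible_k_raises_with_bic_table(self, rng):
        proj = rng.normal(size=(30, 2))
        base = StateModel(pca_mean=np.zeros(2), pca_components=np.eye(2), n_pc=2)
        with pytest.raises(ValueError, match="BIC"):
            cluster_gmm(base, proj, k_range=[5], min_occupancy=20, seed=0)


class TestStateRmsdStats:
    def test_identical_conformers_zero(self):
        m = _model([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        ens = Ensemble([m.copy() for _ in range(8)])
        sm = StateModel(pca_mean=np.zeros(12), pca_components=np.eye(12)[:2],
                        n_pc=2, labels=np.array([1, 1, 1, 1, 2, 2, 2, 2]),
                        centers=np.array([0, 4]), K=2,
                        order_key=np.array([0.0, 0.0]))
        within, between = state_rmsd_stats(ens, sm)
        np.testing.assert_allclose(within, 0.0, atol=1e-12)
        np.testing.assert_allclose(between, 0.0, atol=1e-12)

    def test_translated_states_between_zero(self, rng):
        m = _model(rng.normal(size=(6, 3)))
        shifted = _model(m.centers + [5.0, 0.0, 0.0])
        ens = Ensemble([m, m.copy(), shifted, _model(shifted.centers)])
        sm = StateModel(pca_mean=np.zeros(18), pca_components=np.eye(18)[:2],
                        n_pc=2, labels=np.array([1, 1, 2, 2]),
                        centers=np.array([0, 2]), K=2,
                        order_key=np.array([0.0, 1.0]))
        _, between = state_rmsd_stats(ens, sm)
        assert between[0] == pytest.approx(0.0, abs=1e-10)

    def test_within_matches_exhaustive_pairwise(self, rng):
        """within-state mean RMSD equals the brute-force all-pairs mean."""
        spec = HingeSpec(K=2, frames_per_state=10, jitter_sigma=0.2, seed=3)
        ens, labels = make_hinge_ensemble(spec)
        sm = fit_state_model(ens, n_pc=3, k_range=[2], seed=0)
        within, _ = state_rmsd_stats(ens, sm)
        for k in (1, 2):
            members = np.nonzero(sm.labels == k)[0]
            vals = [superpose(ens[i], ens[j])[2]
                    for a, i in enumerate(members) for j in members[a + 1:]]
            assert within[k - 1] == pytest.approx(np.mean(vals), abs=1e-12)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, hinge_world):
        _, _, _, sm = hinge_world
        save_state_model(tmp_path / "sm", sm)
        back = load_state_model(tmp_path / "sm")
        assert back.K == sm.K and back.n_pc == sm.n_pc
        np.testing.assert_array_equal(back.labels, sm.labels)
        np.testing.assert_array_equal(back.centers, sm.centers)
        np.testing.assert_allclose(back.pca_components, sm.pca_components)
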