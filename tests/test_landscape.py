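import numpy as np
import pytest

from regscape.landscape import (
    ClusterModel,
    cluster_scan,
    davies_bouldin_index,
    featurize,
    fit_tica,
    free_energy_surface,
    representatives,
    silhouette_score,
    state_path,
)
from regscape.synthetic import markov_dihedral_walk


class TestFeaturize:
    def test_trig_values(self):
        phi = np.array([[0.0, 90.0]])
        psi = np.array([[45.0, -90.0]])
        f = featurize(phi, psi)
        # layout: cos(phi...), sin(phi...), cos(psi...), sin(psi...)
        assert f[0, :2] == pytest.approx([1.0, 0.0], abs=1e-12)
        assert f[0, 2:4] == pytest.approx([0.0, 1.0], abs=1e-12)

    def test_periodicity(self):
        a = featurize(np.array([[10.0]]), np.array([[20.0]]))
        b = featurize(np.array([[370.0]]), np.array([[380.0]]))
        assert np.allclose(a, b)

    def test_bounded_and_nan_columns_dropped(self):
        phi = np.array([[np.nan, 30.0], [np.nan, 60.0]])
        psi = np.array([[10.0, np.nan], [20.0, np.nan]])
        f = featurize(phi, psi)
        assert f.shape == (2, 4)
        assert np.all(np.abs(f) <= 1.0)


class TestFitTica:
    def test_two_state_markov_spectral_oracle(self, two_state_model):
        angles, _ = markov_dihedral_walk(two_state_model, 100_000, 8, seed=21)
        feats = featurize(angles[:, :, 0], angles[:, :, 1])
        model = fit_tica(feats, lag=1, n_components=2)
        lam = model.eigenvalues[0]
        assert lam == pytest.approx(0.80, abs=0.02)
        # implied timescale -tau/ln(lambda_2) = 4.48 frames
        assert model.timescales()[0] == pytest.approx(-1 / np.log(0.8), rel=0.10)

    def test_iid_noise_eigenvalues_near_zero(self, rng):
        X = rng.normal(size=(20_000, 6))
        model = fit_tica(X, lag=1, n_components=6)
        assert np.all(np.abs(model.eigenvalues) < 5 / np.sqrt(20_000))

    def test_whitening_contract(self, two_state_model):
        angles, _ = markov_dihedral_walk(two_state_model, 5000, 4, seed=3)
        feats = featurize(angles[:, :, 0], angles[:, :, 1])
        model = fit_tica(feats, lag=2, n_components=2)
        proj = model.projection
        cov = (proj - proj.mean(0)).T @ (proj - proj.mean(0)) / len(proj)
        # C0 estimated over lagged window: identity to estimation error
        assert np.allclose(cov, np.eye(2), atol=0.05)

    def test_eigenvalues_real_sorted_descending(self, two_state_model):
        angles, _ = markov_dihedral_walk(two_state_model, 3000, 4, seed=9)
        feats = featurize(angles[:, :, 0], angles[:, :, 1])
        model = fit_tica(feats, lag=1, n_components=4)
        assert np.isrealobj(model.eigenvalues)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_too_few_frames_rejected(self, rng):
        with pytest.raises(ValueError, match="frames"):
            fit_tica(rng.normal(size=(10, 3)), lag=50)

    def test_singular_without_regularization(self, rng):
        x = rng.normal(size=(500, 1))
        X = np.hstack([x, x])  # rank deficient
        with pytest.raises(np.linalg.LinAlgError):
            fit_tica(X, lag=1, regularization=0.0)


class TestFreeEnergySurface:
    def test_minimum_is_zero(self, rng):
        fes = free_energy_surface(rng.normal(size=(2000, 2)))
        assert fes.minimum() == 0.0

    def test_uniform_is_flat_inside(self, rng):
        Y = rng.uniform(-1, 1, size=(50_000, 2))
        fes = free_energy_surface(Y, grid_size=40)
        inner = fes.F[10:-10, 10:-10]
        assert np.nanmax(inner) < 0.35  # flat to within estimation noise

    def test_mixture_density_ratio_in_kt(self, rng):
        # two sharp modes with weight ratio e -> Delta F = 1 kT
        n1 = 30_000
        n2 = int(round(n1 / np.e))
        a = rng.normal(0.0, 0.05, size=(n1, 2))
        b = rng.normal(0.0, 0.05, size=(n2, 2)) + [2.0, 0.0]
        fes = free_energy_surface(np.vstack([a, b]), grid_size=100, bw_method=0.05)
        ix_a = np.argmin(np.abs(fes.x - 0.0))
        ix_b = np.argmin(np.abs(fes.x - 2.0))
        iy = np.argmin(np.abs(fes.y - 0.0))
        dF = fes.F[iy, ix_b] - fes.F[iy, ix_a]
        assert dF == pytest.approx(1.0, abs=0.1)

    def test_affine_rescaling_invariance(self, rng):
        Y = rng.normal(size=(5000, 2))
        f1 = free_energy_surface(Y, grid_size=30, bw_method=0.2)
        f2 = free_energy_surface(Y * 3.5, grid_size=30, bw_method=0.2)
        assert np.allclose(f1.F, f2.F, atol=1e-8)


FOUR_POINTS = np.array([[0.0], [0.1], [10.0], [10.1]])
FOUR_LABELS = np.array([0, 0, 1, 1])


class TestClusterMetrics:
    def test_four_point_silhouette_hand_value(self):
        # s(0): a=0.1, b=(10+10.1)/2 -> (10.05-0.1)/10.05; mean over points
        expected = np.mean(
            [
                (10.05 - 0.1) / 10.05,
                (9.95 - 0.1) / 9.95,
                (9.95 - 0.1) / 9.95,
                (10.05 - 0.1) / 10.05,
            ]
        )
        got = silhouette_score(FOUR_POINTS, FOUR_LABELS)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.990, abs=1e-3)

    def test_four_point_davies_bouldin_hand_value(self):
        # S = 0.05 each, centroids 0.05 and 10.05 -> DB = (0.05+0.05)/10.0
        got = davies_bouldin_index(FOUR_POINTS, FOUR_LABELS)
        assert got == pytest.approx(0.1 / 10.0, abs=1e-12)
        assert got == pytest.approx(0.01, abs=1e-3)

    def test_metrics_match_sklearn_oracle(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        X = rng.normal(size=(200, 2))
        labels = rng.integers(0, 3, size=200)
        assert silhouette_score(X, labels) == pytest.approx(
            sk.silhouette_score(X, labels), abs=1e-10
        )
        assert davies_bouldin_index(X, labels) == pytest.approx(
            sk.davies_bouldin_score(X, labels), abs=1e-10
        )


class TestClusterScan:
    @pytest.fixture()
    def blobs(self):
        rng = np.random.default_rng(7)
        centers = np.array([[0.0, 0.0], [8.0, 0.0], [0.0, 8.0]])
        return np.vstack(
            [rng.normal(c, 0.4, size=(120, 2)) for c in centers]
        )

    def test_three_blobs_select_k3_high_silhouette(self, blobs):
        models, k = cluster_scan(blobs, k_range=range(2, 8))
        assert k == 3
        assert models[3].silhouette > 0.8

    def test_sparse_clusters_dropped_from_retained(self, blobs):
        outliers = np.array([[50.0, 50.0], [50.2, 50.0]])
        models, _ = cluster_scan(
            np.vstack([blobs, outliers]), k_range=[4], min_population=10
        )
        m = models[4]
        assert len(m.retained) == 3  # the 2-point cluster is not retained

    def test_labels_permutation_consistency(self, blobs, rng):
        perm = rng.permutation(len(blobs))
        models, _ = cluster_scan(blobs[perm], k_range=[3])
        base, _ = cluster_scan(blobs, k_range=[3])
        # un-permuted labelling equals the base labelling up to renaming
        a = base[3].labels
        b = np.empty_like(a)
        b[perm] = models[3].labels
        import pandas as pd

        mapping = pd.crosstab(a, b).idxmax(axis=1)
        assert np.array_equal(mapping[a].to_numpy(), b)


class TestRepresentatives:
    def test_medoid_matches_brute_force(self, rng):
        Y = rng.normal(size=(40, 2))
        labels = np.repeat([0, 1], 20)
        model = ClusterModel(
            k=2, labels=labels, silhouette=0.0, davies_bouldin=0.0, retained=[0, 1]
        )
        meds = representatives(model, Y)
        for c in (0, 1):
            idx = np.flatnonzero(labels == c)
            sums = [
                sum(np.linalg.norm(Y[i] - Y[j]) for j in idx) for i in idx
            ]
            assert meds[c] == idx[int(np.argmin(sums))]

    def test_singleton_cluster_is_its_own_medoid(self):
        Y = np.array([[0.0, 0], [5.0, 5], [5.1, 5]])
        labels = np.array([0, 1, 1])
        model = ClusterModel(
            k=2, labels=labels, silhouette=0, davies_bouldin=0, retained=[0, 1]
        )
        assert representatives(model, Y)[0] == 0

    def test_symmetric_tie_broken_by_lowest_index(self):
        Y = np.array([[0.0, 0], [1.0, 0]])
        model = ClusterModel(
            k=1, labels=np.array([0, 0]), silhouette=0, davies_bouldin=0, retained=[0]
        )
        assert representatives(model, Y)[0] == 0


class TestStatePath:
    def test_constant_labels(self):
        out = state_path(np.zeros(10, dtype=int), window=3)
        assert np.allclose(out[0], 1.0)

    def test_alternating_window_two(self):
        labels = np.array([0, 1] * 10)
        out = state_path(labels, window=2)
        assert np.allclose(out[0], 0.5) and np.allclose(out[1], 0.5)

    def test_window_one_is_indicator(self):
        labels = np.array([0, 1, 1, 0])
        out = state_path(labels, window=1)
        assert np.array_equal(out[1], [0.0, 1.0, 1.0, 0.0])
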