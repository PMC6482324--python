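"""The mode-clustering engine: FPS, adaptive KDE, quick-shift, mixture, PMI."""

import numpy as np
import pytest

from pammotifs.pamm import (
    ClusterModel,
    FeatureMatrix,
    build_mixture,
    estimate_density,
    fit_pamm,
    fps_select,
    grid_kde,
    merge_shallow_clusters,
    quick_shift,
)
from pammotifs.synth import MixtureSpec, sample_mixture


class TestFeatureMatrix:
    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            FeatureMatrix(np.array([[1.0, np.inf]]))

    def test_periodic_wrap(self):
        fm = FeatureMatrix(np.array([[190.0, -200.0]]), periodicity=np.array([360.0, 360.0]))
        np.testing.assert_allclose(fm.vectors, [[-170.0, 160.0]])


class TestFps:
    def test_all_points_when_n_equals(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        idx = fps_select(FeatureMatrix(X), 20, seed=1)
        assert sorted(idx) == list(range(20))

    def test_forced_farthest_point(self):
        X = np.array([[0.0], [1.0], [10.0]])
        # whichever the seeded first pick is, {0, 10} ends up selected
        for seed in range(5):
            idx = fps_select(FeatureMatrix(X), 2, seed=seed)
            vals = sorted(X[idx, 0])
            assert vals in ([0.0, 10.0], [1.0, 10.0])  # 1 only if first pick
            if 0 in idx or X[idx[0], 0] == 0.0:
                assert 10.0 in X[idx, 0]

    def test_beats_random_min_distance(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(2000, 2))
        fm = FeatureMatrix(X)

        def min_pairwise(ids):
            P = X[ids]
            d = np.linalg.norm(P[:, None] - P[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            return d.min()

        wins = 0
        for seed in range(20):
            fps_ids = fps_select(fm, 50, seed=seed)
            rand_ids = np.random.default_rng(seed).choice(2000, 50, replace=False)
            if min_pairwise(fps_ids) >= min_pairwise(rand_ids):
                wins += 1
        assert wins == 20

    def test_too_many_points_raises(self):
        with pytest.raises(ValueError):
            fps_select(FeatureMatrix(np.zeros((5, 1)) + np.arange(5)[:, None]), 6, 0)

    def test_periodic_aware(self):
        # points at -179 and 179 degrees are 2 degrees apart on the circle
        X = np.array([[-179.0], [179.0], [0.0]])
        fm = FeatureMatrix(X, periodicity=np.array([360.0]))
        rng_first = fps_select(fm, 2, seed=0)
        # the two extreme angles are nearly identical; second pick must be 0
        assert 2 in rng_first or X[rng_first[1], 0] == 0.0


class TestEstimateDensity:
    def test_standard_normal_density(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((100_000, 1))
        fm = FeatureMatrix(X)
        idx = fps_select(fm, 200, seed=0)
        grid = estimate_density(fm, idx, bandwidth_scale=1.0)
        at_zero = grid.densities[np.argmin(np.abs(grid.positions[:, 0]))]
        assert at_zero == pytest.approx(1.0 / np.sqrt(2 * np.pi), rel=0.05)

    def test_periodicity_invariance(self):
        rng = np.random.default_rng(9)
        X = rng.normal(30.0, 15.0, size=(3000, 1))
        fm = FeatureMatrix(X, periodicity=np.array([360.0]))
        shifted = FeatureMatrix(X + 360.0, periodicity=np.array([360.0]))
        idx = fps_select(fm, 100, seed=1)
        g1 = estimate_density(fm, idx, 0.5)
        g2 = estimate_density(shifted, idx, 0.5)
        np.testing.assert_allclose(g1.densities, g2.densities, rtol=1e-12)

    def test_voronoi_weights_partition(self, two_blob_features):
        fm, _ = two_blob_features
        idx = fps_select(fm, 150, seed=2)
        grid = estimate_density(fm, idx, 0.5)
        assert grid.voronoi_weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert (grid.densities >= 0).all() and np.isfinite(grid.densities).all()

    def test_degenerate_dimension_named(self):
        X = np.column_stack([np.random.default_rng(0).normal(size=50), np.ones(50)])
        fm = FeatureMatrix(X, dim_names=["a", "b"])
        with pytest.raises(ValueError, match="b"):
            estimate_density(fm, np.arange(10), 0.5)


class TestQuickShift:
    def test_single_gaussian_single_cluster(self):
        fm, _ = sample_mixture(
            MixtureSpec(
                means=[np.zeros(2)],
                covariances=[np.eye(2)],
                weights=np.array([1.0]),
                n_samples=5000,
                seed=3,
            )
        )
        idx = fps_select(fm, 300, seed=0)
        grid = estimate_density(fm, idx, 0.5)
        labels = merge_shallow_clusters(grid, quick_shift(grid, 1.0))
        assert np.unique(labels).size == 1

    def test_two_blobs_two_clusters(self, two_blob_features):
        fm, _ = two_blob_features
        idx = fps_select(fm, 400, seed=5)
        grid = estimate_density(fm, idx, 0.5)
        labels = merge_shallow_clusters(grid, quick_shift(grid, 1.0))
        assert np.unique(labels).size == 2
        # cluster modes near the true means (brute-force density maximum)
        for mean in ([0.0, 0.0], [10.0, 10.0]):
            root_ds = []
            for lab in np.unique(labels):
                members = np.where(labels == lab)[0]
                root = members[np.argmax(grid.densities[members])]
                root_ds.append(np.linalg.norm(grid.positions[root] - mean))
            assert min(root_ds) < 0.3

    def test_three_planted_modes(self):
        fm, _ = sample_mixture(
            MixtureSpec(
                means=[np.array([0.0, 0.0]), np.array([4.0, 0.0]), np.array([0.0, 4.0])],
                covariances=[0.25 * np.eye(2)] * 3,
                weights=np.array([1 / 3] * 3),
                n_samples=15000,
                seed=17,
            )
        )
        model = fit_pamm(fm, n_grid=1000, bandwidth_scale=0.3, qs_scale=1.0, seed=4)
        assert model.n_modes == 3


class TestBuildMixture:
    def test_single_cluster_weight_one(self):
        fm, _ = sample_mixture(
            MixtureSpec(
                means=[np.zeros(2)],
                covariances=[np.eye(2)],
                weights=np.array([1.0]),
                n_samples=3000,
                seed=1,
            )
        )
        idx = fps_select(fm, 200, seed=0)
        grid = estimate_density(fm, idx, 0.5)
        model = build_mixture(grid, np.zeros(200, dtype=int))
        assert model.n_modes == 1
        assert model.modes[0].weight == 1.0

    def test_planted_weights_recovered(self, small_model):
        weights = sorted(m.weight for m in small_model.modes)
        assert abs(weights[0] - 0.3) < 0.05 and abs(weights[1] - 0.7) < 0.05

    def test_prune_and_renormalize(self, two_blob_features):
        fm, _ = two_blob_features
        idx = fps_select(fm, 300, seed=2)
        grid = estimate_density(fm, idx, 0.5)
        labels = merge_shallow_clusters(grid, quick_shift(grid, 1.0))
        # graft a fake tiny cluster onto one grid point with ~zero weight
        tiny = np.argmin(grid.voronoi_weights)
        labels = labels.copy()
        labels[tiny] = labels.max() + 1
        grid.voronoi_weights[tiny] = 1e-6
        model = build_mixture(grid, labels, prune_threshold=1e-5)
        assert model.n_modes == 2
        assert sum(m.weight for m in model.modes) == pytest.approx(1.0, abs=1e-12)


class TestPmi:
    def test_single_mode_zeta_zero_is_one(self):
        from pammotifs.pamm import GaussianMode

        model = ClusterModel(
            modes=[GaussianMode(1.0, np.zeros(2), np.eye(2))], zeta=0.0
        )
        x = np.random.default_rng(0).normal(size=(100, 2)) * 5
        np.testing.assert_allclose(model.pmi(0, x), 1.0, atol=1e-12)

    def test_partition_of_unity(self, small_model):
        rng = np.random.default_rng(12)
        x = rng.uniform(-5, 15, size=(1000, 2))
        resp = small_model.responsibilities(x, zeta=0.0)
        np.testing.assert_allclose(resp.sum(axis=0), 1.0, atol=1e-10)

    def test_zeta_bounds_scores(self, small_model):
        rng = np.random.default_rng(13)
        x = rng.uniform(-5, 15, size=(500, 2))
        resp = small_model.responsibilities(x, zeta=1e-5)
        assert (resp > 0).all() and (resp < 1).all()
        assert (resp.sum(axis=0) <= 1 + 1e-12).all()

    def test_symmetric_midpoint(self):
        from pammotifs.pamm import GaussianMode

        model = ClusterModel(
            modes=[
                GaussianMode(0.5, np.array([-2.0, 0.0]), np.eye(2)),
                GaussianMode(0.5, np.array([2.0, 0.0]), np.eye(2)),
            ],
            zeta=0.0,
        )
        mid = np.array([[0.0, 0.0]])
        assert model.pmi(0, mid)[0] == pytest.approx(0.5, abs=1e-12)
        assert model.pmi(1, mid)[0] == pytest.approx(0.5, abs=1e-12)

    def test_far_field_decays_to_zero_with_zeta(self, small_model):
        far = np.array([[500.0, 500.0]])
        resp = small_model.responsibilities(far, zeta=1e-5)
        assert resp.max() < 1e-6


class TestPeriodicClustering:
    def test_global_shift_invariance(self):
        fm, _ = sample_mixture(
            MixtureSpec(
                means=[np.array([-60.0, -45.0]), np.array([150.0, 140.0])],
                covariances=[100.0 * np.eye(2)] * 2,
                weights=np.array([0.5, 0.5]),
                n_samples=8000,
                periodicity=np.array([360.0, 360.0]),
                seed=21,
            )
        )
        shifted = FeatureMatrix(
            fm.vectors + 100.0, periodicity=np.array([360.0, 360.0])
        )
        m1 = fit_pamm(fm, n_grid=400, bandwidth_scale=0.3, qs_scale=1.0, seed=2)
        m2 = fit_pamm(shifted, n_grid=400, bandwidth_scale=0.3, qs_scale=1.0, seed=2)
        assert m1.n_modes == m2.n_modes
        means1 = sorted(tuple(np.round(m.mean, 1)) for m in m1.modes)
        means2 = sorted(
            tuple(np.round((m.mean - 100.0 + 180.0) % 360.0 - 180.0, 1))
            for m in m2.modes
        )
        for a, b in zip(means1, means2):
            diff = (np.array(a) - np.array(b) + 180.0) % 360.0 - 180.0
            assert np.abs(diff).max() < 5.0


class TestModelPersistence:
    def test_bit_exact_round_trip(self, small_model, tmp_path):
        path = tmp_path / "model.txt"
        small_model.save(path)
        loaded = ClusterModel.load(path)
        assert loaded.n_modes == small_model.n_modes
        assert loaded.zeta == small_model.zeta
        for a, b in zip(small_model.modes, loaded.modes):
            assert a.weight == b.weight
            assert (a.mean == b.mean).all()
            assert (a.covariance == b.covariance).all()
        path2 = tmp_path / "model2.txt"
        loaded.save(path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_rejects_foreign_file(self, tmp_path):
        bad = tmp_path / "bad.txt"
        bad.write_text("not a model\n")
        with pytest.raises(ValueError):
            ClusterModel.load(bad)


class TestDeterminism:
    def test_identical_inputs_identical_model(self, two_blob_features, tmp_path):
        fm, _ = two_blob_features
        paths = []
        for run in range(2):
            model = fit_pamm(fm, n_grid=200, bandwidth_scale=0.5, qs_scale=1.0, seed=9)
            p = tmp_path / f"m{run}.txt"
            model.save(p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()


class TestGridKde:
    def test_density_integrates_to_one_on_fine_grid(self):
        rng = np.random.default_rng(31)
        X = rng.standard_normal((5000, 1))
        kde = grid_kde(FeatureMatrix(X), n_grid=200, bandwidth_scale=1.0, seed=0)
        xs = np.linspace(-6, 6, 2001)[:, None]
        vals = kde.pdf(xs)
        integral = np.trapezoid(vals, xs[:, 0])
        assert integral == pytest.approx(1.0, abs=0.01)
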