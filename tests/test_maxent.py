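import numpy as np
import pytest

from invasion_hotspots.climate import BioclimStack
from invasion_hotspots.grid import GridSpec
from invasion_hotspots.maxent import (
    FeatureSet,
    build_features,
    cross_validate,
    default_betas,
    fit,
    kkt_residual,
    penalized_loglik,
    predict,
)


def tiny_problem(seed=0, n_pres=12, n_bg=40, n_pred=6):
    rng = np.random.default_rng(seed)
    X_bg = rng.uniform(0, 1, (n_bg, n_pred))
    X_pres = rng.uniform(0.3, 0.9, (n_pres, n_pred))
    return build_features(X_pres, X_bg, [f"p{i}" for i in range(n_pred)])


class TestBuildFeatures:
    def test_27_features_for_6_predictors(self):
        fs, F_pres, F_bg = tiny_problem()
        assert fs.n_features == 27  # 6 linear + 6 quadratic + 15 products
        assert F_pres.shape[1] == F_bg.shape[1] == 27

    def test_scaling_maps_training_extremes_to_unit_interval(self):
        fs, F_pres, F_bg = tiny_problem()
        F_all = np.vstack([F_pres, F_bg])
        np.testing.assert_allclose(F_all.min(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(F_all.max(axis=0), 1.0, atol=1e-12)

    def test_constant_predictor_features_dropped(self, caplog):
        rng = np.random.default_rng(1)
        X_pres = rng.uniform(0, 1, (10, 3))
        X_bg = rng.uniform(0, 1, (30, 3))
        X_pres[:, 1] = 0.5
        X_bg[:, 1] = 0.5
        with caplog.at_level("WARNING"):
            fs, _, _ = build_features(X_pres, X_bg, ["a", "b", "c"])
        # of the 9 candidates (3+3+3), b loses linear, quadratic and both
        # products involving it: 5 remain
        assert fs.n_features == 5
        assert all("b" not in lab for lab in fs.labels())

    def test_too_few_presences_rejected(self):
        with pytest.raises(ValueError, match="presence"):
            build_features(np.ones((1, 2)), np.random.default_rng(0).uniform(size=(5, 2)), ["a", "b"])


class TestFit:
    def test_no_signal_gives_near_zero_weights(self):
        # presence sample == background sample: nothing to separate
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (40, 3))
        fs, F_pres, F_bg = build_features(X, X, ["a", "b", "c"])
        model = fit(fs, F_pres, F_bg)
        assert np.all(np.abs(model.lambdas) <= 1e-4)
        surf = model.scores(F_bg)
        assert np.ptp(surf) / surf.mean() < 1e-3  # near-uniform output

    def test_single_feature_matches_grid_search_oracle(self):
        # 8-cell landscape, one linear feature, 4 presences: brute force
        # the penalized objective on a dense lambda grid
        f_land = np.array([0.0, 0.1, 0.3, 0.4, 0.55, 0.7, 0.9, 1.0])[:, None]
        f_pres = np.array([0.55, 0.7, 0.9, 1.0])[:, None]
        fs = FeatureSet(("x",), [("linear", 0)], np.zeros(1), np.ones(1))
        betas = np.array([0.05])
        f_bg = np.array([0.0, 0.1, 0.3, 0.4])[:, None]
        model = fit(fs, f_pres, f_bg, betas=betas)
        grid = np.arange(-10, 10, 0.01)
        objs = [penalized_loglik(np.array([g]), f_pres, f_land, betas) for g in grid]
        best = grid[int(np.argmax(objs))]
        assert model.lambdas[0] == pytest.approx(best, abs=1e-2)

    def test_kkt_conditions_at_optimum(self):
        fs, F_pres, F_bg = tiny_problem(seed=3)
        model = fit(fs, F_pres, F_bg)
        F_land = np.vstack([F_pres, F_bg])
        q = model.scores(F_land)
        q = q / q.sum()
        gap = np.abs(q @ F_land - F_pres.mean(axis=0))
        assert np.all(gap <= model.betas + 1e-6)
        active = model.lambdas != 0
        assert np.all(np.abs(gap[active] - model.betas[active]) <= 1e-4)

    def test_distribution_sums_to_one(self):
        fs, F_pres, F_bg = tiny_problem(seed=4)
        model = fit(fs, F_pres, F_bg)
        q = model.scores(np.vstack([F_pres, F_bg]))
        assert q.sum() == pytest.approx(1.0, abs=1e-9)

    def test_regularization_path_monotone(self):
        fs, F_pres, F_bg = tiny_problem(seed=5, n_pres=30, n_bg=100)
        norms = []
        for mult in (0.5, 1.0, 2.0, 4.0):
            model = fit(fs, F_pres, F_bg, beta_multiplier=mult)
            norms.append(np.abs(model.lambdas).sum())
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_huge_beta_kills_all_weights(self):
        fs, F_pres, F_bg = tiny_problem(seed=6)
        model = fit(fs, F_pres, F_bg, beta_multiplier=1e6)
        np.testing.assert_array_equal(model.lambdas, 0.0)

    def test_default_beta_schedule_interpolates_on_sample_size(self):
        rng = np.random.default_rng(0)
        F_small = rng.uniform(0, 1, (10, 4))
        F_large = rng.uniform(0, 1, (200, 4))
        b_small = default_betas(F_small, 1.0)
        b_large = default_betas(F_large, 1.0)
        assert b_small.mean() > b_large.mean()
        np.testing.assert_allclose(default_betas(F_small, 2.0), 2 * b_small)


def grid_bioclim(seed=0, rows=5, cols=6):
    rng = np.random.default_rng(seed)
    grid = GridSpec(rows, cols, 0.0, rows * 0.5, 0.5)
    layers = {
        "MAT": rng.uniform(5, 20, grid.shape),
        "MTWM": rng.uniform(25, 35, grid.shape),
        "MTCM": rng.uniform(-5, 5, grid.shape),
        "AP": rng.uniform(300, 1200, grid.shape),
        "PS": rng.uniform(10, 60, grid.shape),
        "TCF": rng.uniform(10, 70, grid.shape),
    }
    return BioclimStack(grid, layers)


class TestPredict:
    def test_all_zero_lambdas_give_uniform_raw(self):
        bc = grid_bioclim()
        rows, cols = np.nonzero(bc.valid)
        X = bc.matrix(rows, cols)
        fs, F_pres, F_bg = build_features(X[:4], X)
        model = fit(fs, F_pres[:4], F_bg, beta_multiplier=1e6)  # forces lambdas to 0
        surf = predict(model, bc)
        np.testing.assert_allclose(surf.raw[bc.valid], 1.0 / bc.grid.n_cells, atol=1e-12)

    def test_monotone_in_single_positive_feature(self):
        bc = grid_bioclim(seed=2)
        fs = FeatureSet(("MAT",), [("linear", 0)], np.array([5.0]), np.array([20.0]))
        from invasion_hotspots.maxent import MaxEntModel

        model = MaxEntModel(
            fs, np.array([3.0]), np.array([0.1]), 1.0, normalizer=0.0, entropy=1.0, converged=True
        )
        # feature set over MAT only: patch a single-predictor stack view
        rows, cols = np.nonzero(bc.valid)
        F, _ = fs.transform(bc["MAT"][rows, cols][:, None], clamp=True)
        scores = model.scores(F)
        order_scores = np.argsort(scores)
        order_mat = np.argsort(bc["MAT"][rows, cols])
        np.testing.assert_array_equal(order_scores, order_mat)

    def test_clamped_cell_count(self):
        bc = grid_bioclim(seed=3)
        rows, cols = np.nonzero(bc.valid)
        X = bc.matrix(rows, cols)
        # train only on a subset with restricted MAT range so projection clamps
        train = X[X[:, 0] < np.median(X[:, 0])]
        fs, F_pres, F_bg = build_features(train[:5], train)
        model = fit(fs, F_pres, F_bg)
        surf = predict(model, bc)
        raw = fs.raw_features(X)
        scaled = (raw - fs.lo) / (fs.hi - fs.lo)
        expected = int(np.sum(np.any((scaled < 0) | (scaled > 1), axis=1)))
        assert surf.n_clamped_cells == expected
        assert expected > 0

    def test_missing_layer_rejected_by_name(self):
        bc = grid_bioclim()
        del bc.layers["PS"]
        with pytest.raises(ValueError, match="PS"):
            BioclimStack(bc.grid, bc.layers)

    def test_serialization_roundtrip(self):
        from invasion_hotspots.maxent import MaxEntModel

        fs, F_pres, F_bg = tiny_problem(seed=7)
        model = fit(fs, F_pres, F_bg)
        back = MaxEntModel.from_json(model.to_json())
        np.testing.assert_array_equal(back.lambdas, model.lambdas)
        np.testing.assert_allclose(back.scores(F_bg), model.scores(F_bg))


class TestCrossValidate:
    def test_folds_partition_presences(self):
        fs, F_pres, F_bg = tiny_problem(seed=8, n_pres=100)
        results = cross_validate(fs, F_pres, F_bg, k=5, seed=1)
        assert len(results) == 5
        all_test = np.concatenate([idx for _, idx in results])
        assert len(all_test) == 100
        assert len(np.unique(all_test)) == 100  # disjoint, union = all
        assert all(len(idx) == 20 for _, idx in results)

    def test_same_seed_same_folds(self):
        fs, F_pres, F_bg = tiny_problem(seed=9, n_pres=30)
        a = cross_validate(fs, F_pres, F_bg, k=3, seed=4)
        b = cross_validate(fs, F_pres, F_bg, k=3, seed=4)
        for (_, ia), (_, ib) in zip(a, b):
            np.testing.assert_array_equal(ia, ib)

    def test_k_exceeding_presences_rejected(self):
        fs, F_pres, F_bg = tiny_problem(seed=10, n_pres=4)
        with pytest.raises(ValueError):
            cross_validate(fs, F_pres, F_bg, k=10, seed=0)
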