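"""Epsilon-SVR fitting, cross-validated grid search and model persistence."""

import numpy as np
import pytest

from aliqa.qa_model import (
    DEFAULT_FOLDS,
    MULTI_GRID,
    PAIRWISE_GRID,
    HyperParams,
    LabeledDataset,
    SchemaMismatchError,
    TrainedModel,
    fit_svr,
    grid_search_cv,
    load_model,
    predict,
    save_model,
)
from aliqa.synthetic import SimulationParams, simulate_pairwise_dataset


def _dataset(X, y, schema="pairwise"):
    n, d = X.shape
    return LabeledDataset(
        record_ids=tuple(f"r{i}" for i in range(n)),
        target_ids=tuple(f"T{i // 5}" for i in range(n)),
        X=X,
        y=y,
        schema=schema,
        feature_names=tuple(f"f{j}" for j in range(d)),
    )


@pytest.fixture(scope="module")
def synth500():
    _, ds = simulate_pairwise_dataset(SimulationParams(n=500, seed=7, noise_sigma=0.05))
    return ds


class TestDefaultGrids:
    def test_pairwise_grid_is_6x6x8_with_5_folds(self):
        assert len(PAIRWISE_GRID["w"]) == 6
        assert len(PAIRWISE_GRID["c"]) == 6
        assert len(PAIRWISE_GRID["g"]) == 8
        assert PAIRWISE_GRID["w"] == (0.5, 0.2, 0.1, 0.05, 0.02, 0.01)
        assert PAIRWISE_GRID["c"] == (2.0, 1.0, 0.5, 0.1, 0.05, 0.01)
        assert PAIRWISE_GRID["g"] == (0.5, 0.3, 0.2, 0.1, 0.05, 0.01, 0.005, 0.001)
        assert DEFAULT_FOLDS["pairwise"] == 5

    def test_multi_grid_with_10_folds(self):
        assert MULTI_GRID["w"] == (0.1, 0.08, 0.06, 0.05, 0.02, 0.01)
        assert MULTI_GRID["c"] == (2.0, 1.0, 0.5, 0.1, 0.05, 0.01)
        assert MULTI_GRID["g"] == (0.5, 0.4, 0.3, 0.2, 0.1, 0.05, 0.01, 0.005, 0.001)
        assert DEFAULT_FOLDS["multi"] == 10


class TestFitPredict:
    def test_constant_labels_predict_the_constant(self):
        rng = np.random.default_rng(0)
        ds = _dataset(rng.normal(size=(40, 4)), np.full(40, 0.5))
        model = fit_svr(ds, HyperParams(0.1, 1.0, 0.5))
        assert predict(model, rng.normal(size=(10, 4))) == pytest.approx(np.full(10, 0.5))

    def test_epsilon_tube_contract(self):
        X = np.tile([0.3, 0.4, 0.5, 0.6], (10, 1))
        ds = _dataset(X, np.full(10, 0.8))
        w = 0.05
        model = fit_svr(ds, HyperParams(w, 1.0, 0.5))
        pred = predict(model, X[:1])[0]
        assert abs(pred - 0.8) <= w + 1e-9

    def test_noise_floor_bounds_heldout_rmse(self, synth500):
        train, test = synth500.subset(np.arange(400)), synth500.subset(np.arange(400, 500))
        model = fit_svr(train, HyperParams(0.02, 1.0, 0.5))
        err = predict(model, test.X) - test.y
        assert np.sqrt(np.mean(err**2)) <= 0.07  # sigma = 0.05 noise floor

    def test_prediction_near_training_label_in_low_noise(self):
        _, ds = simulate_pairwise_dataset(SimulationParams(n=200, seed=3, noise_sigma=0.01))
        model = fit_svr(ds, HyperParams(0.02, 2.0, 0.5))
        pred = predict(model, ds.X)
        inside = np.abs(pred - ds.y) <= 0.02 + 0.01
        assert inside.mean() > 0.9  # most rows within tube width + margin of their label

    def test_clipping_to_unit_interval(self):
        model = TrainedModel(
            schema="pairwise",
            feature_names=("f0",),
            hyperparams=HyperParams(0.1, 1.0, 0.5),
            scale_min=np.zeros(1),
            scale_max=np.ones(1),
            support_vectors=np.zeros((0, 1)),
            dual_coef=np.zeros(0),
            intercept=1.07,
            matrix_ids=("BLOSUM62",),
        )
        assert predict(model, np.array([[0.5]]))[0] == 1.0

    def test_too_few_rows(self):
        ds = _dataset(np.zeros((1, 2)), np.array([0.5]))
        with pytest.raises(ValueError, match="at least 2"):
            fit_svr(ds, HyperParams(0.1, 1.0, 0.5))

    def test_schema_mismatch_named_in_error(self):
        ds = _dataset(np.random.default_rng(1).normal(size=(10, 4)), np.full(10, 0.5))
        model = fit_svr(ds, HyperParams(0.1, 1.0, 0.5))
        with pytest.raises(SchemaMismatchError, match="pairwise.*multi"):
            predict(model, ds.X, schema="multi")

    def test_nonpositive_hyperparams_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            HyperParams(0.0, 1.0, 0.5)


SMALL_GRID = {"w": (0.1, 0.02), "c": (1.0,), "g": (0.5, 0.05)}


class TestGridSearch:
    def test_deterministic_for_fixed_seed(self, synth500):
        ds = synth500.subset(np.arange(120))
        a = grid_search_cv(ds, grid=SMALL_GRID, k=5, seed=11)
        b = grid_search_cv(ds, grid=SMALL_GRID, k=5, seed=11)
        assert a == b

    def test_best_beats_worst(self, synth500):
        ds = synth500.subset(np.arange(150))
        report = grid_search_cv(ds, grid=SMALL_GRID, k=5, seed=2)
        rmses = [r for _, r, _ in report.grid_results]
        assert report.mean_rmse == min(rmses) <= max(rmses)

    def test_mean_equals_mean_of_folds(self, synth500):
        ds = synth500.subset(np.arange(100))
        report = grid_search_cv(ds, grid=SMALL_GRID, k=4, seed=5)
        assert report.mean_rmse == pytest.approx(np.mean(report.fold_rmse))
        assert report.mean_abs == pytest.approx(np.mean(report.fold_abs))

    def test_group_by_target_keeps_targets_whole(self, synth500):
        # grouped CV must still run and stay deterministic
        ds = synth500.subset(np.arange(100))
        a = grid_search_cv(ds, grid=SMALL_GRID, k=5, seed=1, group_by_target=True)
        b = grid_search_cv(ds, grid=SMALL_GRID, k=5, seed=1, group_by_target=True)
        assert a == b

    def test_more_label_noise_never_helps(self):
        """Best CV RMSE is non-decreasing in the label noise level."""
        grid = {"w": (0.02,), "c": (1.0,), "g": (0.5,)}
        for seed in (1, 2, 3):
            best = []
            for sigma in (0.02, 0.05, 0.1):
                _, ds = simulate_pairwise_dataset(
                    SimulationParams(n=150, seed=seed, noise_sigma=sigma)
                )
                best.append(grid_search_cv(ds, grid=grid, k=5, seed=seed).mean_rmse)
            assert best[0] <= best[1] <= best[2]

    def test_fewer_rows_than_folds(self, synth500):
        with pytest.raises(ValueError, match="fewer rows"):
            grid_search_cv(synth500.subset(np.arange(3)), grid=SMALL_GRID, k=5, seed=0)


class TestPersistence:
    def test_round_trip_is_bit_exact(self, synth500, tmp_path):
        ds = synth500.subset(np.arange(150))
        model = fit_svr(ds, HyperParams(0.02, 1.0, 0.5))
        path = tmp_path / "m.aliqa"
        save_model(model, path)
        loaded = load_model(path)
        probe = np.random.default_rng(9).uniform(size=(100, 4))
        assert np.array_equal(predict(model, probe), predict(loaded, probe))

    def test_truncated_file_is_an_explicit_error(self, synth500, tmp_path):
        ds = synth500.subset(np.arange(50))
        model = fit_svr(ds, HyperParams(0.1, 1.0, 0.5))
        path = tmp_path / "m.aliqa"
        save_model(model, path)
        path.write_text(path.read_text()[: len(path.read_text()) // 2])
        with pytest.raises(ValueError, match="not a parsable model file"):
            load_model(path)

    def test_format_version_checked(self, tmp_path):
        path = tmp_path / "bad.aliqa"
        path.write_text('{"format": "aliqa-model/99"}')
        with pytest.raises(ValueError, match="unsupported model format"):
            load_model(path)

    def test_matrix_provenance_warning(self, synth500, tmp_path):
        ds = synth500.subset(np.arange(50))
        model = fit_svr(ds, HyperParams(0.1, 1.0, 0.5))
        path = tmp_path / "m.aliqa"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.matrix_ids == ("BLOSUM62",)
        with pytest.warns(UserWarning, match="trained with"):
            predict(loaded, ds.X[:2], matrix_ids=("GONNET160",))
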