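"""Splitting, network training, grid search, prediction."""

import numpy as np
import pandas as pd
import pytest
from sklearn.neural_network import MLPClassifier

import meltid as m
from meltid.classifier import (GridSearchSpec, NetConfig, SplitSpec,
                               default_search_grid, grid_search, load_model,
                               predict, save_model, split_corpus, train_fann)
from meltid.features import FeatureMatrix, build_matrix
from meltid.signatures import process_run

from conftest import simulate_small_corpus


def toy_matrix(labels, seed=0, n_features=6):
    rng = np.random.default_rng(seed)
    centers = {l: rng.normal(0, 5, n_features) for l in sorted(set(labels))}
    values = np.vstack([centers[l] + rng.normal(0, 0.1, n_features)
                        for l in labels])
    ids = [f"r{i:03d}" for i in range(len(labels))]
    return FeatureMatrix(ids, ids, list(labels),
                         [f"f{j}" for j in range(n_features)], values)


@pytest.fixture(scope="module")
def separable_corpus(panel):
    """Two well-separated species, 40 zero-noise runs each."""
    by = {p.species_name: p for p in panel}
    models = [by["Alopias pelagicus"], by["Sphyrna lewini"]]
    grid = m.AcquisitionGrid(n_points=256)
    runs = simulate_small_corpus(models, grid, m.NoiseModel.zero(),
                                 n_specimens=20, replicates=2, seed=0)
    return build_matrix([process_run(r) for r in runs])


class TestSplitCorpus:
    def test_partition_is_disjoint_and_exhaustive(self, separable_corpus):
        tr, va = split_corpus(separable_corpus, SplitSpec(seed=0))
        assert len(tr.run_ids) + len(va.run_ids) == len(separable_corpus.run_ids)
        assert not set(tr.run_ids) & set(va.run_ids)

    def test_exact_seventy_thirty_on_ten_rows(self):
        mat = toy_matrix(["A"] * 10)
        tr, va = split_corpus(mat, SplitSpec(train_fraction=0.7, seed=1))
        assert (len(tr.run_ids), len(va.run_ids)) == (7, 3)

    def test_per_species_proportions_within_one_row(self, desk_corpus):
        mat = build_matrix(desk_corpus["retained"])
        tr, va = split_corpus(mat, SplitSpec(seed=0))
        assert len(tr.run_ids) + len(va.run_ids) == 357
        tr_counts = pd.Series(tr.labels).value_counts()
        all_counts = pd.Series(mat.labels).value_counts()
        for species, n in all_counts.items():
            assert abs(tr_counts.get(species, 0) - 0.7 * n) <= 1.0

    def test_same_seed_identical_partition(self, separable_corpus):
        a = split_corpus(separable_corpus, SplitSpec(seed=5))
        b = split_corpus(separable_corpus, SplitSpec(seed=5))
        assert a[0].run_ids == b[0].run_ids

    def test_singleton_stratum_warns_and_goes_to_train(self):
        mat = toy_matrix(["A"] * 6 + ["B"])
        with pytest.warns(UserWarning, match="single"):
            tr, va = split_corpus(mat, SplitSpec(seed=0))
        assert "B" in tr.labels and "B" not in va.labels

    def test_group_mode_keeps_specimens_together(self, desk_corpus):
        mat = build_matrix(desk_corpus["retained"])
        tr, va = split_corpus(mat, SplitSpec(seed=0, group_by_specimen=True))
        assert not set(tr.specimen_ids) & set(va.specimen_ids)


class TestTrainFann:
    def test_separable_species_reach_perfect_validation(self, separable_corpus):
        tr, va = split_corpus(separable_corpus, SplitSpec(seed=0))
        model = train_fann(NetConfig(hidden_layers=(16,), epochs=20, seed=0),
                           tr, va)
        assert model.validation_accuracy == 100.0
        # independent check: sklearn's MLP agrees the problem is separable
        ref = MLPClassifier(hidden_layer_sizes=(16,), max_iter=500, random_state=0)
        ref.fit(tr.values, tr.labels)
        assert ref.score(va.values, va.labels) == 1.0

    def test_history_logs_both_sides_every_epoch(self, separable_corpus):
        tr, va = split_corpus(separable_corpus, SplitSpec(seed=0))
        model = train_fann(NetConfig(hidden_layers=(8,), epochs=7, seed=0), tr, va)
        assert len(model.history) == 7
        assert {"train_accuracy", "train_rmse", "validation_accuracy",
                "validation_rmse"} <= set(model.history.columns)
        assert ((model.history.train_rmse >= 0)
                & (model.history.train_rmse <= 1)).all()

    def test_huge_weight_decay_collapses_scores(self, desk_corpus):
        mat = build_matrix(desk_corpus["retained"])
        tr, va = split_corpus(mat, SplitSpec(seed=0))
        model = train_fann(NetConfig(hidden_layers=(16,), epochs=5, l2=50.0,
                                     seed=0), tr, va)
        preds = predict(model, va)
        assert max(float(p.scores.max()) for p in preds) < 0.6

    def test_single_class_rejected(self):
        mat = toy_matrix(["A"] * 8)
        tr, va = split_corpus(mat, SplitSpec(seed=0))
        with pytest.raises(ValueError, match="two classes"):
            train_fann(NetConfig(), tr, va)


class TestPredict:
    def test_training_rows_of_perfect_model_get_own_labels(self, separable_corpus):
        tr, va = split_corpus(separable_corpus, SplitSpec(seed=0))
        model = train_fann(NetConfig(hidden_layers=(16,), epochs=20, seed=0),
                           tr, va)
        assert model.train_accuracy == 100.0
        preds = predict(model, tr)
        assert [p.predicted for p in preds] == tr.labels

    def test_scores_normalized_and_duplicates_identical(self, separable_corpus):
        tr, va = split_corpus(separable_corpus, SplitSpec(seed=0))
        model = train_fann(NetConfig(hidden_layers=(8,), epochs=5, seed=0), tr, va)
        doubled = va.subset(np.array([0, 0, 1]))
        preds = predict(model, doubled)
        for p in preds:
            assert p.scores.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(p.scores >= 0)
        np.testing.assert_array_equal(preds[0].scores, preds[1].scores)

    def test_identical_pair_splits_score_mass(self, panel):
        """Zero-noise runs of look-alike species cannot be assigned with
        confidence after balanced training."""
        by = {p.species_name: p for p in panel}
        models = [by["Galeocerdo cuvier"], by["Glaucostegus typus"]]
        grid = m.AcquisitionGrid(n_points=256)
        runs = simulate_small_corpus(models, grid, m.NoiseModel.zero(),
                                     n_specimens=10, replicates=2, seed=1)
        mat = build_matrix([process_run(r) for r in runs])
        tr, va = split_corpus(mat, SplitSpec(seed=0))
        model = train_fann(NetConfig(hidden_layers=(16,), epochs=30, seed=0),
                           tr, va)
        preds = predict(model, va)
        assert all(float(p.scores.max()) < 0.95 for p in preds)

    def test_feature_width_mismatch_rejected(self, separable_corpus):
        tr, va = split_corpus(separable_corpus, SplitSpec(seed=0))
        model = train_fann(NetConfig(hidden_layers=(8,), epochs=3, seed=0), tr, va)
        with pytest.raises(ValueError, match="width"):
            predict(model, toy_matrix(["A", "B"] * 3))


class TestGridSearch:
    def test_single_config_grid_returns_it(self, separable_corpus):
        spec = GridSearchSpec(params={"hidden_layers": [(8,)], "epochs": [5]},
                              max_models=10, seed=0)
        table, best = grid_search(separable_corpus, spec, SplitSpec(seed=0))
        assert len(table) == 1
        assert best.config.hidden_layers == (8,)

    def test_selection_prefers_higher_validation_accuracy(self, separable_corpus):
        # one config cannot learn (epochs=0 is invalid; use tiny lr) while
        # the other converges; the better one must be selected
        spec = GridSearchSpec(params={"learning_rate": [1e-6, 0.05],
                                      "hidden_layers": [(16,)], "epochs": [15]},
                              max_models=2, seed=0)
        table, best = grid_search(separable_corpus, spec, SplitSpec(seed=0))
        assert best.validation_accuracy == table.validation_accuracy.max()
        assert best.config.learning_rate == 0.05

    def test_max_models_stops_search(self, separable_corpus):
        spec = GridSearchSpec(params={"hidden_layers": [(4,), (8,), (16,)],
                                      "epochs": [2, 4], "learning_rate": [0.05, 0.1]},
                              max_models=5, seed=0)
        table, _ = grid_search(separable_corpus, spec, SplitSpec(seed=0))
        assert len(table) == 5

    def test_same_seed_same_search(self, separable_corpus):
        spec = GridSearchSpec(params={"hidden_layers": [(4,), (8,)],
                                      "epochs": [2, 4]}, max_models=3, seed=9)
        t1, b1 = grid_search(separable_corpus, spec, SplitSpec(seed=0))
        t2, b2 = grid_search(separable_corpus, spec, SplitSpec(seed=0))
        pd.testing.assert_frame_equal(t1, t2.assign(seconds=t1.seconds))
        assert b1.config == b2.config

    def test_empty_grid_rejected(self, separable_corpus):
        with pytest.raises(ValueError, match="empty"):
            grid_search(separable_corpus, GridSearchSpec(params={}),
                        SplitSpec(seed=0))

    def test_default_grid_has_at_least_301_combinations(self):
        grid = default_search_grid()
        assert int(np.prod([len(v) for v in grid.values()])) >= 301


class TestPersistence:
    def test_save_load_round_trip(self, separable_corpus, tmp_path):
        tr, va = split_corpus(separable_corpus, SplitSpec(seed=0))
        model = train_fann(NetConfig(hidden_layers=(8,), epochs=5, seed=0), tr, va)
        save_model(model, tmp_path / "model.json")
        loaded = load_model(tmp_path / "model.json")
        a = predict(model, va)
        b = predict(loaded, va)
        for pa, pb in zip(a, b):
            np.testing.assert_allclose(pa.scores, pb.scores, atol=1e-12)
        assert loaded.config == model.config
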