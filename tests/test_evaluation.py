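import math

import numpy as np
import pandas as pd
import pytest
from conftest import FAST_GRID

from scselect import (
    GeneratorConfig,
    cell_type_similarity,
    corrupt_markers,
    default_param_grid,
    evaluate_predictions,
    fit_embedding,
    generate,
    lognormalize,
    make_imbalanced_subsets,
    project,
    rank_strategies,
    run_benchmark,
    train_downstream_rf,
)


class TestMetrics:
    def test_perfect_prediction_scores_one_everywhere(self):
        y = ["a", "b", "c"] * 10
        rec = evaluate_predictions(y, y)
        for m in ("sensitivity", "f1", "mcc", "kappa", "balanced_accuracy"):
            assert getattr(rec, m) == pytest.approx(1.0)

    def test_binary_confusion_closed_forms(self):
        """TP=40, FN=10, FP=20, TN=30 against independently coded formulas."""
        truth = np.asarray(["pos"] * 50 + ["neg"] * 50)
        pred = np.asarray(["pos"] * 40 + ["neg"] * 10
                          + ["pos"] * 20 + ["neg"] * 30)
        rec = evaluate_predictions(pred, truth)
        tp, fn, fp, tn = 40, 10, 20, 30
        recall_pos, recall_neg = tp / (tp + fn), tn / (tn + fp)
        prec_pos, prec_neg = tp / (tp + fp), tn / (tn + fn)
        f1_pos = 2 * prec_pos * recall_pos / (prec_pos + recall_pos)
        f1_neg = 2 * prec_neg * recall_neg / (prec_neg + recall_neg)
        mcc = (tp * tn - fp * fn) / math.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        po = (tp + tn) / 100
        pe = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / 100**2
        kappa = (po - pe) / (1 - pe)
        assert rec.sensitivity == pytest.approx((recall_pos + recall_neg) / 2)
        assert rec.balanced_accuracy == pytest.approx((recall_pos + recall_neg) / 2)
        assert rec.f1 == pytest.approx((f1_pos + f1_neg) / 2)
        assert rec.mcc == pytest.approx(mcc)
        assert rec.kappa == pytest.approx(kappa)

    def test_label_permutation_invariance(self, rng):
        truth = rng.choice(["a", "b", "c"], 120)
        pred = rng.choice(["a", "b", "c"], 120)
        rec1 = evaluate_predictions(pred, truth)
        swap = {"a": "z", "b": "y", "c": "x"}
        rec2 = evaluate_predictions([swap[p] for p in pred],
                                    [swap[t] for t in truth])
        for m in ("sensitivity", "f1", "mcc", "kappa", "balanced_accuracy"):
            assert getattr(rec1, m) == pytest.approx(getattr(rec2, m))

    def test_unassigned_predictions_dropped(self):
        truth = ["a", "a", "b", "b"]
        pred = ["a", "unassigned", "b", "unassigned"]
        rec = evaluate_predictions(pred, truth)
        assert rec.balanced_accuracy == pytest.approx(1.0)
        with pytest.raises(ValueError, match="no cells left"):
            evaluate_predictions(["unassigned"] * 4, truth)


class TestDownstreamClassifier:
    def test_grid_shape(self):
        grid = default_param_grid("rna")
        n = (len(grid["pca__n_components"]) * len(grid["rf__max_features"])
             * len(grid["rf__n_estimators"]))
        assert n == 12
        assert default_param_grid("cytof")["pca__n_components"] == [20, 39]

    def test_separable_data_near_perfect_f1(self, small_rna_lognorm):
        ds, truth, _ = small_rna_lognorm
        y = truth.loc[ds.cell_ids].to_numpy()
        clf = train_downstream_rf(ds.values[:300], y[:300], "rna", seed=0,
                                  param_grid=FAST_GRID)
        rec = evaluate_predictions(clf.predict(ds.to_dense()[300:]), y[300:])
        assert rec.f1 > 0.95

    def test_same_seed_same_configuration(self, small_rna_lognorm):
        ds, truth, _ = small_rna_lognorm
        y = truth.loc[ds.cell_ids].to_numpy()
        grid = {"pca__n_components": [5, 10], "rf__max_features": [2],
                "rf__n_estimators": [50]}
        b1 = train_downstream_rf(ds.values[:150], y[:150], seed=4,
                                 param_grid=grid).best_params_
        b2 = train_downstream_rf(ds.values[:150], y[:150], seed=4,
                                 param_grid=grid).best_params_
        assert b1 == b2

    def test_small_class_warns_not_errors(self, small_rna_lognorm):
        ds, truth, _ = small_rna_lognorm
        y = truth.loc[ds.cell_ids].to_numpy()
        idx = np.concatenate([np.flatnonzero(y == "A")[:30],
                              np.flatnonzero(y == "B")[:3]])
        with pytest.warns(UserWarning, match="smallest class"):
            train_downstream_rf(ds.values[idx], y[idx], seed=0,
                                param_grid=FAST_GRID)


class TestSimilarity:
    def test_identical_centroids_distance_zero(self):
        Z = np.tile(np.asarray([[1.0, 2.0, 3.0]]), (10, 1))
        truth = ["a"] * 5 + ["b"] * 5
        sim = cell_type_similarity(Z, np.asarray([0.5, 0.3, 0.2]), truth)
        assert sim.distances.loc["a", "b"] == pytest.approx(0.0)

    def test_weighted_orthogonal_centroids_distance_one(self):
        Z = np.vstack([np.tile([1.0, 0.0], (4, 1)),
                       np.tile([0.0, 1.0], (4, 1))])
        truth = ["a"] * 4 + ["b"] * 4
        sim = cell_type_similarity(Z, np.asarray([0.6, 0.4]), truth)
        assert sim.distances.loc["a", "b"] == pytest.approx(1.0)

    def test_uniform_weights_reduce_to_plain_cosine(self, rng):
        from scipy.spatial.distance import cosine

        Z = rng.normal(size=(60, 8))
        truth = rng.choice(["a", "b", "c"], 60)
        w = np.full(8, 1 / 8)
        sim = cell_type_similarity(Z, w, truth)
        for a in "abc":
            for b in "abc":
                if a >= b:
                    continue
                ca = Z[truth == a].mean(axis=0)
                cb = Z[truth == b].mean(axis=0)
                assert sim.distances.loc[a, b] == pytest.approx(
                    cosine(ca, cb), abs=1e-9)

    def test_pair_pickers_match_arg_extremes(self, rng):
        Z = rng.normal(size=(80, 6)) + np.repeat(
            rng.normal(scale=3, size=(4, 6)), 20, axis=0)
        truth = np.repeat(["a", "b", "c", "d"], 20)
        sim = cell_type_similarity(Z, np.full(6, 1 / 6), truth)
        d = sim.distances.to_numpy().copy()
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        assert set(sim.closest_pair()) == {sim.distances.index[i],
                                           sim.distances.columns[j]}


@pytest.fixture(scope="module")
def pool():
    cfg = GeneratorConfig(
        n_cells=2400, n_genes=150,
        proportions={"a": 0.3, "b": 0.3, "c": 0.2, "d": 0.2},
        markers_per_type=3, program_genes_per_type=10, seed=2,
    )
    ds, truth, _ = generate(cfg)
    return lognormalize(ds), truth


class TestImbalanceDesigns:

    def test_two_type_counts(self, pool):
        ds, truth = pool
        sub, y = make_imbalanced_subsets(ds, truth, "two_type_similar",
                                         types=("a", "b"), seed=0)
        assert y.value_counts().to_dict() == {"a": 450, "b": 50}
        sub, y = make_imbalanced_subsets(ds, truth, "two_type_balanced",
                                         types=("a", "b"), seed=0)
        assert y.value_counts().to_dict() == {"a": 250, "b": 250}

    def test_multi_type_counts(self, pool):
        ds, truth = pool
        _, y = make_imbalanced_subsets(ds, truth, "multi_imbalanced",
                                       types=("a",), seed=0)
        assert y.value_counts().to_dict() == {"a": 100, "b": 25, "c": 25,
                                              "d": 25}
        _, y = make_imbalanced_subsets(ds, truth, "multi_balanced", seed=0)
        assert set(y.value_counts()) == {100}

    def test_similarity_driven_pair_choice(self, pool):
        ds, truth = pool
        emb = fit_embedding(ds, 20)
        sim = cell_type_similarity(project(ds, emb), emb.variance_explained,
                                   truth.loc[ds.cell_ids].to_numpy())
        sub, y = make_imbalanced_subsets(ds, truth, "two_type_similar",
                                         similarity=sim, seed=0)
        assert set(y.unique()) == set(sim.closest_pair())

    def test_insufficient_cells_named(self, small_rna_lognorm):
        ds, truth, _ = small_rna_lognorm  # 400 cells; no type reaches 450
        with pytest.raises(ValueError, match="'A' has"):
            make_imbalanced_subsets(ds, truth, "two_type_similar",
                                    types=("A", "B"), seed=0)


class TestMarkerCorruption:
    def test_zero_fraction_identity(self, small_rna_lognorm):
        ds, _, spec = small_rna_lognorm
        out = corrupt_markers(spec, ds, 0.0, seed=0)
        assert out.positive == spec.positive

    def test_full_corruption_replaces_everything(self, small_rna_lognorm):
        ds, _, spec = small_rna_lognorm
        out = corrupt_markers(spec, ds, 1.0, seed=0)
        assert not (out.all_markers() & spec.all_markers())

    def test_replacements_outside_original_file(self, small_rna_lognorm):
        ds, _, spec = small_rna_lognorm
        out = corrupt_markers(spec, ds, 0.5, seed=1)
        new = out.all_markers() - spec.all_markers()
        assert new and not (new & spec.all_markers())
        # half the marker entries changed
        n_entries = sum(len(v) for v in spec.positive.values())
        changed = sum(a != b for t in spec.types
                      for a, b in zip(spec.positive[t], out.positive[t]))
        assert changed == round(0.5 * n_entries)


class TestBenchmark:
    def test_record_grid_and_ranking(self, small_rna_lognorm):
        ds, truth, spec = small_rna_lognorm
        res = run_benchmark(ds, truth, strategies=("random", "ranked"),
                            budgets=(60,), n_splits=1, seed=0, markers=spec,
                            downstream_grid=FAST_GRID)
        assert len(res) == 2
        assert set(res["strategy"]) == {"random", "ranked"}
        ranking = rank_strategies(res)
        assert list(ranking["rank"]) == [1, 2]
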