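"""Grid enumeration, metrics, cross-validation and export."""

from fractions import Fraction
from itertools import product

import numpy as np
import pytest

from bacprom.dataset import FeatureEncoding, build_dataset
from bacprom.errors import EncodingMismatchError, GridSpecError
from bacprom.svmgrid import (
    ConfusionCounts,
    GridCell,
    GridSpec,
    SvmGridSearch,
    cross_validate,
    export_results,
    geometric_series,
    grid_search,
    load_model,
    make_parameter_grid,
    metrics,
    predict,
    rank_results,
    read_results,
    save_model,
    train_final,
)
from bacprom.synth import SyntheticSpec, generate_labeled_benchmark

REDUCED = GridSpec(
    svm_types=("C_SVC",), kernels=("LINEAR", "RBF"),
    c_min=0.0625, c_max=16.0, c_factor=16.0,
    g_min=0.000244140625, g_max=0.0625, g_factor=16.0,
)


class TestGeometricSeries:
    def test_default_cost_series(self):
        values = GridSpec().c_values
        assert len(values) == 7
        assert values[0] == 0.00390625 and values[-1] == 65536.0

    def test_default_gamma_series(self):
        values = GridSpec().g_values
        assert len(values) == 7
        assert values[0] == 1.52587890625e-5 and values[-1] == 256.0

    def test_degenerate_single_value(self):
        assert geometric_series(2.0, 2.0, 16.0) == (2.0,)

    def test_unreachable_maximum_is_spec_error(self):
        with pytest.raises(GridSpecError, match="not reachable"):
            geometric_series(1.0, 10.0, 2.0)

    def test_endpoint_snapping_within_tolerance(self):
        # 0.1 * 10^3 accumulates float error but snaps to 100.0 exactly
        values = geometric_series(0.1, 100.0, 10.0)
        assert values[-1] == 100.0


class TestMakeParameterGrid:
    def test_small_grid_cardinality(self):
        spec = GridSpec(svm_types=("C_SVC", "NU_SVC"), kernels=("RBF",),
                        c_min=1.0, c_max=16.0, c_factor=16.0,
                        g_min=0.1, g_max=1.6, g_factor=16.0)
        assert len(make_parameter_grid(spec)) == 8

    def test_full_default_grid_excludes_precomputed(self):
        cells = make_parameter_grid(GridSpec())
        assert len(cells) == 5 * 4 * 7 * 7  # 980
        assert not any(c.kernel == "PRECOMPUTED" for c in cells)

    def test_deterministic_ordering(self):
        spec = GridSpec(svm_types=("C_SVC",), kernels=("RBF",),
                        c_min=1.0, c_max=16.0, c_factor=16.0,
                        g_min=0.1, g_max=1.6, g_factor=16.0)
        cells = make_parameter_grid(spec)
        assert cells == sorted(cells, key=lambda c: (c.c, c.gamma))

    def test_table_defaults_present(self):
        spec = GridSpec()
        assert (spec.nu, spec.epsilon, spec.degree) == (0.5, 0.001, 3)
        assert (spec.coef0, spec.cache_mb, spec.class_weight) == (0.0, 100.0, 1.0)
        assert spec.shrinking and not spec.probability


class TestMetrics:
    @pytest.mark.parametrize("tp,tn,fp,fn,expected", [
        (5, 5, 0, 0, (1.0, 1.0, 1.0)),
        (3, 4, 1, 2, (0.7, 0.8, 0.6)),
        (0, 10, 0, 10, (0.5, 1.0, 0.0)),  # degenerate always-negative classifier
    ])
    def test_hand_computed_values(self, tp, tn, fp, fn, expected):
        assert metrics(ConfusionCounts(tp, tn, fp, fn)) == pytest.approx(expected)

    def test_exhaustive_small_confusion_matrices(self):
        """Check against an independent exact-rational oracle for every
        confusion matrix with all counts <= 5."""
        for tp, tn, fp, fn in product(range(6), repeat=4):
            if tp + tn + fp + fn == 0:
                continue
            a, s, sn = metrics(ConfusionCounts(tp, tn, fp, fn))
            assert a == float(Fraction(tp + tn, tp + tn + fp + fn))
            if tn + fp == 0:
                assert s is None
            else:
                assert s == float(Fraction(tn, tn + fp))
            if tp + fn == 0:
                assert sn is None
            else:
                assert sn == float(Fraction(tp, tp + fn))

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))


class TestCrossValidate:
    def test_separable_dataset_high_accuracy(self, separable_benchmark):
        cell = GridCell("C_SVC", "LINEAR", 1.0, 0.01)
        result = cross_validate(cell, separable_benchmark, folds=5, seed=0)
        assert result.accuracy >= 0.95
        assert result.counts.total == separable_benchmark.n

    def test_metrics_recomputable_from_counts(self, separable_benchmark):
        cell = GridCell("C_SVC", "RBF", 1.0, 0.01)
        r = cross_validate(cell, separable_benchmark, folds=5, seed=0)
        a, s, sn = metrics(r.counts)
        assert abs(a - r.accuracy) < 1e-12
        assert abs(s - r.specificity) < 1e-12
        assert abs(sn - r.sensitivity) < 1e-12

    def test_permuted_labels_destroy_signal(self, separable_benchmark):
        rng = np.random.default_rng(13)
        y = rng.permutation(separable_benchmark.y)
        cell = GridCell("C_SVC", "LINEAR", 1.0, 0.01)
        r = cross_validate(cell, (separable_benchmark.features, y), folds=5, seed=0)
        assert 0.35 <= r.accuracy <= 0.65

    def test_deterministic_under_seed(self, separable_benchmark):
        cell = GridCell("NU_SVC", "RBF", 1.0, 0.01)
        a = cross_validate(cell, separable_benchmark, folds=5, seed=4)
        b = cross_validate(cell, separable_benchmark, folds=5, seed=4)
        assert a == b

    def test_one_class_trains_on_positives_only(self, separable_benchmark):
        cell = GridCell("ONE_CLASS", "RBF", 1.0, 0.01)
        r = cross_validate(cell, separable_benchmark, folds=5, seed=0)
        assert not r.failed
        assert r.counts.total == separable_benchmark.n
        assert r.specificity is not None  # mixed held-out folds contain negatives

    def test_svr_types_classify_at_half_threshold(self, separable_benchmark):
        for svm_type in ("EPSILON_SVR", "NU_SVR"):
            r = cross_validate(GridCell(svm_type, "LINEAR", 1.0, 0.01),
                               separable_benchmark, folds=3, seed=0)
            assert not r.failed
            assert r.accuracy > 0.8  # separable even through the regression route

    def test_single_class_two_class_type_rejected(self, separable_benchmark):
        X = separable_benchmark.features
        y = np.ones(X.shape[0], dtype=int)
        with pytest.raises(ValueError, match="both classes"):
            cross_validate(GridCell("C_SVC", "RBF", 1.0, 0.01), (X, y), 5, 0)

    def test_folds_exceeding_class_size_rejected(self, separable_benchmark):
        X = separable_benchmark.features[:12]
        y = separable_benchmark.y[:12]
        y[-2:] = 0  # minority class of size 2
        with pytest.raises(ValueError, match="folds"):
            cross_validate(GridCell("C_SVC", "RBF", 1.0, 0.01), (X, y), 5, 0)


class TestGridSearch:
    def test_result_count_matches_grid(self, separable_benchmark):
        results = grid_search(separable_benchmark, REDUCED, folds=3, seed=0)
        assert len(results) == 2 * 3 * 3  # kernels x C x gamma

    def test_ranking_contract(self, separable_benchmark):
        results = grid_search(separable_benchmark, REDUCED, folds=3, seed=0)
        accs = [r.accuracy for r in results if not r.failed]
        assert accs == sorted(accs, reverse=True)
        assert results[0].accuracy == max(accs)

    def test_rank_ties_break_by_sensitivity_then_c_then_gamma(self):
        def res(acc, sn, c, g):
            counts = ConfusionCounts(1, 1, 0, 0)
            from bacprom.svmgrid import EvaluationResult
            return EvaluationResult("C_SVC", "RBF", c, g, counts, acc, 1.0, sn, 5, 0)

        ranked = rank_results([
            res(0.9, 0.8, 2.0, 1.0),
            res(0.9, 0.9, 4.0, 1.0),
            res(0.9, 0.9, 1.0, 2.0),
            res(0.9, 0.9, 1.0, 1.0),
            res(0.95, 0.1, 8.0, 8.0),
        ])
        key = [(r.accuracy, r.sensitivity, r.c, r.gamma) for r in ranked]
        assert key == [(0.95, 0.1, 8.0, 8.0), (0.9, 0.9, 1.0, 1.0),
                       (0.9, 0.9, 1.0, 2.0), (0.9, 0.9, 4.0, 1.0),
                       (0.9, 0.8, 2.0, 1.0)]

    def test_sklearn_estimator_interface(self, separable_benchmark):
        search = SvmGridSearch(spec=REDUCED, folds=3, seed=0)
        assert search.get_params()["folds"] == 3
        search.fit(separable_benchmark.features, separable_benchmark.y)
        assert hasattr(search, "best_estimator_")
        pred = search.predict(separable_benchmark.features)
        assert set(pred) <= {0, 1}
        assert (pred == separable_benchmark.y).mean() > 0.95

    def test_label_noise_degrades_best_accuracy(self):
        """Flipping 0%, 10%, 30% of the labels must not increase the
        best cell's mean CV accuracy (three seeded repetitions)."""
        spec = SyntheticSpec(genome_length=70_000, n_promoters=100,
                             mutation_rate=0.02, seed=21)
        ds = generate_labeled_benchmark(spec, n_negatives=100, seed=22)
        small = GridSpec(svm_types=("C_SVC",), kernels=("LINEAR",),
                         c_min=1.0, c_max=1.0, c_factor=16.0,
                         g_min=0.01, g_max=0.01, g_factor=16.0)
        mean_best = []
        for rate in (0.0, 0.1, 0.3):
            accs = []
            for rep in range(3):
                rng = np.random.default_rng(100 + rep)
                y = ds.y.copy()
                flip = rng.random(len(y)) < rate
                y[flip] = 1 - y[flip]
                search = SvmGridSearch(spec=small, folds=3, seed=rep, refit=False)
                search.fit(ds.features, y)
                accs.append(search.best_result_.accuracy)
            mean_best.append(np.mean(accs))
        assert mean_best[0] >= mean_best[1] >= mean_best[2]


@pytest.fixture(scope="module")
def trained(separable_benchmark):
    cell = GridCell("C_SVC", "RBF", 1.0, 0.01)
    return train_final(cell, separable_benchmark)


class TestModelPersistence:
    def test_training_positives_predicted_as_promoters(self, trained, separable_benchmark):
        pos = [s for s, l in zip(separable_benchmark.sequences,
                                 separable_benchmark.labels) if l == "promoter"]
        labels = predict(trained, pos[:20])
        assert labels == ["promoter"] * 20

    def test_save_load_round_trip(self, trained, separable_benchmark, tmp_path):
        p = tmp_path / "model.joblib"
        save_model(trained, p)
        loaded = load_model(p)
        assert loaded.cell == trained.cell
        assert loaded.encoding == trained.encoding
        seqs = separable_benchmark.sequences[:100]
        assert predict(loaded, seqs) == predict(trained, seqs)

    def test_encoding_mismatch_names_both_descriptors(self, trained):
        kmer = FeatureEncoding("kmer", k=3)
        with pytest.raises(EncodingMismatchError, match="onehot.*kmer"):
            predict(trained, ["A" * 80], encoding=kmer)

    def test_wrong_window_length_rejected(self, trained):
        with pytest.raises(EncodingMismatchError, match="length 80"):
            predict(trained, ["ACGT" * 10])


class TestExportResults:
    def test_file_layout_and_formatting(self, separable_benchmark, tmp_path):
        results = grid_search(separable_benchmark, REDUCED, folds=3, seed=0)[:3]
        p = tmp_path / "results.csv"
        export_results(results, p)
        lines = p.read_text().splitlines()
        assert len(lines) == 4
        assert lines[0] == "Type,Kernel,C,G,A,S,SN,TP,TN,FP,FN"

    def test_percent_formatting_two_decimals(self, tmp_path):
        from bacprom.svmgrid import EvaluationResult
        r = EvaluationResult("C_SVC", "RBF", 1.0, 0.1,
                             ConfusionCounts(7, 7, 3, 3), 0.7, 0.7, 0.7, 5, 0)
        p = tmp_path / "r.csv"
        export_results([r], p)
        assert ",70.00,70.00,70.00," in p.read_text().splitlines()[1]

    def test_round_trip_preserves_ranking(self, separable_benchmark, tmp_path):
        results = grid_search(separable_benchmark, REDUCED, folds=3, seed=0)
        p = tmp_path / "results.csv"
        export_results(results, p)
        rows = read_results(p)
        assert [(row["Type"], row["Kernel"], row["C"], row["G"]) for row in rows] \
            == [(r.svm_type, r.kernel, r.c, r.gamma) for r in results]
        assert [row["A"] for row in rows] \
            == [round(100 * r.accuracy, 2) for r in results]

    def test_empty_results_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_results([], tmp_path / "r.csv")
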