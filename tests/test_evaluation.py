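import itertools

import numpy as np
import pytest

import evokgsim as ek
from evokgsim.evaluation import EvaluationReport

from naive_oracle import naive_waf


class TestWaf:
    def test_worked_example(self):
        got = ek.waf([1, 1, 1, 1, 0, 0], [1, 1, 1, 0, 0, 1])
        assert got == pytest.approx((0.75 * 4 + 0.5 * 2) / 6)
        assert got == pytest.approx(0.6667, abs=1e-4)

    def test_perfect_prediction(self):
        assert ek.waf([0, 1, 1], [0, 1, 1]) == 1.0

    def test_all_wrong_balanced(self):
        assert ek.waf([0, 0, 1, 1], [1, 1, 0, 0]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ek.waf([0, 1], [0])

    def test_exhaustive_small_confusion_tables(self):
        """Agreement with hand precision/recall on all 2x2 tables <= 5."""
        for tp, fp, fn, tn in itertools.product(range(6), repeat=4):
            if tp + fp + fn + tn == 0:
                continue
            y_true = [1] * tp + [0] * fp + [1] * fn + [0] * tn
            y_pred = [1] * tp + [1] * fp + [0] * fn + [0] * tn
            assert ek.waf(y_true, y_pred) == pytest.approx(
                naive_waf(y_true, y_pred), abs=1e-12
            )

    def test_waf_one_iff_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.integers(0, 2, 15)
            p = y.copy()
            assert ek.waf(y, p) == 1.0
            p[rng.integers(0, 15)] ^= 1
            assert ek.waf(y, p) < 1.0


class TestFilterPairs:
    def test_unannotated_entity_removed(self, small_synth):
        _, _, store, _, _ = small_synth
        ents = sorted(store.entities)[:2]
        ds = ek.PairDataset(
            [(ents[0], ents[1], 1), (ents[0], "GHOST", 1)], name="t"
        )
        kept = ek.filter_pairs(ds, store)
        assert len(kept) == 1

    def test_single_aspect_annotation_suffices(self, toy_store):
        ds = ek.PairDataset([("p1", "p2", 1)])
        assert len(ek.filter_pairs(ds, toy_store)) == 1

    def test_empty_store_removes_everything(self, toy_graph):
        empty = ek.AnnotationStore(direct={}, graph_ref=toy_graph)
        ds = ek.PairDataset([("a", "b", 0), ("c", "d", 1)])
        assert len(ek.filter_pairs(ds, empty)) == 0


class TestStratifiedKFold:
    def test_fold_sizes_and_stratification(self):
        y = [1] * 12 + [0] * 8
        folds = ek.stratified_kfold(np.array(y), k=10, seed=0)
        for train, test in folds:
            assert len(test) == 2
            assert np.array(y)[test].sum() in (1, 2)

    def test_partition(self):
        y = np.array([0, 1] * 15)
        folds = ek.stratified_kfold(y, k=5, seed=1)
        all_test = np.concatenate([t for _, t in folds])
        assert sorted(all_test) == list(range(30))

    def test_seed_pinning(self):
        y = np.array([0, 1] * 20)
        f1 = ek.stratified_kfold(y, k=10, seed=3)
        f2 = ek.stratified_kfold(y, k=10, seed=3)
        for (a, b), (c, d) in zip(f1, f2):
            np.testing.assert_array_equal(a, c)
            np.testing.assert_array_equal(b, d)

    def test_small_class_still_partitions(self):
        y = np.array([1] * 15 + [0] * 3)
        folds = ek.stratified_kfold(y, k=10, seed=0)
        all_test = np.concatenate([t for _, t in folds])
        assert sorted(all_test) == list(range(18))

    def test_k_larger_than_dataset_rejected(self):
        with pytest.raises(ValueError):
            ek.stratified_kfold(np.array([0, 1, 0, 1]), k=10, seed=0)


class TestDedupAcross:
    def test_overlap_removed_from_train(self):
        train = ek.PairDataset([("A", "B", 1), ("C", "D", 0)], name="tr")
        test = ek.PairDataset([("A", "B", 1)], name="te")
        tr2, te2 = ek.dedup_across(train, test)
        assert tr2.pair_keys() == {("C", "D")}
        assert te2.pair_keys() == {("A", "B")}

    def test_reversed_order_detected(self):
        train = ek.PairDataset([("A", "B", 1)])
        test = ek.PairDataset([("B", "A", 0)])
        tr2, te2 = ek.dedup_across(train, test)
        assert not (tr2.pair_keys() & te2.pair_keys())

    def test_disjoint_unchanged(self):
        train = ek.PairDataset([("A", "B", 1)])
        test = ek.PairDataset([("C", "D", 0)])
        tr2, te2 = ek.dedup_across(train, test)
        assert tr2.pairs == train.pairs and te2.pairs == test.pairs

    def test_remove_from_test_side(self):
        train = ek.PairDataset([("A", "B", 1)])
        test = ek.PairDataset([("B", "A", 1), ("X", "Y", 0)])
        _, te2 = ek.dedup_across(train, test, remove_from="test")
        assert te2.pair_keys() == {("X", "Y")}


class TestPairDataset:
    def test_duplicate_rows_removed_at_load(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("# c\nA\tB\t1\nB\tA\t1\nC\tD\t0\n")
        ds = ek.PairDataset.load(p)
        assert len(ds) == 2

    def test_save_load_round_trip(self, tmp_path):
        ds = ek.PairDataset([("A", "B", 1), ("C", "D", 0)], name="x")
        path = tmp_path / "ds.tsv"
        ds.save(path)
        back = ek.PairDataset.load(path)
        assert back.pairs == ds.pairs


class TestRunProtocol:
    def test_cv_static_baseline(self, labeled_table):
        rep = ek.run_protocol(
            labeled_table, ek.StaticCombinationClassifier(kind="Max"), "cv", seeds=[0]
        )
        assert len(rep.fold_scores) == 10
        assert rep.median_waf == pytest.approx(
            float(np.median(rep.fold_scores))
        )
        assert all("threshold" in e for e in rep.extras)

    def test_cross_deterministic_runs_once(self, labeled_table):
        half = len(labeled_table) // 2
        tr = labeled_table.subset(range(half))
        te = labeled_table.subset(range(half, len(labeled_table)))
        rep = ek.run_protocol(
            (tr, te), ek.StaticCombinationClassifier(kind="Avg"), "cross",
            seeds=list(range(10)),
        )
        assert len(rep.fold_scores) == 1

    def test_cross_overlap_removed_from_train(self, labeled_table):
        tr = labeled_table.subset(range(0, 60))
        te = labeled_table.subset(range(40, 100))
        rep = ek.run_protocol(
            (tr, te), ek.StaticCombinationClassifier(kind="Max"), "cross", seeds=[0]
        )
        assert len(rep.fold_scores) == 1  # ran after silent dedup

    def test_gp_cv_reproducible(self, labeled_table):
        est = ek.EvoKGSimClassifier(population_size=40, generations=4)
        r1 = ek.run_protocol(labeled_table, est, "cv", seeds=[5], k=5)
        r2 = ek.run_protocol(labeled_table, est, "cv", seeds=[5], k=5)
        assert r1.fold_scores == r2.fold_scores
        assert r1.extras == r2.extras

    def test_report_json_round_trip(self, tmp_path, labeled_table):
        rep = ek.run_protocol(
            labeled_table, ek.StaticCombinationClassifier(kind="BP"), "cv", seeds=[0]
        )
        path = tmp_path / "rep.json"
        rep.save(path)
        back = EvaluationReport.load(path)
        assert back.fold_scores == rep.fold_scores
        assert back.median_waf == rep.median_waf


class TestCompareMethods:
    def test_identical_vectors_not_significant(self):
        stat, p, sig = ek.compare_methods([0.8] * 10, [0.8] * 10)
        assert stat == 0.0 and not sig

    def test_clearly_different_vectors_significant(self):
        stat, p, sig = ek.compare_methods([0.9] * 10, [0.5] * 10, alpha=0.01)
        assert sig and p < 0.01

    def test_alpha_respected(self):
        # two mildly different samples: significant at 0.05, not at 1e-6
        a = [0.70, 0.72, 0.71, 0.74, 0.73, 0.75, 0.72, 0.71, 0.73, 0.74]
        b = [0.68, 0.69, 0.70, 0.71, 0.69, 0.70, 0.71, 0.68, 0.70, 0.69]
        _, p, sig_tight = ek.compare_methods(a, b, alpha=1e-6)
        assert not sig_tight
        _, p2, _ = ek.compare_methods(a, b, alpha=0.05)
        assert p == p2

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError):
            ek.compare_methods([0.5], [0.6, 0.7])
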