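import numpy as np
import pytest
from scipy.stats import mannwhitneyu

import oracles
from ppigru.classify import ClassifierConfig, PredictionSet
from ppigru.encoders import ProteinRecord
from ppigru.evalcv import (
    PipelineConfig,
    compute_metrics,
    cross_dataset_test,
    fit_pipeline,
    optimize_lag,
    run_cv,
    stratified_kfold,
)
from ppigru.synthdata import GeneratorConfig, generate


class TestComputeMetrics:
    def test_perfect_predictions(self):
        truth = np.array([1, 0, 1, 0])
        rep = compute_metrics(truth, PredictionSet(np.array([0.9, 0.1, 0.8, 0.2])))
        for m in ("ACC", "PRE", "SE", "SP", "F1", "MCC", "AUC", "AUPR"):
            assert rep[m] == pytest.approx(1.0)

    def test_worked_confusion_example(self):
        # TP=3, FP=1, TN=4, FN=2
        truth = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        probs = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.6, 0.3, 0.2, 0.1, 0.4])
        rep = compute_metrics(truth, PredictionSet(probs))
        assert rep.counts.TP == 3 and rep.counts.FP == 1
        assert rep["ACC"] == pytest.approx(0.7)
        assert rep["PRE"] == pytest.approx(0.75)
        assert rep["SE"] == pytest.approx(0.6)
        assert rep["SP"] == pytest.approx(0.8)
        assert rep["MCC"] == pytest.approx(10 / np.sqrt(600))

    def test_degenerate_all_positive_predictions(self):
        truth = np.array([1, 1, 0, 0])
        rep = compute_metrics(truth, PredictionSet(np.array([0.9, 0.8, 0.7, 0.6])))
        assert rep["SE"] == 1.0 and rep["SP"] == 0.0
        assert rep["ACC"] == 0.5 and rep["MCC"] == 0.0
        assert "MCC" in rep.undefined or rep["MCC"] == 0.0

    def test_matches_confusion_oracle_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(4, 40))
            truth = rng.integers(0, 2, n)
            if truth.min() == truth.max():
                truth[0] = 1 - truth[0]
            probs = rng.random(n)
            rep = compute_metrics(truth, PredictionSet(probs))
            want = oracles.oracle_metrics(truth, probs)
            for m in ("ACC", "PRE", "SE", "SP", "F1", "MCC"):
                assert rep[m] == pytest.approx(want[m], abs=1e-12), m

    def test_auc_equals_rank_statistic(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(6, 60))
            truth = rng.integers(0, 2, n)
            if truth.min() == truth.max():
                truth[0] = 1 - truth[0]
            probs = rng.random(n).round(1)  # provoke ties
            rep = compute_metrics(truth, PredictionSet(probs))
            assert rep["AUC"] == pytest.approx(
                oracles.oracle_auc_mannwhitney(truth, probs), abs=1e-12)
            u = mannwhitneyu(probs[truth == 1], probs[truth == 0]).statistic
            assert rep["AUC"] == pytest.approx(
                u / ((truth == 1).sum() * (truth == 0).sum()), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([1, 0]), PredictionSet(np.array([0.5])))


class TestStratifiedKFold:
    def test_balanced_ten_pairs(self):
        y = np.array([1, 0] * 5)
        folds = stratified_kfold(y, k=5, seed=1)
        for f in range(5):
            mask = folds == f
            assert mask.sum() == 2 and y[mask].sum() == 1

    def test_partition_and_determinism(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 103)
        f1 = stratified_kfold(y, seed=9)
        f2 = stratified_kfold(y, seed=9)
        np.testing.assert_array_equal(f1, f2)
        sizes = np.bincount(f1, minlength=5)
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == 103

    def test_class_ratio_within_one_pair(self):
        rng = np.random.default_rng(5)
        y = (rng.random(100) < 0.3).astype(int)
        folds = stratified_kfold(y, seed=2)
        global_pos = y.sum() / 5
        for f in range(5):
            assert abs(y[folds == f].sum() - global_pos) <= 1

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(np.array([0, 1, 1]), k=5)


def tiny_dataset(n=30, effect=0.3, seed=11, lengths=(30, 60)):
    cfg = GeneratorConfig(n_pairs=n, length_range=lengths, effect=effect, seed=seed)
    return generate(cfg)


FAST_CLS = ClassifierConfig(n_iterations=30, seed=1)


def fast_config(**kw):
    defaults = dict(
        lags={"pseaac": 3, "ad": 2, "ac": 3},
        classifier=FAST_CLS,
        epochs=1,
        techniques=("pseaac", "ct", "mmi"),
    )
    defaults.update(kw)
    return PipelineConfig(**defaults)


class TestRunCV:
    def test_five_folds_and_strong_signal_recovery(self, props, cmap):
        proteins, pairs = tiny_dataset(n=60, effect=0.3)
        res = run_cv(proteins, pairs, props, cmap, fast_config())
        assert len(res.fold_reports) == 5
        assert np.bincount(res.fold_assignment).tolist() == [12] * 5
        assert res.mean["ACC"] >= 0.7  # strong compositional signal

    def test_train_once_mode_runs_and_reports_same_width(self, props, cmap):
        proteins, pairs = tiny_dataset(n=30, effect=0.3)
        cfg = fast_config(leakage_policy="train-once")
        res = run_cv(proteins, pairs, props, cmap, cfg)
        # rule widths for pair dims 46 (pseaac lag 3), 686 (ct), 238 (mmi)
        assert res.merged_width == 2 * (4 + 64 + 16)

    def test_strategies_share_merged_width(self, props, cmap):
        proteins, pairs = tiny_dataset(n=20, effect=0.3)
        widths = {}
        for strategy in ("multiens", "multicon", "multisep"):
            cfg = fast_config(strategy=strategy,
                              lags={"pseaac": 8, "ad": 7, "ac": 9},
                              techniques=("pseaac", "ad", "ac", "ct", "ld", "mmi"),
                              leakage_policy="train-once")
            res = run_cv(proteins, pairs, props, cmap, cfg)
            widths[strategy] = res.merged_width
        assert widths == {"multiens": 584, "multicon": 584, "multisep": 584}


class TestOptimizeLag:
    def test_short_sequences_bound_lag_range(self, props, cmap):
        proteins, pairs = tiny_dataset(n=12, lengths=(12, 20))
        with pytest.raises(ValueError, match="length"):
            optimize_lag(proteins, pairs, props, cmap, "ac",
                         lag_range=range(1, 13), classifier=FAST_CLS)

    def test_returns_per_lag_table_and_best(self, props, cmap):
        proteins, pairs = tiny_dataset(n=30, effect=0.3)
        best, table = optimize_lag(proteins, pairs, props, cmap, "pseaac",
                                   lag_range=range(1, 4), classifier=FAST_CLS)
        assert set(table) == {1, 2, 3}
        assert best in table
        assert table[best]["ACC"] == max(t["ACC"] for t in table.values())

    def test_tie_breaks_to_smallest_lag(self, props, cmap, monkeypatch):
        proteins, pairs = tiny_dataset(n=20)
        import ppigru.evalcv as ev

        def fake_metrics(truth, preds):
            rep = compute_metrics(truth, preds)
            rep.values = {m: 0.5 for m in rep.values}
            return rep

        monkeypatch.setattr(ev, "compute_metrics", fake_metrics)
        best, _ = ev.optimize_lag(proteins, pairs, props, cmap, "ac",
                                  lag_range=range(1, 4), classifier=FAST_CLS)
        assert best == 1

    def test_recovers_planted_lag_structure(self, props, cmap):
        """Sequences whose positives repeat classes at distance 2 should be
        separable by autocovariance only once the lag search reaches 2."""
        from conftest import RESIDUES

        rng = np.random.default_rng(21)

        def markov_seq(L, repeat_p):
            seq = list(rng.choice(RESIDUES, 2))
            for i in range(2, L):
                if rng.random() < repeat_p:
                    seq.append(seq[i - 2])
                else:
                    seq.append(str(rng.choice(RESIDUES)))
            return "".join(seq)

        proteins, pairs = {}, []
        for i in range(50):
            lab = i % 2
            p = 0.8 if lab else 0.0
            a, b = f"a{i}", f"b{i}"
            proteins[a] = ProteinRecord(a, markov_seq(60, p))
            proteins[b] = ProteinRecord(b, markov_seq(60, p))
            pairs.append((a, b, lab))
        best, table = optimize_lag(proteins, pairs, props, cmap, "ac",
                                   lag_range=range(1, 4), classifier=FAST_CLS)
        # lag 1 sees no distance-2 covariance; lags >= 2 do
        assert table[2]["ACC"] > table[1]["ACC"]
        assert best >= 2
        assert table[best]["ACC"] >= 0.7

    def test_nonlagged_technique_rejected(self, props, cmap):
        proteins, pairs = tiny_dataset(n=12)
        with pytest.raises(ValueError):
            optimize_lag(proteins, pairs, props, cmap, "ct")


class TestCrossDataset:
    def test_external_metrics_and_positive_only_flagging(self, props, cmap):
        proteins, pairs = tiny_dataset(n=40, effect=0.3)
        pipeline = fit_pipeline(proteins, pairs, props, cmap, fast_config())
        ext_prot, ext_pairs = tiny_dataset(n=20, effect=0.3, seed=99)
        rep = cross_dataset_test(pipeline, ext_prot, ext_pairs)
        assert 0 <= rep["ACC"] <= 1
        pos_only = [(a, b, 1) for a, b, lab in ext_pairs if lab == 1]
        rep2 = cross_dataset_test(pipeline, ext_prot, pos_only)
        assert "SP" in rep2.omitted
        assert rep2["ACC"] == pytest.approx(rep2["SE"])

    def test_empty_test_set_rejected(self, props, cmap):
        proteins, pairs = tiny_dataset(n=20)
        pipeline = fit_pipeline(proteins, pairs, props, cmap, fast_config())
        with pytest.raises(ValueError, match="empty"):
            cross_dataset_test(pipeline, {}, [])
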