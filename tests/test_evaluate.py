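"""Protocol contracts: splits, metrics, early stopping, aggregation."""

import numpy as np
import pytest

import frostgrip as fg
from frostgrip.evaluate import (RunResult, aggregate_results, compute_metrics,
                                stratified_split, train_run, repeat_protocol,
                                _mean_loss, stack_inputs)

from conftest import make_toy_inputs


BALANCED_240 = [fg.NORMAL] * 120 + [fg.FROST] * 120


class TestStratifiedSplit:
    def test_exact_721_arithmetic(self):
        plan = stratified_split(BALANCED_240, seed=0)
        assert (len(plan.train_idx), len(plan.val_idx), len(plan.test_idx)) \
            == (168, 48, 24)
        labels = np.array(BALANCED_240)
        for idx, expected in [(plan.train_idx, 84), (plan.val_idx, 24),
                              (plan.test_idx, 12)]:
            counts = [(labels[idx] == c).sum() for c in (fg.NORMAL, fg.FROST)]
            assert counts == [expected, expected]

    def test_disjoint_and_exhaustive(self):
        plan = stratified_split(BALANCED_240, seed=3)
        merged = np.concatenate([plan.train_idx, plan.val_idx, plan.test_idx])
        assert sorted(merged) == list(range(240))

    def test_deterministic_per_seed(self):
        a = stratified_split(BALANCED_240, seed=5)
        b = stratified_split(BALANCED_240, seed=5)
        assert np.array_equal(a.test_idx, b.test_idx)

    def test_seeds_give_distinct_test_sets(self):
        tests = {tuple(stratified_split(BALANCED_240, seed=s).test_idx)
                 for s in range(10)}
        assert len(tests) == 10

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            stratified_split(BALANCED_240, ratios=(0.7, 0.2, 0.2))

    def test_minimum_class_size(self):
        with pytest.raises(ValueError, match="at least 10"):
            stratified_split([fg.NORMAL] * 5 + [fg.FROST] * 20)

    def test_largest_remainder_within_one_sample(self):
        labels = [fg.NORMAL] * 23 + [fg.FROST] * 17
        plan = stratified_split(labels, seed=1)
        arr = np.array(labels)
        for idx, ratio in [(plan.train_idx, 0.7), (plan.val_idx, 0.2),
                           (plan.test_idx, 0.1)]:
            for cls, n_cls in ((fg.NORMAL, 23), (fg.FROST, 17)):
                got = (arr[idx] == cls).sum()
                assert abs(got - ratio * n_cls) <= 1


class TestComputeMetrics:
    def test_hand_computed_example(self):
        m = compute_metrics([[10, 1], [2, 11]])
        normal = m["per_class"][fg.NORMAL]
        assert normal["precision"] == pytest.approx(0.8333, abs=1e-4)
        assert normal["recall"] == pytest.approx(0.9091, abs=1e-4)
        assert normal["f1"] == pytest.approx(0.8696, abs=1e-4)
        assert m["accuracy"] == pytest.approx(0.875)

    def test_perfect_prediction(self):
        m = compute_metrics([[12, 0], [0, 12]])
        assert m["accuracy"] == 1.0
        for cls in (fg.NORMAL, fg.FROST):
            assert all(v == 1.0 for v in m["per_class"][cls].values())

    def test_coin_flip_confusion(self):
        m = compute_metrics([[6, 6], [6, 6]])
        assert m["accuracy"] == 0.5
        assert m["per_class"][fg.NORMAL]["f1"] == pytest.approx(0.5)

    def test_degenerate_flagged_not_crashed(self):
        m = compute_metrics([[0, 10], [0, 10]])
        assert m["degenerate"]
        assert m["per_class"][fg.NORMAL]["precision"] == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([[0, 0], [0, 0]])


def _fake_run(seed, accs):
    metrics = {}
    for subset, acc in zip(("train", "val", "test"), accs):
        per = {c: {"precision": acc, "recall": acc, "f1": acc}
               for c in (fg.NORMAL, fg.FROST)}
        metrics[subset] = {"accuracy": acc, "per_class": per,
                           "degenerate": False}
    return RunResult(seed=seed, kind="fusion", train_loss_history=[],
                     val_loss_history=[], best_epoch=0, best_val_loss=0.0,
                     confusions={}, metrics=metrics, n_params=0,
                     stopped_epoch=0)


class TestAggregation:
    def test_constant_metric(self):
        report = aggregate_results(
            {"fusion": [_fake_run(s, (0.9, 0.9, 0.9)) for s in range(10)]})
        cell = report.table["fusion"]["test"]["accuracy"]
        assert cell == {"mean": pytest.approx(0.9), "sd": pytest.approx(0.0)}

    def test_two_point_sample_sd(self):
        report = aggregate_results(
            {"fusion": [_fake_run(0, (1, 1, 0.8)), _fake_run(1, (1, 1, 1.0))]})
        cell = report.table["fusion"]["test"]["accuracy"]
        assert cell["mean"] == pytest.approx(0.9)
        assert cell["sd"] == pytest.approx(0.1414, abs=1e-4)

    def test_single_run_rejected(self):
        with pytest.raises(ValueError, match="repeats"):
            aggregate_results({"fusion": [_fake_run(0, (1, 1, 1))]})

    def test_report_complete(self):
        runs = {k: [_fake_run(s, (0.9, 0.8, 0.7)) for s in range(3)]
                for k in ("fusion", "rnn")}
        report = aggregate_results(runs)
        for kind in runs:
            for subset in ("train", "val", "test"):
                entry = report.table[kind][subset]
                assert set(entry) == {"accuracy", fg.NORMAL, fg.FROST}


@pytest.fixture(scope="module")
def toy_run():
    inputs = make_toy_inputs(n_per_class=20, seed=0)
    plan = stratified_split([m.label for m in inputs], seed=0)
    tcfg = fg.TrainingConfig(max_epochs=60, patience=10, seed=0)
    result, model = train_run("pressure_only", inputs, plan, tcfg,
                              return_model=True)
    return inputs, plan, result, model


class TestTrainRun:
    def test_separable_classes_perfect_test_accuracy(self, toy_run):
        _, _, result, _ = toy_run
        assert result.metrics["test"]["accuracy"] == 1.0

    def test_history_bounded_by_max_epochs(self, toy_run):
        _, _, result, _ = toy_run
        assert len(result.val_loss_history) <= 300
        assert result.best_epoch <= result.stopped_epoch

    def test_restored_params_reproduce_best_val_loss(self, toy_run):
        inputs, plan, result, model = toy_run
        P, V, Y = stack_inputs(inputs)
        re_eval = _mean_loss(model, P, V, Y, plan.val_idx)
        assert re_eval == pytest.approx(result.best_val_loss, abs=1e-6)
        assert re_eval == pytest.approx(
            min(result.val_loss_history), abs=1e-12)

    def test_confusion_marginals_match_subset_sizes(self, toy_run):
        inputs, plan, result, _ = toy_run
        labels = np.array([m.label for m in inputs])
        for subset, idx in plan.subsets().items():
            cm = np.array(result.confusions[subset])
            assert cm.sum() == len(idx)
            row_sums = cm.sum(axis=1)
            for c, cls in enumerate((fg.NORMAL, fg.FROST)):
                assert row_sums[c] == (labels[idx] == cls).sum()

    def test_empty_subset_rejected(self):
        inputs = make_toy_inputs(n_per_class=20, seed=0)
        plan = stratified_split([m.label for m in inputs], seed=0)
        plan.test_idx = np.array([], dtype=int)
        with pytest.raises(ValueError, match="empty"):
            train_run("pressure_only", inputs, plan, fg.TrainingConfig(seed=0))


class TestRepeatProtocol:
    def test_single_repeat_rejected(self):
        inputs = make_toy_inputs(n_per_class=20)
        with pytest.raises(ValueError, match="repeats"):
            repeat_protocol(("pressure_only",), inputs, n_repeats=1)

    def test_kinds_share_split_seeds(self):
        inputs = make_toy_inputs(n_per_class=15, seed=2)
        tcfg = fg.TrainingConfig(max_epochs=5, patience=4, seed=0)
        results, report = repeat_protocol(
            ("pressure_only", "vibration_only"), inputs, n_repeats=2,
            base_seed=11, tcfg=tcfg)
        assert [r.seed for r in results["pressure_only"]] == \
            [r.seed for r in results["vibration_only"]] == [11, 12]
        assert set(report.table) == {"pressure_only", "vibration_only"}
        # aggregate recomputation from the stored runs matches exactly
        assert aggregate_results(results).to_dict() == report.to_dict()
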