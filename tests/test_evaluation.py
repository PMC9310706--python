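"""Metrics, AUC oracle equivalence, CV structure, paired comparisons."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from milrad import (
    ConfusionCounts,
    MILModelConfig,
    OversampleConfig,
    TrainConfig,
    compare_methods,
    compute_auc,
    compute_metrics,
    cross_validate,
    sweep_oversampling,
)
from milrad.evaluation import CVReport
from milrad.synthetic import SimConfig, simulate_dataset

FAST_MODEL = MILModelConfig(input_dim=10, hidden_dims=(8, 6), attention_dim=4)
FAST_TRAIN = TrainConfig(epochs=3, seed=0)


@pytest.fixture(scope="module")
def small_bags():
    cfg = SimConfig(n_subjects=30, n_features=10, signal_features=3, seed=8)
    bags, _ = simulate_dataset(cfg)
    return bags


class TestMetrics:
    def test_arithmetic(self):
        m = compute_metrics(ConfusionCounts(tp=3, tn=1, fp=0, fn=1))
        assert m == {"recall": 0.75, "accuracy": 0.8, "ppv": 1.0, "npv": 0.5}

    def test_zero_over_zero_flagged_undefined(self):
        m = compute_metrics(ConfusionCounts(tp=0, tn=2, fp=0, fn=1))
        assert np.isnan(m["ppv"])
        assert m["npv"] == 2 / 3

    def test_all_correct_gives_ones(self):
        m = compute_metrics(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert all(v == 1.0 for v in m.values())


class TestAUC:
    def test_perfect_separation(self):
        assert compute_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_constant_scores_give_half(self):
        assert compute_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_single_class_undefined(self):
        assert np.isnan(compute_auc([1, 1, 1], [0.2, 0.5, 0.9]))

    def test_matches_pairwise_oracle_and_sklearn(self, rng):
        """Rank AUC equals the O(n^2) pairwise comparison count (ties get
        half credit) on 50 random score sets, to 1e-12."""
        for _ in range(50):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, size=n)
            if len(set(y.tolist())) < 2:
                y[0], y[1] = 0, 1
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            pos, neg = scores[y == 1], scores[y == 0]
            wins = sum(
                1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
            )
            oracle = wins / (len(pos) * len(neg))
            assert abs(compute_auc(y, scores) - oracle) < 1e-12
            assert compute_auc(y, scores) == pytest.approx(roc_auc_score(y, scores))


def _mock_report(values, signature=("s",)):
    n = len(values)
    rep = pd.DataFrame(
        {
            "repetition": range(n), "tp": 1, "tn": 1, "fp": 0, "fn": 0,
            "recall": values, "accuracy": values, "ppv": values,
            "npv": values, "auc": values,
        }
    )
    return CVReport("m", rep.copy(), rep, signature)


class TestCompareMethods:
    def test_identical_reports_give_p_one(self):
        v = np.linspace(0.5, 0.9, 20)
        assert compare_methods(_mock_report(v), _mock_report(v)) == 1.0

    def test_uniform_improvement_reaches_minimal_p(self):
        """One method better by a constant in all 20 repetitions: the
        sign-flip null puts the observed statistic at the extreme, so the
        two-sided p cannot go below 2 * 2**-20 and must be tiny."""
        v = np.linspace(0.5, 0.9, 20)
        p = compare_methods(_mock_report(v + 0.05), _mock_report(v))
        assert 2 * 2.0**-20 <= p < 1e-4

    def test_unpaired_reports_rejected(self):
        a = _mock_report(np.ones(5), signature=("a",))
        b = _mock_report(np.ones(5), signature=("b",))
        with pytest.raises(ValueError, match="not paired"):
            compare_methods(a, b)


class TestCrossValidate:
    def test_each_subject_tested_exactly_once_per_repetition(self, small_bags):
        report = cross_validate(
            small_bags, FAST_MODEL, FAST_TRAIN, n_repetitions=2, n_folds=5, seed=4
        )
        per_rep = report.fold_records.groupby("repetition")[["tp", "tn", "fp", "fn"]].sum()
        assert (per_rep.sum(axis=1) == len(small_bags)).all()
        assert report.fold_records.groupby("repetition")["fold"].nunique().eq(5).all()

    def test_fixed_seed_reports_bit_identical(self, small_bags):
        kw = dict(n_repetitions=2, n_folds=3, seed=7)
        a = cross_validate(small_bags, FAST_MODEL, FAST_TRAIN, **kw)
        b = cross_validate(small_bags, FAST_MODEL, FAST_TRAIN, **kw)
        pd.testing.assert_frame_equal(a.fold_records, b.fold_records)
        pd.testing.assert_frame_equal(a.rep_metrics, b.rep_metrics)

    def test_no_shuffle_makes_repetitions_identical(self, small_bags):
        report = cross_validate(
            small_bags, FAST_MODEL, FAST_TRAIN,
            n_repetitions=2, n_folds=3, seed=5, shuffle=False,
        )
        r0 = report.fold_records.query("repetition == 0").drop(columns="repetition")
        r1 = report.fold_records.query("repetition == 1").drop(columns="repetition")
        pd.testing.assert_frame_equal(r0.reset_index(drop=True), r1.reset_index(drop=True))

    def test_methods_share_splits_and_are_paired(self, small_bags):
        reports = cross_validate(
            small_bags,
            {"attention": FAST_MODEL,
             "mean": MILModelConfig(**{**FAST_MODEL.to_dict(), "pooling": "mean"})},
            FAST_TRAIN, n_repetitions=2, n_folds=3, seed=2,
        )
        assert set(reports) == {"attention", "mean"}
        p = compare_methods(reports["attention"], reports["mean"])
        assert 0.0 < p <= 1.0

    def test_synthetic_bags_rejected_as_cv_input(self):
        cfg = SimConfig(n_subjects=6, n_features=10, signal_features=3, seed=2)
        bad, _ = simulate_dataset(cfg)
        bad[0].synthetic = True
        with pytest.raises(ValueError, match="real bags"):
            cross_validate(bad, FAST_MODEL, FAST_TRAIN, n_repetitions=1, n_folds=2)

    def test_oversampling_level_zero_equals_plain_cv(self, small_bags):
        kw = dict(n_repetitions=1, n_folds=3, seed=3)
        sweep = sweep_oversampling(
            small_bags, FAST_MODEL, FAST_TRAIN, levels=(0, 5), **kw
        )
        plain = cross_validate(small_bags, FAST_MODEL, FAST_TRAIN, **kw)
        pd.testing.assert_frame_equal(sweep[0].rep_metrics, plain.rep_metrics)
        assert set(sweep) == {0, 5}

    def test_report_aggregation_shapes(self, small_bags):
        report = cross_validate(
            small_bags, FAST_MODEL, FAST_TRAIN, n_repetitions=3, n_folds=3, seed=1
        )
        for metric in ("recall", "accuracy", "ppv", "npv", "auc"):
            assert 0.0 <= report.mean(metric) <= 1.0
            assert report.sem(metric) >= 0.0
        assert "Cross-validation report" in report.summary()
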