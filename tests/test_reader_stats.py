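"""Evaluation statistics: metrics, scores, ROC, bootstrap, models."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from conftest import concordant_pair_auc
from polypcadx.datamodel import ClipCall, Confidence, Histology
from polypcadx.reader_stats import (
    accuracy_model,
    agreement_histogram,
    auc_mann_whitney,
    cadx_score,
    hierarchical_bootstrap,
    margin_test,
    metric_block,
    reviewer_score,
    roc_auc,
    sample_size,
)

A, NA, U = ClipCall.ADENOMA, ClipCall.NON_ADENOMA, ClipCall.UNDETERMINED
HA, HN = Histology.ADENOMA, Histology.NON_ADENOMA


class TestReviewerScore:
    def test_eight_levels(self):
        levels = [
            reviewer_score(A, Confidence.VERY_HIGH),
            reviewer_score(A, Confidence.HIGH),
            reviewer_score(A, Confidence.LOW),
            reviewer_score(A, Confidence.VERY_LOW),
            reviewer_score(NA, Confidence.VERY_LOW),
            reviewer_score(NA, Confidence.LOW),
            reviewer_score(NA, Confidence.HIGH),
            reviewer_score(NA, Confidence.VERY_HIGH),
        ]
        assert levels == [8, 7, 6, 5, 4, 3, 2, 1]

    def test_undetermined_has_no_score(self):
        with pytest.raises(ValueError):
            reviewer_score(U, Confidence.HIGH)

    def test_roc_invariant_under_monotone_relabeling(self, rng):
        scores = rng.integers(1, 9, size=60).astype(float)
        labels = rng.random(60) < 0.4
        labels[0], labels[1] = True, False
        relabeled = 2.0 ** scores  # strictly monotone transform
        assert auc_mann_whitney(scores, labels) == pytest.approx(
            auc_mann_whitney(relabeled, labels)
        )


class TestCadxScore:
    def test_all_adenoma(self):
        assert cadx_score(7, 0) == 1.0

    def test_ratio(self):
        assert cadx_score(3, 9) == 0.25

    def test_no_predictions_absent(self):
        assert cadx_score(0, 0) is None


class TestMetricBlock:
    def test_all_correct(self):
        b = metric_block([A, NA], [HA, HN])
        assert b.accuracy == 1.0 and b.undetermined_rate == 0.0
        assert b.sensitivity == 1.0 and b.specificity == 1.0

    def test_partial_with_undetermined(self):
        calls = [A, A, NA, U]
        truths = [HA, HN, HN, HA]
        b = metric_block(calls, truths)
        assert b.accuracy == pytest.approx(2 / 3)
        assert b.undetermined_rate == 0.25
        assert b.n_determined + 1 == b.n_total

    def test_all_undetermined_flagged(self):
        b = metric_block([U, U], [HA, HN])
        assert b.undetermined_rate == 1.0
        assert b.accuracy is None
        assert "accuracy" in b.undefined

    def test_count_conservation(self, rng):
        calls = [rng.choice([A, NA, U]) for _ in range(40)]
        truths = [rng.choice([HA, HN]) for _ in range(40)]
        b = metric_block(calls, truths)
        assert b.n_determined == sum(1 for c in calls if c is not U)


class TestRocAuc:
    def test_perfect_separation(self):
        curve = roc_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert curve.auc == 1.0

    def test_three_of_four_concordant(self):
        curve = roc_auc([0.9, 0.6, 0.5, 0.7], [True, True, False, False])
        assert curve.auc == 0.75

    def test_all_ties(self):
        assert roc_auc([0.5] * 6, [True, False] * 3).auc == 0.5

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [True, True])

    def test_curve_monotone(self, rng):
        scores = rng.random(50)
        labels = rng.random(50) < 0.5
        labels[:2] = [True, False]
        curve = roc_auc(scores, labels)
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)

    def test_matches_oracles(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 20))
            scores = np.round(rng.random(n), 1)  # force ties
            labels = rng.random(n) < 0.5
            labels[:2] = [True, False]
            got = auc_mann_whitney(scores, labels)
            assert got == pytest.approx(concordant_pair_auc(scores, labels))
            assert got == pytest.approx(roc_auc_score(labels, scores))


class TestMarginTest:
    def test_non_inferior(self):
        assert margin_test((-0.04, 0.03), 0.10, "non_inferiority") == "non_inferior"

    def test_superior(self):
        assert margin_test((0.01, 0.12), mode="superiority") == "superior"

    def test_inconclusive(self):
        assert margin_test((-0.12, 0.02), 0.10, "non_inferiority") == "inconclusive"

    def test_monotone_in_lower_bound(self):
        verdicts = [
            margin_test((lo, 0.5), 0.10, "non_inferiority")
            for lo in (-0.2, -0.1001, -0.0999, 0.0, 0.2)
        ]
        # once non-inferior, stays non-inferior as the bound rises
        first_pass = verdicts.index("non_inferior")
        assert all(v == "non_inferior" for v in verdicts[first_pass:])


class TestSampleSize:
    @pytest.mark.parametrize(
        "n,dropout,expected", [(480, 0.05, 504), (480, 0.0, 480), (100, 0.10, 110)]
    )
    def test_inflation(self, n, dropout, expected):
        assert sample_size(n, dropout) == expected

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            sample_size(0, 0.05)
        with pytest.raises(ValueError):
            sample_size(100, 1.0)


def _toy_study(rng, n_polyps=60, n_rev=(4, 5)):
    truth = rng.random(n_polyps) < 0.4
    truth[:2] = [True, False]
    wl = np.clip(truth + rng.normal(0, 0.35, n_polyps), 0, 1).astype(float)
    panels = {}
    for name, k in zip(("experts", "non_experts"), n_rev):
        m = np.clip(
            4.5 + 3.0 * (truth * 2 - 1) + rng.normal(0, 2.0, (k, n_polyps)), 1, 8
        ).round()
        panels[name] = m
    return truth, {"cadx_wl": wl}, panels


class TestHierarchicalBootstrap:
    def test_identity_resample_recovers_point_estimates(self, rng):
        truth, polyp_scores, panels = _toy_study(rng)
        res = hierarchical_bootstrap(
            truth, polyp_scores, panels,
            contrasts=(("cadx_wl", "experts"),),
            n_iterations=1, seed=0, resampler="identity",
        )
        for name in res.point:
            assert res.samples[name][0] == pytest.approx(res.point[name])
        lo, hi = res.diff_ci["cadx_wl-experts"]
        assert lo == pytest.approx(hi)

    def test_same_seed_reproduces(self, rng):
        truth, polyp_scores, panels = _toy_study(rng)
        a = hierarchical_bootstrap(truth, polyp_scores, panels, n_iterations=50, seed=7)
        b = hierarchical_bootstrap(truth, polyp_scores, panels, n_iterations=50, seed=7)
        assert a.ci == b.ci

    def test_ci_contains_point_estimate(self, rng):
        truth, polyp_scores, panels = _toy_study(rng, n_polyps=120)
        res = hierarchical_bootstrap(
            truth, polyp_scores, panels, n_iterations=200, seed=3
        )
        for name, (lo, hi) in res.ci.items():
            assert lo <= res.point[name] <= hi


class TestAccuracyModel:
    def test_two_group_closed_form(self):
        # saturated two-group log-binomial: ratio = p1/p2 = 0.8/0.6
        correct = np.r_[np.ones(80), np.zeros(20), np.ones(60), np.zeros(40)]
        group = np.r_[np.ones(100, int), np.zeros(100, int)]
        rater = np.r_[["a"] * 100, ["b"] * 100]
        polyp = np.r_[np.arange(100), np.arange(100)].astype(str)
        res = accuracy_model(correct, group, rater, polyp, n_boot=200)
        assert res.ratio == pytest.approx(80 / 60, rel=1e-3)

    def test_null_case_covers_one(self, rng):
        n, k = 200, 4
        correct = (rng.random(n * 2 * k) < 0.8).astype(int)
        group = np.repeat([1, 0], n * k)
        rater = np.r_[
            np.repeat([f"a{i}" for i in range(k)], n),
            np.repeat([f"b{i}" for i in range(k)], n),
        ]
        polyp = np.tile(np.arange(n).astype(str), 2 * k)
        res = accuracy_model(correct, group, rater, polyp, n_boot=300)
        assert res.ratio == pytest.approx(1.0, abs=0.1)
        assert res.ratio_ci[0] <= 1.0 <= res.ratio_ci[1]

    def test_group_must_be_constant_within_rater(self):
        with pytest.raises(ValueError):
            accuracy_model(
                np.array([1, 0]), np.array([0, 1]),
                np.array(["r", "r"]), np.array(["p1", "p2"]),
            )


class TestAgreementHistogram:
    def test_fraction_and_denominator_rule(self):
        calls = pd.DataFrame(
            {
                "group": ["expert"] * 10,
                "polyp_id": ["p"] * 10,
                "call": [A] * 7 + [U] * 3,
            }
        )
        out = agreement_histogram(calls, {"p": HA})
        assert len(out) == 1
        assert out.iloc[0]["fraction_correct"] == 1.0
        assert out.iloc[0]["n_determined"] == 7

    def test_unanimous_disagreement(self):
        calls = pd.DataFrame(
            {"group": ["e"] * 5, "polyp_id": ["p"] * 5, "call": [NA] * 5}
        )
        out = agreement_histogram(calls, {"p": HA})
        assert out.iloc[0]["fraction_correct"] == 0.0
        assert out.iloc[0]["bin"] == 0
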