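import numpy as np
import pandas as pd
import pytest

from reosig.classifier import (
    EvalSummary,
    auc_confidence_interval,
    auc_from_scores,
    classify,
    evaluate,
    roc_points,
)
from reosig.signature import Signature, SignaturePair
from reosig.simulate import SimConfig, distort_monotone, simulate


def _five_pair_signature():
    return Signature(
        anchor="ERG",
        pairs=tuple(SignaturePair(f"R{i}", "gt") for i in range(5)),
    )


def _matrix_for_votes(votes_per_sample):
    """Build a matrix where sample j has ERG above exactly votes[j] partners."""
    sig = _five_pair_signature()
    cols = {}
    for j, n_above in enumerate(votes_per_sample):
        # ERG at 10; partners below (5.0) for the first n_above, above (20) after
        cols[f"s{j}"] = [10.0] + [5.0] * n_above + [20.0] * (5 - n_above)
    m = pd.DataFrame(cols, index=["ERG"] + [f"R{i}" for i in range(5)])
    return m, sig


class TestClassify:
    def test_unanimous_votes_tfp(self):
        m, sig = _matrix_for_votes([5])
        out = classify(m, sig)
        assert out.at["s0", "votes_tfp"] == 5
        assert out.at["s0", "score"] == 1.0
        assert out.at["s0", "predicted"] == "TFP"

    def test_two_of_five_votes_tfn(self):
        m, sig = _matrix_for_votes([2])
        out = classify(m, sig)
        assert out.at["s0", "predicted"] == "TFN"  # 2 < 2.5

    def test_majority_boundary_even_signature(self):
        sig = Signature(anchor="ERG",
                        pairs=(SignaturePair("R0", "gt"), SignaturePair("R1", "gt")))
        m = pd.DataFrame({"s0": [10.0, 5.0, 20.0]}, index=["ERG", "R0", "R1"])
        out = classify(m, sig)
        # 1 of 2 votes is exactly half: ties vote TFP
        assert out.at["s0", "predicted"] == "TFP"

    def test_monotone_invariance_vote_for_vote(self):
        m, truth = simulate(SimConfig(n_genes=50, n_tfn=10, n_tfp=10, seed=6))
        sig = Signature(
            anchor="ERG",
            pairs=tuple(SignaturePair(p, "gt") for p in sorted(truth.planted_partners)),
        )
        base = classify(m, sig)
        for seed in range(5):
            warped = classify(distort_monotone(m, seed=seed), sig)
            pd.testing.assert_frame_equal(base, warped)

    def test_direction_lt_votes(self):
        sig = Signature(anchor="ERG", pairs=(SignaturePair("R0", "lt"),))
        m = pd.DataFrame({"s0": [1.0, 5.0], "s1": [5.0, 1.0]}, index=["ERG", "R0"])
        out = classify(m, sig)
        assert out.at["s0", "predicted"] == "TFP"
        assert out.at["s1", "predicted"] == "TFN"


class TestEvaluate:
    def test_training_cohort_arithmetic(self):
        # 38/46 TFP and 192/226 TFN correct -> accuracy 0.8456, F-1 0.8377
        s = EvalSummary.from_counts(tp=38, fn=8, tn=192, fp=34)
        assert s.accuracy == pytest.approx(0.8456, abs=5e-5)
        assert s.f1 == pytest.approx(0.8377, abs=5e-5)

    def test_validation_cohort_arithmetic(self):
        # 83/103 TFP and 291/352 TFN correct
        s = EvalSummary.from_counts(tp=83, fn=20, tn=291, fp=61)
        assert s.sensitivity == pytest.approx(0.8058, abs=5e-5)
        assert s.accuracy == pytest.approx(0.8220, abs=5e-5)
        assert s.specificity == pytest.approx(291 / 352)

    def test_second_validation_cohort_arithmetic(self):
        # 65/86 TFP and 31/32 TFN correct -> accuracy 81.36%
        s = EvalSummary.from_counts(tp=65, fn=21, tn=31, fp=1)
        assert s.accuracy == pytest.approx(0.8136, abs=5e-5)

    def test_perfect_predictions(self):
        m, sig = _matrix_for_votes([5, 5, 0, 0])
        labels = pd.Series(["TFP", "TFP", "TFN", "TFN"],
                           index=["s0", "s1", "s2", "s3"])
        s = evaluate(classify(m, sig), labels)
        assert (s.sensitivity, s.specificity, s.accuracy, s.f1, s.auc) == (
            1.0, 1.0, 1.0, 1.0, 1.0)

    def test_counts_partition_the_cohort(self):
        m, sig = _matrix_for_votes([5, 3, 2, 0, 4, 1])
        labels = pd.Series(["TFP", "TFP", "TFP", "TFN", "TFN", "TFN"],
                           index=[f"s{j}" for j in range(6)])
        s = evaluate(classify(m, sig), labels)
        assert s.tp + s.fn == 3
        assert s.tn + s.fp == 3
        assert s.accuracy == pytest.approx((s.tp + s.tn) / 6)

    def test_unlabelled_sample_is_error(self):
        m, sig = _matrix_for_votes([5, 0])
        labels = pd.Series(["TFP"], index=["s0"])
        with pytest.raises(ValueError, match="unlabelled"):
            evaluate(classify(m, sig), labels)


def _concordance_auc(scores, y):
    """All-pairs oracle: P(score_TFP > score_TFN) + 0.5 P(tie)."""
    pos = [s for s, t in zip(scores, y) if t]
    neg = [s for s, t in zip(scores, y) if not t]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestROC:
    def test_staircase_ends(self):
        scores = pd.Series([0.2, 0.4, 0.6, 1.0], index=list("abcd"))
        labels = pd.Series(["TFN", "TFN", "TFP", "TFP"], index=list("abcd"))
        pts = roc_points(scores, labels)
        assert tuple(pts[0]) == (0.0, 0.0)
        assert tuple(pts[-1]) == (1.0, 1.0)
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()

    def test_constant_score_auc_half(self):
        scores = pd.Series([0.6] * 6, index=[f"s{i}" for i in range(6)])
        labels = pd.Series(["TFP"] * 3 + ["TFN"] * 3, index=scores.index)
        assert auc_from_scores(scores, labels) == pytest.approx(0.5)

    def test_four_sample_hand_example_matches_concordance(self):
        scores = pd.Series([0.8, 0.4, 0.4, 0.2], index=list("abcd"))
        labels = pd.Series(["TFP", "TFP", "TFN", "TFN"], index=list("abcd"))
        expected = _concordance_auc(scores.tolist(), [True, True, False, False])
        assert auc_from_scores(scores, labels) == pytest.approx(expected)
        assert expected == pytest.approx(0.875)

    @pytest.mark.parametrize("seed", range(20))
    def test_auc_equals_all_pairs_concordance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        scores = pd.Series(rng.integers(0, 6, n) / 5.0,
                           index=[f"s{i}" for i in range(n)])
        y = rng.integers(0, 2, n).astype(bool)
        if y.all() or not y.any():
            y[0] = ~y[0]
        labels = pd.Series(np.where(y, "TFP", "TFN"), index=scores.index)
        assert auc_from_scores(scores, labels) == pytest.approx(
            _concordance_auc(scores.tolist(), y.tolist()), abs=1e-12)
        assert 0.0 <= auc_from_scores(scores, labels) <= 1.0

    def test_single_class_is_error(self):
        scores = pd.Series([0.1, 0.9], index=["a", "b"])
        labels = pd.Series(["TFP", "TFP"], index=["a", "b"])
        with pytest.raises(ValueError, match="both"):
            roc_points(scores, labels)

    def test_bootstrap_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.uniform(size=40), index=[f"s{i}" for i in range(40)])
        labels = pd.Series(np.where(scores > 0.45, "TFP", "TFN").tolist(),
                           index=scores.index)
        lo, hi = auc_confidence_interval(scores, labels, n_boot=200, seed=1)
        point = auc_from_scores(scores, labels)
        assert lo <= point <= hi
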