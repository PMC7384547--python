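"""Confusion/PRF metrics, Cohen's d, learning curves and PELT change points.

PELT is checked against a brute-force exhaustive segmentation search written
here from scratch; Cohen's d against pingouin and F-beta against
scikit-learn computed from raw labels.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import fbeta_score

import roicurate as rc
from roicurate.errors import (
    ShapeMismatchError,
    SizeError,
    UndefinedEffectError,
)
from roicurate.evaluate import ConfusionCounts, prf_scores


# ---------------------------------------------------------------------------
# brute-force change-point oracle (independent of the PELT implementation)
# ---------------------------------------------------------------------------

def _seg_cost(x, i, j):
    seg = x[i:j]
    return float(np.sum((seg - seg.mean()) ** 2))


def exhaustive_change_points(x, penalty):
    """Minimize total L2 cost + penalty per change point over all segmentations."""
    x = np.asarray(x, dtype=float)
    n = x.size
    best_cost, best_breaks = np.inf, []
    for k in range(n):  # number of change points
        for breaks in itertools.combinations(range(1, n), k):
            bounds = [0, *breaks, n]
            cost = sum(_seg_cost(x, a, b) for a, b in zip(bounds, bounds[1:]))
            cost += penalty * k
            if cost < best_cost - 1e-12:
                best_cost, best_breaks = cost, list(breaks)
    return best_breaks, best_cost


class TestConfusion:
    def test_hand_count(self):
        counts, props = rc.confusion([1, 1, 1, 0], [1, 1, 0, 0])
        assert (counts.tp, counts.fn, counts.tn, counts.fp) == (2, 1, 1, 0)
        np.testing.assert_allclose(props[0], [2 / 3, 1 / 3])
        np.testing.assert_allclose(props[1], [0.0, 1.0])

    def test_identity_diagonal_one(self):
        y = [1, 0, 1, 1, 0]
        counts, props = rc.confusion(y, y)
        assert counts.fp == counts.fn == 0
        np.testing.assert_allclose(np.diag(props), 1.0)

    def test_complement_diagonal_zero(self):
        y = np.array([1, 0, 1, 1, 0])
        _, props = rc.confusion(y, 1 - y)
        np.testing.assert_allclose(np.diag(props), 0.0)

    def test_string_labels_accepted(self):
        counts, _ = rc.confusion(["include", "exclude"], ["include", "include"])
        assert (counts.tp, counts.fp) == (1, 1)

    def test_length_mismatch(self):
        with pytest.raises(ShapeMismatchError):
            rc.confusion([1, 0], [1])

    def test_rows_sum_to_one(self, rng):
        y_true = rng.integers(0, 2, 50)
        y_true[0], y_true[1] = 0, 1  # both classes present
        y_pred = rng.integers(0, 2, 50)
        _, props = rc.confusion(y_true, y_pred)
        np.testing.assert_allclose(props.sum(axis=1), 1.0)


class TestPRF:
    def test_direct_formula(self):
        s = prf_scores(ConfusionCounts(tp=8, fp=2, fn=2, tn=0))
        assert (s.precision, s.recall, s.f_beta) == (0.8, 0.8, pytest.approx(0.8))

    def test_perfect_classifier(self):
        s = prf_scores(ConfusionCounts(tp=10, fp=0, fn=0, tn=5))
        assert s.precision == s.recall == s.f_beta == 1.0
        assert not s.degenerate

    def test_beta_limits(self):
        c = ConfusionCounts(tp=6, fp=4, fn=2, tn=8)
        p, r = 0.6, 0.75
        assert prf_scores(c, beta=1e4).f_beta == pytest.approx(r, abs=1e-4)
        assert prf_scores(c, beta=1e-4).f_beta == pytest.approx(p, abs=1e-4)

    def test_degenerate_counts_flagged_zero(self):
        s = prf_scores(ConfusionCounts(tp=0, fp=0, fn=0, tn=5))
        assert s.f_beta == 0.0 and s.degenerate

    @given(tp=st.integers(0, 50), fp=st.integers(0, 50),
           fn=st.integers(0, 50), tn=st.integers(0, 50))
    def test_f1_bounded_by_precision_and_recall(self, tp, fp, fn, tn):
        s = prf_scores(ConfusionCounts(tp, fp, fn, tn))
        if not s.degenerate:
            assert min(s.precision, s.recall) - 1e-12 <= s.f_beta
            assert s.f_beta <= max(s.precision, s.recall) + 1e-12

    def test_fbeta_matches_sklearn_on_random_counts(self, rng):
        for _ in range(1000):
            tp, fp, fn, tn = rng.integers(0, 20, size=4)
            if tp + fn == 0 or tp + fp == 0:
                continue
            beta = float(rng.uniform(0.2, 4.0))
            y_true = [1] * tp + [0] * fp + [1] * fn + [0] * tn
            y_pred = [1] * tp + [1] * fp + [0] * fn + [0] * tn
            expected = fbeta_score(y_true, y_pred, beta=beta, zero_division=0)
            got = prf_scores(ConfusionCounts(tp, fp, fn, tn), beta=beta).f_beta
            assert got == pytest.approx(expected, abs=1e-12)


class TestInterrater:
    def test_identical_raters(self):
        agreement, _ = rc.interrater_agreement([1, 0, 1], [1, 0, 1])
        assert agreement == 1.0

    def test_87_percent_on_100(self, rng):
        a = rng.integers(0, 2, 100)
        b = a.copy()
        flip = rng.choice(100, 13, replace=False)
        b[flip] = 1 - b[flip]
        agreement, matrix = rc.interrater_agreement(a, b)
        assert agreement == pytest.approx(0.87)
        assert matrix.sum() == 100

    def test_fully_discordant(self):
        agreement, _ = rc.interrater_agreement([1, 0], [0, 1])
        assert agreement == 0.0

    def test_length_mismatch(self):
        with pytest.raises(rc.RoicurateError):
            rc.interrater_agreement([1, 0], [1])


class TestCohensD:
    def test_identical_samples_zero(self):
        assert rc.cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_computation(self):
        assert rc.cohens_d([1, 2, 3], [2, 3, 4]) == pytest.approx(-1.0)

    def test_antisymmetry_and_affine_invariance(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        d = rc.cohens_d(a, b)
        assert rc.cohens_d(b, a) == pytest.approx(-d)
        assert rc.cohens_d(3 * a + 7, 3 * b + 7) == pytest.approx(d)

    def test_zero_pooled_sd_undefined(self):
        with pytest.raises(UndefinedEffectError):
            rc.cohens_d([2.0, 2.0], [5.0, 5.0])

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            rc.cohens_d([1.0], [2.0, 3.0])

    def test_matches_pingouin_on_random_pairs(self, rng):
        pingouin = pytest.importorskip("pingouin")
        for _ in range(1000):
            na, nb = rng.integers(2, 40, size=2)
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), na)
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), nb)
            expected = pingouin.compute_effsize(a, b, eftype="cohen")
            assert rc.cohens_d(a, b) == pytest.approx(expected, abs=1e-10)


class TestCertaintyAnalysis:
    def _preds(self, labels, confs):
        return [rc.Prediction(f"r{i}", l, c) for i, (l, c) in enumerate(zip(labels, confs))]

    def test_all_correct_both_undefined(self):
        preds = self._preds(["include", "exclude"] * 3, [0.9] * 6)
        result = rc.certainty_analysis(preds, ["include", "exclude"] * 3)
        assert result["positive_class"].d is None
        assert result["negative_class"].d is None

    def test_delegates_to_cohens_d(self):
        tp_conf, fp_conf = [0.9, 0.9, 0.8], [0.6, 0.5]
        preds = self._preds(["include"] * 5, tp_conf + fp_conf)
        truth = ["include"] * 3 + ["exclude"] * 2
        result = rc.certainty_analysis(preds, truth)
        assert result["positive_class"].d == pytest.approx(
            rc.cohens_d(tp_conf, fp_conf)
        )
        assert result["negative_class"].d is None  # no predicted excludes

    def test_permutation_invariance(self, rng):
        n = 40
        labels = ["include" if v else "exclude" for v in rng.integers(0, 2, n)]
        confs = rng.uniform(0.5, 1.0, n)
        truth = ["include" if v else "exclude" for v in rng.integers(0, 2, n)]
        preds = self._preds(labels, confs)
        base = rc.certainty_analysis(preds, truth)
        order = rng.permutation(n)
        shuffled = rc.certainty_analysis(
            [preds[i] for i in order], [truth[i] for i in order]
        )
        for key in ("positive_class", "negative_class"):
            if base[key].d is None:
                assert shuffled[key].d is None
            else:
                assert shuffled[key].d == pytest.approx(base[key].d)


class TestChangePoints:
    def test_constant_series_no_change_points(self):
        assert rc.detect_change_points([2.0] * 8, 0.5) == []

    def test_single_step_by_hand(self):
        assert rc.detect_change_points([0, 0, 0, 1, 1, 1], 0.1) == [3]

    def test_huge_penalty_suppresses_all(self, rng):
        x = rng.normal(size=20)
        assert rc.detect_change_points(x, 1e9) == []

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rc.detect_change_points([1.0], 0.1)
        with pytest.raises(ValueError):
            rc.detect_change_points([1.0, 2.0], 0.0)

    def test_pelt_equals_exhaustive_on_random_series(self, rng):
        for trial in range(200):
            n = int(rng.integers(2, 13))
            x = np.round(rng.normal(size=n) + rng.integers(0, 3) *
                         (np.arange(n) > n // 2), 3)
            penalty = float(rng.uniform(0.05, 5.0))
            expected, _ = exhaustive_change_points(x, penalty)
            assert rc.detect_change_points(x, penalty) == expected, (trial, x, penalty)

    def test_count_non_increasing_in_penalty(self, rng):
        x = rng.normal(size=15) + np.repeat([0, 3, 0], 5)
        penalties = [0.01, 0.1, 1.0, 10.0, 100.0]
        counts = [len(rc.detect_change_points(x, p)) for p in penalties]
        assert counts == sorted(counts, reverse=True)

    @settings(max_examples=50)
    @given(
        x=st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=10),
        penalty=st.floats(0.01, 10.0),
    )
    def test_pelt_optimal_cost_property(self, x, penalty):
        got = rc.detect_change_points(x, penalty)
        _, best_cost = exhaustive_change_points(x, penalty)
        bounds = [0, *got, len(x)]
        arr = np.asarray(x)
        cost = sum(_seg_cost(arr, a, b) for a, b in zip(bounds, bounds[1:]))
        cost += penalty * len(got)
        assert cost == pytest.approx(best_cost, abs=1e-9)


@pytest.fixture(scope="module")
def dataset():
    spec = rc.SimSpec(n_rois=150, fov=rc.FOVGeometry(32, 32, 120),
                      footprint_radius=3.0, seed=13)
    coll, _ = rc.make_simulated_ground_truth(spec)
    return rc.assemble_dataset(coll, rc.PreprocessSpec(crop_size=20, trace_len=100),
                               seed=1)


class TestLearningCurve:
    def test_deterministic_in_seed(self, dataset):
        spec = rc.ClassifierSpec(family="decision_tree", seed=0)
        a = rc.learning_curve(dataset, spec, [30, 60, 120], seed=4)
        b = rc.learning_curve(dataset, spec, [30, 60, 120], seed=4)
        assert a.scores == b.scores and a.change_points == b.change_points

    def test_full_size_equals_plain_train_score(self, dataset):
        spec = rc.ClassifierSpec(family="decision_tree", seed=0)
        n_train = len(dataset.y_train)
        curve = rc.learning_curve(dataset, spec, [30, n_train], seed=0)
        bundle = rc.train(dataset, spec, run_cv=False)
        preds = rc.predict(bundle, dataset.X_test)
        y_hat = [1 if p.label == "include" else 0 for p in preds]
        counts, _ = rc.confusion(dataset.y_test, y_hat)
        assert curve.scores[-1] == pytest.approx(prf_scores(counts).f_beta)

    def test_sizes_validation(self, dataset):
        spec = rc.ClassifierSpec(seed=0)
        with pytest.raises(ValueError):
            rc.learning_curve(dataset, spec, [60, 30], seed=0)
        with pytest.raises(SizeError):
            rc.learning_curve(dataset, spec, [30, 10 ** 6], seed=0)
        with pytest.raises(SizeError):
            rc.learning_curve(dataset, spec, [4, 30], seed=0)

    def test_nested_subsamples_monotone_trend(self, dataset):
        """Larger training sets should not score much worse (noise allowance)."""
        spec = rc.ClassifierSpec(family="decision_tree", seed=0)
        deficits = []
        for seed in range(10):
            curve = rc.learning_curve(dataset, spec, [50, 100], seed=seed)
            deficits.append(curve.scores[0] - curve.scores[1])
        assert np.median(deficits) <= 0.05

    def test_plateau_size_reported(self, dataset):
        curve = rc.LearningCurve(sizes=[50, 100, 200], scores=[0.5, 0.9, 0.91],
                                 change_points=[1], penalty=0.1)
        assert curve.plateau_size == 100
        flat = rc.LearningCurve(sizes=[50, 100], scores=[0.9, 0.9],
                                change_points=[], penalty=0.1)
        assert flat.plateau_size is None


def test_evaluation_report_round_trips_json(tmp_path, rng):
    truth = ["include"] * 8 + ["exclude"] * 4
    preds = [rc.Prediction(f"r{i}", t if rng.random() > 0.2 else
                           ("exclude" if t == "include" else "include"),
                           float(rng.uniform(0.5, 1)))
             for i, t in enumerate(truth)]
    report = rc.evaluation_report(truth, preds)
    path = tmp_path / "report.json"
    rc.evaluate.export_report(report, str(path))
    import json

    loaded = json.loads(path.read_text())
    assert loaded["n"] == 12
    assert 0.0 <= loaded["f_beta"] <= 1.0
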