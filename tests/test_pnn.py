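"""PNN classifier: kernel closed forms, invariances, LOO evaluation."""

import numpy as np
import pytest

from mucotex.exceptions import DegenerateDataError, ValidationError
from mucotex.pnn import (ConfusionCounts, PNNModel, class_score, evaluate_loo,
                         evaluate_resubstitution, fit, predict, select_sigma)


def _raw_model(sigma=0.5, positive="B"):
    """Two single-point classes on already-standardized axes (identity scaling)."""
    return PNNModel(labels=("A", "B"),
                    patterns=(np.zeros((1, 3)), np.ones((1, 3))),
                    priors=(0.5, 0.5), sigma=sigma,
                    feature_mean=np.zeros(3), feature_sd=np.ones(3),
                    positive_label=positive)


class TestScores:
    def test_single_kernel_closed_form(self):
        scores = class_score(_raw_model(sigma=0.5), np.zeros(3))
        assert scores["A"] == pytest.approx(0.5, abs=1e-12)
        assert scores["B"] == pytest.approx(0.5 * np.exp(-6.0), rel=1e-12)

    def test_query_near_b_predicts_b(self):
        assert predict(_raw_model(), np.full(3, 0.9)) == "B"

    def test_midpoint_tie_goes_to_positive_class(self):
        assert predict(_raw_model(positive="B"), np.full(3, 0.5)) == "B"
        assert predict(_raw_model(positive="A"), np.full(3, 0.5)) == "A"

    def test_far_query_scores_vanish(self):
        scores = class_score(_raw_model(sigma=0.3), np.full(3, 50.0))
        assert max(scores.values()) < 1e-100

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            class_score(_raw_model(), np.zeros(2))


class TestFit:
    def test_pattern_units_stored_per_class(self, rng):
        x = rng.standard_normal((70, 3))
        y = np.array(["lesion"] * 35 + ["normal"] * 35)
        model = fit(x, y, sigma=0.4)
        assert {len(p) for p in model.patterns} == {35}
        assert model.priors == (0.5, 0.5)

    def test_single_case_per_class_is_valid(self):
        model = fit(np.array([[0.0, 1.0], [1.0, 0.0]]), np.array(["a", "b"]), sigma=1.0)
        assert len(model.labels) == 2

    def test_invalid_sigma_and_degenerate_feature(self, rng):
        x = rng.standard_normal((10, 2))
        y = np.array(["a", "b"] * 5)
        with pytest.raises(ValidationError):
            fit(x, y, sigma=0.0)
        x[:, 1] = 7.0
        with pytest.raises(DegenerateDataError):
            fit(x, y, sigma=0.5)

    def test_training_point_recovered_at_small_sigma(self, rng):
        x = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(8, 1, (20, 3))])
        y = np.array(["normal"] * 20 + ["lesion"] * 20)
        model = fit(x, y, sigma=0.1)
        assert predict(model, x[30]) == "lesion"


class TestInvariances:
    def test_one_point_per_class_is_nearest_neighbour(self, rng):
        """Equal priors, one pattern each: the PNN is 1-NN for every sigma."""
        for _ in range(20):
            pts = rng.standard_normal((2, 3)) * 3
            model = PNNModel(labels=("A", "B"), patterns=(pts[:1], pts[1:]),
                             priors=(0.5, 0.5), sigma=float(rng.uniform(0.05, 5)),
                             feature_mean=np.zeros(3), feature_sd=np.ones(3))
            q = rng.standard_normal(3) * 3
            nearest = "A" if np.linalg.norm(q - pts[0]) < np.linalg.norm(q - pts[1]) else "B"
            assert predict(model, q) == nearest

    def test_loo_invariant_to_affine_feature_rescaling(self, rng):
        x = np.vstack([rng.normal(0, 1, (15, 3)), rng.normal(1.5, 1, (15, 3))])
        y = np.array(["normal"] * 15 + ["lesion"] * 15)
        cc1, _, _ = evaluate_loo(x, y, sigma=0.6)
        x2 = x.copy()
        x2[:, 0] = x2[:, 0] * 1000.0 - 77.0
        x2[:, 2] = x2[:, 2] * -0.01 + 5.0
        cc2, _, _ = evaluate_loo(x2, y, sigma=0.6)
        assert (cc1.tp, cc1.fn, cc1.tn, cc1.fp) == (cc2.tp, cc2.fn, cc2.tn, cc2.fp)


class TestEvaluation:
    def test_reported_confusion_arithmetic(self):
        cc = ConfusionCounts(tp=35, fn=0, tn=34, fp=1)
        assert cc.percent_metrics() == {"sensitivity_pct": 100.0, "specificity_pct": 97.0}

    def test_perfect_separation_scores_100(self, rng):
        x = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))])
        y = np.array(["normal"] * 10 + ["lesion"] * 10)
        cc, sens, spec = evaluate_loo(x, y, sigma=0.5)
        assert sens == 1.0 and spec == 1.0

    def test_resubstitution_at_least_as_good_as_loo(self, rng):
        x = np.vstack([rng.normal(0, 1, (20, 2)), rng.normal(1, 1, (20, 2))])
        y = np.array(["normal"] * 20 + ["lesion"] * 20)
        cc_loo, _, _ = evaluate_loo(x, y, sigma=0.3)
        cc_res = evaluate_resubstitution(x, y, sigma=0.3)
        assert cc_res.tp + cc_res.tn >= cc_loo.tp + cc_loo.tn

    def test_shuffled_labels_score_near_chance(self, rng):
        """Permutation null: mean LOO sensitivity should hover around 50%."""
        x = rng.standard_normal((24, 3))
        sens = []
        for _ in range(60):
            y = rng.permutation(np.array(["normal"] * 12 + ["lesion"] * 12))
            _, s, _ = evaluate_loo(x, y, sigma=0.8)
            sens.append(s)
        assert abs(np.mean(sens) - 0.5) < 0.10

    def test_loo_needs_two_per_class(self, rng):
        x = rng.standard_normal((3, 2))
        y = np.array(["normal", "normal", "lesion"])
        with pytest.raises(ValidationError):
            evaluate_loo(x, y, sigma=0.5)


class TestSigmaSelection:
    def test_single_candidate_returned(self, rng):
        x = np.vstack([rng.normal(0, 1, (8, 2)), rng.normal(3, 1, (8, 2))])
        y = np.array(["normal"] * 8 + ["lesion"] * 8)
        assert select_sigma(x, y, grid=[0.7]) == 0.7

    def test_empty_or_invalid_grid_rejected(self, rng):
        x = rng.standard_normal((8, 2))
        y = np.array(["normal", "lesion"] * 4)
        with pytest.raises(ValidationError):
            select_sigma(x, y, grid=[])
        with pytest.raises(ValidationError):
            select_sigma(x, y, grid=[0.5, -1.0])

    def test_selected_sigma_maximizes_loo_accuracy(self, rng):
        x = np.vstack([rng.normal(0, 1, (15, 2)), rng.normal(2.5, 1, (15, 2))])
        y = np.array(["normal"] * 15 + ["lesion"] * 15)
        grid = [0.05, 0.2, 0.8, 2.0]
        best = select_sigma(x, y, grid=grid)
        accs = {}
        for s in grid:
            cc, _, _ = evaluate_loo(x, y, sigma=s)
            accs[s] = cc.tp + cc.tn
        assert accs[best] == max(accs.values())
        # ties resolve to the smallest candidate
        tied = [s for s, a in accs.items() if a == accs[best]]
        assert best == min(tied)
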