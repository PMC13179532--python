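"""Cluster labelling, contingency tables and validation statistics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soundturn import decisions as dec
from soundturn.decisions import (
    DirectionTable,
    average_correct_rate,
    binomial_p_one_sided,
    combine_decisions,
    contingency,
    label_clusters,
    predict,
    specificity,
)
from soundturn.em import MixtureModel3
from soundturn.reference_counts import reference_table, reference_tables


def lateral_model(left=-0.4, centre=0.01, right=0.4, sd=0.05):
    means = np.array([[left, 0.0], [centre, 0.0], [right, 0.0]])
    return MixtureModel3(np.full(3, 1 / 3), means, np.stack([np.eye(2) * sd**2] * 3))


def training_blobs(model, n=40, seed=0, flip_sides=False):
    rng = np.random.default_rng(seed)
    X, sides = [], []
    for k, side in [(0, "left"), (2, "right")]:
        pts = model.means[k] + 0.03 * rng.standard_normal((n, 2))
        X.append(pts)
        s = side if not flip_sides else ("right" if side == "left" else "left")
        sides += [s] * n
    X.append(model.means[1] + 0.03 * rng.standard_normal((2 * n, 2)))
    sides += ["left", "right"] * n
    return np.concatenate(X), np.asarray(sides)


class TestLabelClusters:
    def test_constructed_alignment(self):
        model = lateral_model()
        X, sides = training_blobs(model)
        lab = label_clusters(model, X, sides)
        assert lab.mapping == ("left", "centre", "right")
        assert lab.decision_axis == 0

    def test_mirrored_data_swaps_left_right_in_space(self):
        """Negating axis 1 swaps which side of the axis is called left/right
        (training agreement follows the data); centre is unchanged."""
        model = lateral_model()
        X, sides = training_blobs(model)
        lab = label_clusters(model, X, sides)
        mirrored = MixtureModel3(model.weights, model.means * [-1, 1],
                                 model.covariances)
        lab_m = label_clusters(mirrored, X * [-1, 1], sides)
        # cluster 0 now sits at +0.4 but keeps its label: the positive side
        # of the axis is now labelled "left"
        assert lab_m.mapping == lab.mapping == ("left", "centre", "right")
        assert mirrored.means[lab_m.cluster_of("left"), 0] > 0
        # mirroring the sides as well swaps the labels themselves
        flipped = np.where(sides == "left", "right", "left")
        lab_f = label_clusters(mirrored, X * [-1, 1], flipped)
        assert lab_f.mapping == ("right", "centre", "left")

    def test_maximizes_training_agreement_over_both_mappings(self):
        """Returned mapping beats the swapped alternative, checked exhaustively."""
        model = lateral_model()
        # sides deliberately mostly OPPOSITE to the sign convention
        X, sides = training_blobs(model, flip_sides=True)
        lab = label_clusters(model, X, sides)
        assign = np.argmax(dec.responsibilities(X, model), axis=1)

        def agreement(mapping):
            return sum(mapping[k] == s for k, s in zip(assign, sides)
                       if mapping[k] != "centre")

        alt = tuple({"left": "right", "right": "left"}.get(c, c)
                    for c in lab.mapping)
        assert agreement(lab.mapping) >= agreement(alt)
        assert lab.mapping == ("right", "centre", "left")

    def test_tied_centre_is_error(self):
        model = lateral_model(left=-0.4, centre=0.4, right=0.4)
        X, sides = training_blobs(model)
        with pytest.raises(dec.LabellingError):
            label_clusters(model, X, sides)


class TestPredict:
    def test_class_of_each_cluster_mean(self):
        model = lateral_model()
        X, sides = training_blobs(model)
        lab = label_clusters(model, X, sides)
        assert predict(model, lab, model.means[0:1])[0] == "left"
        assert predict(model, lab, [[0.01, 0.0]])[0] == "centre"
        assert predict(model, lab, model.means[2:3])[0] == "right"

    def test_agrees_with_posterior_argmax_oracle(self, rng):
        model = lateral_model()
        X, sides = training_blobs(model)
        lab = label_clusters(model, X, sides)
        pts = rng.uniform(-0.6, 0.6, (100, 2))
        preds = predict(model, lab, pts)
        from soundturn.em import posterior
        for p, cls in zip(pts, preds):
            k = int(np.argmax(posterior(model, p)))
            assert lab.mapping[k] == cls


class TestContingency:
    def test_empty_input_all_zero(self):
        t = contingency([], [], "training", "head_rot")
        assert t.counts.sum() == 0 and t.n_decisions == 0

    def test_all_centre(self):
        t = contingency(["centre"] * 10, ["left", "right"] * 5, "training", "head_rot")
        assert t.counts[1].sum() == 10
        assert t.counts[0].sum() == t.counts[2].sum() == 0

    def test_matches_hand_enumeration(self):
        preds = ["left"] * 5 + ["right"] * 4 + ["centre"] * 11
        sides = (["left"] * 3 + ["right"] * 2 + ["right"] * 3 + ["left"] * 1
                 + ["left", "right"] * 5 + ["left"])
        t = contingency(preds, sides, "validation_infant", "gaze_left")
        np.testing.assert_array_equal(t.counts, [[3, 2], [6, 5], [1, 3]])
        assert t.n_trials == 20 and t.n_decisions == 9 and t.n_correct == 6

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            contingency(["left"], [], "training", "head_rot")

    @given(st.lists(st.tuples(st.sampled_from(dec.CLASSES),
                              st.sampled_from(dec.SIDES)), max_size=60))
    @settings(derandomize=True, max_examples=50)
    def test_totals_conserved(self, pairs):
        preds = [p for p, _ in pairs]
        sides = [s for _, s in pairs]
        t = contingency(preds, sides, "training", "head_rot")
        assert t.counts.sum() == len(pairs)
        for j, side in enumerate(dec.SIDES):
            assert t.counts[:, j].sum() == sides.count(side)


class TestSpecificity:
    def test_reported_infant_head_rotation_counts(self):
        t = reference_table("head_rot", "validation_infant")
        assert t.n_decisions == 76 and t.n_correct == 44
        assert specificity(t) == pytest.approx(44 / 76)
        assert round(100 * specificity(t)) == 58

    def test_all_decisions_correct(self):
        t = DirectionTable(np.array([[5, 0], [2, 3], [0, 7]]), "training", "head_rot")
        assert specificity(t) == 1.0

    def test_no_decision_marker(self):
        t = DirectionTable(np.array([[0, 0], [9, 8], [0, 0]]), "training", "head_rot")
        assert specificity(t) is None


class TestBinomial:
    def test_16_of_20(self):
        p = binomial_p_one_sided(16, 20)
        assert p == pytest.approx(0.005909, abs=5e-7)
        assert float(f"{p:.1g}") == 0.006

    def test_k_zero_is_one(self):
        for n in (1, 5, 20):
            assert binomial_p_one_sided(0, n) == 1.0

    @pytest.mark.parametrize("n", [1, 7, 13, 20])
    def test_matches_exhaustive_enumeration(self, n):
        """Exact tail equals counting all 2^n equiprobable outcomes."""
        ones = np.bitwise_count(np.arange(2 ** n, dtype=np.uint32))
        for k in range(n + 1):
            count = int(np.sum(ones >= k))
            assert binomial_p_one_sided(k, n) == pytest.approx(
                count / 2 ** n, rel=1e-12)

    def test_monotone_nonincreasing_in_k(self):
        ps = [binomial_p_one_sided(k, 30) for k in range(31)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert all(0 < p <= 1 for p in ps)

    def test_invalid_inputs_rejected(self):
        for k, n in [(-1, 10), (11, 10), (0, 0)]:
            with pytest.raises(ValueError):
                binomial_p_one_sided(k, n)


class TestAverages:
    def test_reported_infant_average_is_68(self):
        assert average_correct_rate(reference_tables("validation_infant").values()) == 68

    def test_reported_toddler_average_is_96(self):
        assert average_correct_rate(reference_tables("validation_toddler").values()) == 96

    def test_identical_tables_average_to_their_specificity(self):
        t = DirectionTable(np.array([[3, 1], [5, 5], [0, 2]]), "training", "head_rot")
        tables = [DirectionTable(t.counts, "training", fs)
                  for fs in ("head_rot", "gaze_left", "gaze_angle", "pca2")]
        assert average_correct_rate(tables) == round(100 * specificity(t))

    def test_undefined_tables_excluded_with_warning(self):
        empty = DirectionTable(np.array([[0, 0], [4, 4], [0, 0]]), "training", "pca2")
        full = DirectionTable(np.array([[4, 0], [0, 0], [0, 4]]), "training", "head_rot")
        with pytest.warns(UserWarning, match="no"):
            assert average_correct_rate([empty, full]) == 100
        with pytest.warns(UserWarning):
            assert average_correct_rate([empty]) is None


class TestCombine:
    def test_single_source_and_agreement_cases(self):
        combined, s = combine_decisions(["centre", "left", "left"],
                                        ["left", "centre", "left"])
        assert list(combined) == ["left", "left", "left"]
        assert s["n_both"] == 1 and s["n_agree"] == 1 and s["n_conflict"] == 0

    def test_conflict_policy(self):
        combined, s = combine_decisions(["left"], ["right"])
        assert list(combined) == ["right"] and s["n_conflict"] == 1
        combined, _ = combine_decisions(["left"], ["right"], conflict_policy="head")
        assert list(combined) == ["left"]

    def test_hand_enumerated_ten_trials_with_two_conflicts(self):
        head = ["left", "left", "right", "centre", "centre",
                "left", "right", "centre", "right", "centre"]
        gaze = ["left", "right", "left", "left", "centre",
                "left", "right", "right", "centre", "centre"]
        combined, s = combine_decisions(head, gaze)
        assert s == {"n_decisions_head": 6, "n_decisions_gaze": 7,
                     "n_decisions_combined": 8, "n_both": 5, "n_agree": 3,
                     "n_conflict": 2}
        assert list(combined) == ["left", "right", "left", "left", "centre",
                                  "left", "right", "right", "right", "centre"]

    @given(st.lists(st.tuples(st.sampled_from(dec.CLASSES),
                              st.sampled_from(dec.CLASSES)), max_size=50))
    @settings(derandomize=True, max_examples=50)
    def test_never_fewer_decisions_than_either_source(self, pairs):
        head = [h for h, _ in pairs]
        gaze = [g for _, g in pairs]
        _, s = combine_decisions(head, gaze)
        assert s["n_decisions_combined"] >= s["n_decisions_head"]
        assert s["n_decisions_combined"] >= s["n_decisions_gaze"]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine_decisions(["left"], [])
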