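import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from favoxel import (
    CohortConfig,
    SelectionRule,
    direction_sign,
    discriminative_map,
    fisher_score,
    loocv,
    pairwise_contrasts,
    region_mask,
    select_voxels,
    threshold_sweep,
    train_svm,
)
from favoxel.roi_features import FeatureMatrix, features_from_arrays
from favoxel.synthetic_data import cohort_arrays

PAIR = ("AD", "CTRL")


def fisher_oracle(X, y, pair):
    """Brute-force per-voxel Fisher score via explicit loops."""
    out = []
    for j in range(X.shape[1]):
        a = [X[i, j] for i in range(len(y)) if y[i] == pair[0]]
        b = [X[i, j] for i in range(len(y)) if y[i] == pair[1]]
        ma, mb = sum(a) / len(a), sum(b) / len(b)
        va = sum((v - ma) ** 2 for v in a) / (len(a) - 1)
        vb = sum((v - mb) ** 2 for v in b) / (len(b) - 1)
        if va + vb == 0:
            out.append(np.inf if ma != mb else 0.0)
        else:
            out.append((ma - mb) ** 2 / (va + vb))
    return np.array(out)


def two_class_matrix(X, y):
    return FeatureMatrix(
        X, np.zeros((X.shape[1], 3), dtype=int),
        [f"s{i}" for i in range(len(y))], list(y),
    )


class TestFisherScore:
    def test_hand_computed_example(self):
        X = np.array([[0.40], [0.44], [0.30], [0.34]])
        y = np.array(["AD", "AD", "CTRL", "CTRL"])
        fs = fisher_score(X, y, PAIR)
        assert fs.scores[0] == pytest.approx(6.25, rel=1e-12)

    def test_equal_means_zero_score(self):
        X = np.array([[1.0], [2.0], [1.0], [2.0]])
        y = np.array(["AD", "AD", "CTRL", "CTRL"])
        assert fisher_score(X, y, PAIR).scores[0] == 0.0

    def test_degenerate_constant_classes(self):
        X = np.array([[0.0, 5.0], [0.0, 5.0], [1.0, 5.0], [1.0, 5.0]])
        y = np.array(["AD", "AD", "CTRL", "CTRL"])
        scores = fisher_score(X, y, PAIR).scores
        assert np.isposinf(scores[0])  # means differ, variances zero
        assert scores[1] == 0.0  # all identical

    def test_matches_bruteforce_oracle_random(self):
        rng = np.random.default_rng(12)
        X = rng.uniform(0, 1, (30, 100))
        y = np.array(["AD"] * 15 + ["CTRL"] * 15)
        fs = fisher_score(X, y, PAIR)
        np.testing.assert_allclose(fs.scores, fisher_oracle(X, y, PAIR), atol=1e-12)

    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0), st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 1, (10, 5))
        y = np.array(["AD"] * 5 + ["CTRL"] * 5)
        s1 = fisher_score(X, y, PAIR).scores
        s2 = fisher_score(a * X + b, y, PAIR).scores
        np.testing.assert_allclose(s1, s2, rtol=1e-8)

    def test_small_class_rejected(self):
        X = np.zeros((3, 2))
        y = np.array(["AD", "CTRL", "CTRL"])
        with pytest.raises(ValueError, match=">= 2 subjects"):
            fisher_score(X, y, PAIR)


class TestDirectionSign:
    def test_sign_convention_and_tie(self):
        # voxel 0: decrease in AD; voxel 1: increase; voxel 2: tie
        X = np.array(
            [[0.3, 0.6, 0.5], [0.3, 0.6, 0.5], [0.5, 0.4, 0.5], [0.5, 0.4, 0.5]]
        )
        y = np.array(["AD", "AD", "CTRL", "CTRL"])
        signs = direction_sign(X, y, PAIR)
        assert list(signs) == [1.0, -1.0, 0.0]

    def test_tie_excluded_from_both_subsets(self):
        scores = type("S", (), {})()
        X = np.array([[0.5], [0.5], [0.5], [0.5]])
        y = np.array(["AD", "AD", "CTRL", "CTRL"])
        fs = fisher_score(X, y, PAIR)
        signs = direction_sign(X, y, PAIR)
        for direction in ("decrease", "increase"):
            rule = SelectionRule(direction=direction, class_pair=PAIR)
            assert select_voxels(fs, rule, signs).size == 0

    def test_null_voxels_positive_about_half_the_time(self):
        rng = np.random.default_rng(3)
        pos = 0
        n_trials = 200
        for _ in range(n_trials):
            X = rng.normal(0.5, 0.1, (10, 1))
            y = np.array(["AD"] * 5 + ["CTRL"] * 5)
            pos += direction_sign(X, y, PAIR)[0] > 0
        # binomial(200, 0.5) 99.9% interval
        assert 70 < pos < 130


class TestSelectVoxels:
    def _scores(self, values):
        X = np.zeros((4, len(values)))
        y = np.array(["AD", "AD", "CTRL", "CTRL"])
        fs = fisher_score(X, y, PAIR)
        fs.scores = np.asarray(values, dtype=float)
        return fs

    def test_strict_inequality(self):
        fs = self._scores([0.3, 0.5, 1.2, 0.4])
        rule = SelectionRule(fisher_threshold=0.4, class_pair=PAIR)
        assert list(select_voxels(fs, rule)) == [1, 2]

    def test_threshold_above_max_empty(self):
        fs = self._scores([0.3, 0.5])
        rule = SelectionRule(fisher_threshold=10.0, class_pair=PAIR)
        assert select_voxels(fs, rule).size == 0

    def test_zero_threshold_keeps_positive_scores(self):
        fs = self._scores([0.0, 0.1, 0.0, 2.0])
        rule = SelectionRule(fisher_threshold=0.0, class_pair=PAIR)
        assert list(select_voxels(fs, rule)) == [1, 3]

    def test_matches_exhaustive_set_construction(self):
        rng = np.random.default_rng(8)
        scores = rng.exponential(0.5, 200)
        signs = rng.choice([-1.0, 0.0, 1.0], 200)
        fs = self._scores(scores)
        for thr in (None, 0.0, 0.3, 1.0):
            for direction in ("any", "decrease", "increase"):
                rule = SelectionRule(
                    fisher_threshold=thr, direction=direction, class_pair=PAIR
                )
                expected = [
                    j
                    for j in range(200)
                    if (thr is None or scores[j] > thr)
                    and (
                        direction == "any"
                        or (direction == "decrease" and signs[j] > 0)
                        or (direction == "increase" and signs[j] < 0)
                    )
                ]
                assert list(select_voxels(fs, rule, signs)) == expected

    def test_infinite_scores_always_selected(self):
        fs = self._scores([np.inf, 0.1])
        rule = SelectionRule(fisher_threshold=100.0, class_pair=PAIR)
        assert list(select_voxels(fs, rule)) == [0]


class TestSVM:
    def test_separable_1d(self):
        X = np.array([[-1.0], [-1.1], [1.0], [1.1]])
        y = np.array(["CTRL", "CTRL", "AD", "AD"])
        model = train_svm(X, y, PAIR)
        assert list(model.predict(X)) == ["CTRL", "CTRL", "AD", "AD"]

    def test_duplicating_subjects_invariant(self):
        # well separated so no margin violations: solution identical under
        # duplication (which otherwise rescales the effective penalty)
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.2, (10, 3)), rng.normal(3, 0.2, (10, 3))])
        y = np.array(["CTRL"] * 10 + ["AD"] * 10)
        test_points = rng.normal(1.5, 1.5, (20, 3))
        m1 = train_svm(X, y, PAIR)
        m2 = train_svm(np.vstack([X, X]), np.concatenate([y, y]), PAIR)
        assert list(m1.predict(test_points)) == list(m2.predict(test_points))

    def test_symmetric_midpoint_tie_goes_negative(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]])
        y = np.array(["AD", "AD", "CTRL", "CTRL"])
        model = train_svm(X, y, PAIR)
        f = model.decision_function(np.array([[0.0, 0.0]]))
        assert abs(f[0]) < 1e-6
        # an exact zero must resolve to the negative class of the pair
        model.coef_ = np.zeros_like(model.coef_)
        model.intercept_ = 0.0
        assert model.predict(np.array([[0.0, 0.0]]))[0] == "CTRL"

    def test_single_class_rejected(self):
        X = np.zeros((4, 2))
        y = np.array(["AD"] * 4)
        with pytest.raises(ValueError, match="both classes"):
            train_svm(X, y, PAIR)


class TestLOOCV:
    def test_prediction_count_and_accuracy_granularity(self, cingulum_features):
        rule = SelectionRule(class_pair=PAIR)
        res = loocv(cingulum_features, rule)
        assert res.n == 30
        assert res.accuracy == pytest.approx(
            sum(f.true_label == f.predicted_label for f in res.folds) / 30
        )
        assert (res.accuracy * 30) == pytest.approx(round(res.accuracy * 30))

    def test_determinism(self, cingulum_features):
        rule = SelectionRule(fisher_threshold=0.4, class_pair=PAIR)
        r1 = loocv(cingulum_features, rule)
        r2 = loocv(cingulum_features, rule)
        assert [f.predicted_label for f in r1.folds] == [
            f.predicted_label for f in r2.folds
        ]
        assert r1.accuracy == r2.accuracy

    def test_leakage_freedom(self, cingulum_features):
        """Mutating the held-out subject's features must change neither the
        fold's selected voxels nor its decision function."""
        rule = SelectionRule(fisher_threshold=0.4, class_pair=PAIR)
        fm = cingulum_features.subset_groups(["AD", "CTRL"])
        base = loocv(fm, rule)
        mutated = FeatureMatrix(
            fm.values.copy(), fm.voxel_index, fm.subject_ids, fm.groups
        )
        # corrupt subject 0; only the fold holding it out trains without it
        mutated.values[0] = 0.99
        res = loocv(mutated, rule)
        sid = fm.subject_ids[0]
        f0_base = next(f for f in base.folds if f.held_out_id == sid)
        f0_mut = next(f for f in res.folds if f.held_out_id == sid)
        assert np.array_equal(f0_base.selected, f0_mut.selected)
        np.testing.assert_array_equal(f0_base.decision_coef, f0_mut.decision_coef)
        assert f0_base.decision_intercept == f0_mut.decision_intercept

    def test_empty_selection_defaults_to_negative_class(self, cingulum_features):
        rule = SelectionRule(fisher_threshold=1e9, class_pair=PAIR)
        res = loocv(cingulum_features, rule)
        assert all(f.fallback_used for f in res.folds)
        assert all(f.n_selected == 0 for f in res.folds)
        assert all(f.predicted_label == "CTRL" for f in res.folds)
        assert res.accuracy == pytest.approx(0.5)  # balanced folds at chance

    def test_single_subject_fold_mode(self, cingulum_features):
        rule = SelectionRule(class_pair=PAIR)
        res = loocv(cingulum_features, rule, leave_one_pair_out=False)
        assert res.n == 30  # still one prediction per subject
        held = sorted(f.held_out_id for f in res.folds)
        assert held == sorted(cingulum_features.subset_groups(["AD", "CTRL"]).subject_ids)

    def test_planted_effect_recovered(self, cingulum_features):
        rule = SelectionRule(fisher_threshold=0.4, class_pair=PAIR)
        res = loocv(cingulum_features, rule)
        assert res.accuracy > 0.7


class TestSweepAndContrasts:
    def test_sweep_shapes_and_argmax_tiebreak(self, cingulum_features):
        thresholds = np.array([0.0, 0.5, 1.0])
        rule = SelectionRule(class_pair=PAIR)
        sweep = threshold_sweep(cingulum_features, rule, thresholds)
        assert len(sweep.results) == 3
        accs = sweep.accuracies
        ties = np.flatnonzero(accs == accs.max())
        assert sweep.argmax_threshold == thresholds[ties[0]]

    def test_nonincreasing_grid_rejected(self, cingulum_features):
        with pytest.raises(ValueError):
            threshold_sweep(
                cingulum_features, SelectionRule(class_pair=PAIR), np.array([0.5, 0.5])
            )

    def test_pairwise_contrasts_sizes_and_pattern(self, cingulum_features):
        rule = SelectionRule(fisher_threshold=0.4)
        results = pairwise_contrasts(cingulum_features, rule)
        assert set(results) == {("AD", "CTRL"), ("AD", "MCI"), ("MCI", "CTRL")}
        for res in results.values():
            assert res.n == 30
        # planted AD effect, null MCI: the AD contrast dominates
        assert (
            results[("AD", "CTRL")].accuracy >= results[("MCI", "CTRL")].accuracy
        )

    def test_decrease_direction_dominates_increase(self, toy_atlas):
        """With a planted FA decrease, decrease-restricted voxel subsets beat
        increase-restricted ones (median over seeds)."""
        mask = region_mask(toy_atlas, "cingulum_hippocampal")
        dec, inc = [], []
        for seed in range(5):
            cfg = CohortConfig(seed=seed, effect_delta_ad=0.15, subject_sd=0.02,
                               region_offset_sd=0.02)
            ids, groups, fa = cohort_arrays(cfg, toy_atlas)
            fm = features_from_arrays(fa, ids, groups, mask)
            dec.append(loocv(fm, SelectionRule(direction="decrease", class_pair=PAIR)).accuracy)
            inc.append(loocv(fm, SelectionRule(direction="increase", class_pair=PAIR)).accuracy)
        assert np.median(dec) >= np.median(inc)


class TestDiscriminativeMap:
    def test_map_values_equal_fisher_scores(self, cingulum_features, grid20):
        fm = cingulum_features.subset_groups(["AD", "CTRL"])
        fs = fisher_score(fm.values, np.asarray(fm.groups), PAIR)
        score_vol, mask_vol = discriminative_map(
            cingulum_features, grid20, PAIR, threshold=0.4
        )
        coords = tuple(fm.voxel_index.T)
        np.testing.assert_allclose(score_vol.values[coords], fs.scores)
        assert mask_vol.values.sum() == (fs.scores > 0.4).sum()

    def test_infinite_threshold_empty_mask(self, cingulum_features, grid20):
        _, mask_vol = discriminative_map(
            cingulum_features, grid20, PAIR, threshold=np.inf
        )
        assert mask_vol.values.sum() == 0
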