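"""Feature selection, the stage estimators, and the LOO harnesses."""

import numpy as np
import pandas as pd
import pytest

from hdwear.models import (
    SUBSCORE_SPECS,
    LassoSelector,
    ModelingError,
    Stage1Classifier,
    Stage2Regressor,
    TwoStageScorer,
    composite_strategies,
    loo_stage1,
    loo_stage2,
    two_stage_predict,
)


def _synthetic_regression(n=27, p=60, informative=(3, 17), noise=0.1, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = 3.0 * X[:, informative[0]] - 2.0 * X[:, informative[1]]
    y += noise * rng.standard_normal(n)
    return X, y


def _separable_cohort(n_per_class=14, p=50, shift=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((2 * n_per_class, p))
    X[:n_per_class, :5] += shift
    groups = np.array(["hd"] * n_per_class + ["control"] * n_per_class)
    idx = [f"hd_{i}" for i in range(n_per_class)] + [
        f"c_{i}" for i in range(n_per_class)
    ]
    return pd.DataFrame(X, index=idx), groups


class TestLassoSelector:
    def test_recovers_informative_features(self):
        X, y = _synthetic_regression()
        sel = LassoSelector(task="regress", random_state=0).fit(X, y)
        support = set(np.flatnonzero(sel.support_mask_))
        assert {3, 17} <= support

    def test_cap_of_one_keeps_single_feature(self):
        X, y = _synthetic_regression()
        sel = LassoSelector(task="regress", cap=1, random_state=0).fit(X, y)
        assert sel.n_selected_ == 1

    def test_312_columns_select_at_most_19(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((27, 312))
        y = X[:, :40] @ rng.standard_normal(40) + 0.1 * rng.standard_normal(27)
        sel = LassoSelector(task="regress", random_state=0).fit(X, y)
        assert 1 <= sel.n_selected_ <= 19

    def test_classification_selection_respects_cap(self):
        X, groups = _separable_cohort()
        sel = LassoSelector(task="classify", random_state=0).fit(X.values, groups)
        assert 1 <= sel.n_selected_ <= 19

    def test_constant_columns_never_selected(self):
        X, y = _synthetic_regression()
        X[:, 7] = 2.5
        sel = LassoSelector(task="regress", random_state=0).fit(X, y)
        assert not sel.support_mask_[7]


class TestLooStage1:
    def test_perfect_separation_all_families(self):
        X, groups = _separable_cohort()
        for family in ("lda", "svm", "knn"):
            results = loo_stage1(X, groups, family, random_state=0)
            correct = [r.prediction == g for r, g in zip(results, groups)]
            assert np.mean(correct) == 1.0, family

    def test_one_round_per_subject(self):
        X, groups = _separable_cohort(n_per_class=5)
        results = loo_stage1(X, groups, "lda", random_state=0)
        assert len(results) == len(X)
        assert [r.held_out_id for r in results] == list(X.index)

    def test_permuted_labels_give_chance_accuracy(self):
        """Null-distribution check: with labels shuffled, LOO accuracy stays
        within the chance band across repeated permutations."""
        X, groups = _separable_cohort()
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            perm = rng.permutation(groups)
            if len(np.unique(perm[:-1])) < 2:  # keep folds two-class
                continue
            results = loo_stage1(X, perm, "lda", random_state=seed)
            accs.append(np.mean([r.prediction == g for r, g in zip(results, perm)]))
        assert 0.25 <= float(np.median(accs)) <= 0.75

    def test_single_class_rejected(self):
        X, _ = _separable_cohort(n_per_class=4)
        with pytest.raises(ModelingError):
            loo_stage1(X, ["hd"] * len(X), "lda")

    def test_selection_cap_holds_every_round(self):
        X, groups = _separable_cohort()
        results = loo_stage1(X, groups, "lda", random_state=0)
        assert max(len(r.selected_features) for r in results) <= 19

    def test_no_leakage_probe(self):
        """Corrupting the held-out subject's features must not change what
        that round's training selects."""
        X, groups = _separable_cohort()
        clean = loo_stage1(X, groups, "lda", random_state=0)
        X_corrupt = X.copy()
        X_corrupt.iloc[3] = 1e6
        corrupt = loo_stage1(X_corrupt, groups, "lda", random_state=0)
        assert clean[3].selected_features == corrupt[3].selected_features

    def test_bitwise_determinism(self):
        X, groups = _separable_cohort()
        a = loo_stage1(X, groups, "lda", random_state=0)
        b = loo_stage1(X, groups, "lda", random_state=0)
        assert a == b


class TestLooStage2:
    def test_noiseless_linear_target_recovered(self):
        X, y = _synthetic_regression(n=14, p=40, noise=0.0)
        y = 10.0 + y  # keep scores positive
        spec = SUBSCORE_SPECS["total_chorea"]
        for family in ("gp", "svm"):
            results = loo_stage2(pd.DataFrame(X), y, spec, family, random_state=0)
            pred = np.array([float(r.prediction) for r in results])
            clipped = np.clip(y, 0, spec.range)
            assert np.mean(np.abs(pred - clipped)) < 0.05 * spec.range, family

    def test_constant_target_predicts_constant(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.standard_normal((8, 20)))
        results = loo_stage2(X, np.full(8, 3.0), SUBSCORE_SPECS["gait"], "gp")
        assert all(float(r.prediction) == 3.0 for r in results)

    def test_predictions_respect_score_range(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((10, 20)))
        y = rng.uniform(0, 4, size=10)
        results = loo_stage2(X, y, SUBSCORE_SPECS["gait"], "tree", random_state=0)
        preds = np.array([float(r.prediction) for r in results])
        assert (preds >= 0).all() and (preds <= 4).all()

    def test_too_few_subjects_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).standard_normal((4, 10)))
        with pytest.raises(ModelingError, match="5"):
            loo_stage2(X, np.arange(4.0), SUBSCORE_SPECS["gait"], "gp")


class TestTwoStage:
    def test_controls_scored_zero_when_stage1_is_perfect(self):
        X, groups = _separable_cohort(n_per_class=7)
        scores = {i: 10.0 for i, g in zip(X.index, groups) if g == "hd"}
        pred, s1, _ = two_stage_predict(
            X, groups, scores, SUBSCORE_SPECS["total_chorea"], random_state=0
        )
        assert all(r.prediction == g for r, g in zip(s1, groups))  # perfect stage 1
        for sid, g in zip(X.index, groups):
            if g == "control":
                assert pred[sid] == 0.0

    def test_constant_hd_scores_predicted_exactly(self):
        X, groups = _separable_cohort(n_per_class=7)
        scores = {i: 12.0 for i, g in zip(X.index, groups) if g == "hd"}
        pred, _, _ = two_stage_predict(
            X, groups, scores, SUBSCORE_SPECS["total_chorea"], random_state=0
        )
        for sid, g in zip(X.index, groups):
            if g == "hd":
                assert pred[sid] == pytest.approx(12.0)

    def test_misclassified_control_receives_stage2_prediction(self):
        # make one control look exactly like an HD subject
        X, groups = _separable_cohort(n_per_class=7, shift=6.0)
        X.loc["c_0"] = X.loc["hd_0"] + 0.01
        scores = {i: 15.0 for i, g in zip(X.index, groups) if g == "hd"}
        pred, s1, _ = two_stage_predict(
            X, groups, scores, SUBSCORE_SPECS["total_chorea"], random_state=0
        )
        cls = {r.held_out_id: r.prediction for r in s1}
        assert cls["c_0"] == "hd"  # the planted impostor is misclassified
        assert pred["c_0"] > 0.0  # and scored by the stage-2 model

    def test_output_covers_cohort(self):
        X, groups = _separable_cohort(n_per_class=6)
        scores = {i: 5.0 for i, g in zip(X.index, groups) if g == "hd"}
        pred, _, _ = two_stage_predict(
            X, groups, scores, SUBSCORE_SPECS["gait"], random_state=0
        )
        assert len(pred) == len(X)


class TestCompositeStrategies:
    def _cohort_scores(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        names = [n_ for n_ in SUBSCORE_SPECS if n_ != "composite"]
        scores = pd.DataFrame(
            {n_: rng.integers(0, 5, size=n).astype(float) for n_ in names},
            index=[f"hd_{i}" for i in range(n)],
        )
        # features linear in the subscores, light noise
        W = rng.standard_normal((len(names), 30))
        X = pd.DataFrame(
            scores.values @ W + 0.05 * rng.standard_normal((n, 30)),
            index=scores.index,
        )
        return X, scores

    def test_summed_is_sum_of_per_subscore_predictions(self):
        X, scores = self._cohort_scores()
        out = composite_strategies(X, scores, "svm", random_state=0)
        assert set(out.columns) == {"summed", "direct", "true_composite"}
        assert (out.true_composite == scores.sum(axis=1)).all()

    def test_additive_ground_truth_strategies_agree(self):
        X, scores = self._cohort_scores()
        out = composite_strategies(X, scores, "svm", random_state=0)
        close = np.abs(out.summed - out.direct) <= 0.1 * 60
        assert close.mean() >= 0.8

    def test_direct_beats_summed_under_subscore_noise(self):
        """Summing seven per-subscore predictions accumulates their errors,
        so with noisy subscore channels the direct composite model has the
        lower nMAE (median over seeds)."""
        from hdwear.evaluation import nmae

        names = [n for n in SUBSCORE_SPECS if n != "composite"]
        deltas = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            scores = pd.DataFrame(
                {n: rng.integers(0, 5, size=12).astype(float) for n in names},
                index=[f"hd_{i}" for i in range(12)],
            )
            composite = scores.sum(axis=1)
            # one clean composite channel; per-subscore channels are noisy
            per_sub = scores.values + 1.5 * rng.standard_normal(scores.shape)
            X = pd.DataFrame(
                np.column_stack([composite.values, per_sub,
                                 0.5 * rng.standard_normal((12, 10))]),
                index=scores.index,
            )
            out = composite_strategies(X, scores, "svm", random_state=seed)
            err_sum = nmae(out.summed, out.true_composite, 60)
            err_dir = nmae(out.direct, out.true_composite, 60)
            deltas.append(err_dir - err_sum)
        assert np.median(deltas) < 0


class TestEstimatorInterface:
    def test_get_set_params_round_trip(self):
        est = Stage2Regressor(family="tree", subscore_range=20)
        params = est.get_params()
        clone = Stage2Regressor(**params)
        assert clone.get_params() == params

    def test_two_stage_scorer_fit_predict(self):
        X, groups = _separable_cohort(n_per_class=7)
        y = np.where(groups == "hd", 10.0, 0.0)
        scorer = TwoStageScorer(subscore_range=60, random_state=0)
        scorer.fit(X.values, y, groups=groups)
        pred = scorer.predict(X.values)
        assert pred.shape == (len(X),)
        assert (pred >= 0).all() and (pred <= 60).all()

    def test_unknown_family_rejected_before_compute(self):
        X, groups = _separable_cohort(n_per_class=3)
        with pytest.raises(ModelingError, match="family"):
            Stage1Classifier(family="forest").fit(X.values, groups)
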