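"""Nested split plan, boosted feature selection, final ensemble, prediction."""

import numpy as np
import pandas as pd
import pytest

from amlsig.ensemble import (
    MissingFeatureError,
    NestedSplitPlan,
    SplitPlanMaterialized,
    density_mode,
    feature_selection_round,
    fit_final_ensemble,
    make_split_plan,
    predict,
    tune_hyperparameters,
)

CHEAP = {"max_depth": 2, "eta": 0.1, "num_boost_round": 20}


def _labeled_frame(n=32, n_feat=12, informative=1, sep=3.0, seed=0):
    rng = np.random.default_rng(seed)
    y = pd.Series(np.array([1, 0] * (n // 2)), index=[f"s{i:02d}" for i in range(n)])
    x = rng.normal(size=(n, n_feat))
    for k in range(informative):
        x[:, k] += sep * y.to_numpy()
    return pd.DataFrame(x, index=y.index, columns=[f"f{k}" for k in range(n_feat)]), y


class TestNestedSplitPlan:
    def test_default_plan_yields_2000_models(self):
        assert NestedSplitPlan().model_count == 2000

    def test_reduced_plan_arithmetic(self):
        assert NestedSplitPlan(n_outer=10, cv_folds=5, cv_repeats=1).model_count == 50

    def test_validation(self):
        with pytest.raises(ValueError):
            NestedSplitPlan(n_outer=0)
        with pytest.raises(ValueError):
            NestedSplitPlan(outer_test_fraction=1.0)
        with pytest.raises(ValueError):
            NestedSplitPlan(top_k_round1=5, top_k_round2=10)

    def test_json_round_trip(self):
        plan = NestedSplitPlan(n_outer=7, seed=3)
        assert NestedSplitPlan.from_json(plan.to_json()) == plan


class TestMakeSplitPlan:
    def test_partition_properties_at_cohort_size(self):
        _, y = _labeled_frame(n=32)
        plan = NestedSplitPlan(n_outer=20, outer_test_fraction=0.2, seed=1)
        splits = make_split_plan(y, plan)
        assert len(splits) == 20
        all_ids = set(y.index)
        for train, test in splits.pairs:
            assert len(test) in (6, 7)
            assert set(train) | set(test) == all_ids
            assert set(train) & set(test) == set()
            # stratification: both classes in every hold-out
            assert y[test].nunique() == 2

    def test_same_seed_reproduces_splits(self):
        _, y = _labeled_frame()
        plan = NestedSplitPlan(n_outer=5, seed=9)
        assert make_split_plan(y, plan).pairs == make_split_plan(y, plan).pairs

    def test_json_round_trip(self):
        _, y = _labeled_frame()
        splits = make_split_plan(y, NestedSplitPlan(n_outer=3, seed=0))
        assert SplitPlanMaterialized.from_json(splits.to_json()).pairs == [
            (list(tr), list(te)) for tr, te in splits.pairs
        ]

    def test_tiny_class_rejected(self):
        y = pd.Series([1] + [0] * 14, index=[f"s{i}" for i in range(15)])
        with pytest.raises(ValueError, match="stratification"):
            make_split_plan(y, NestedSplitPlan(n_outer=2))


class TestFeatureSelection:
    def test_perfect_separator_ranks_first(self):
        x, y = _labeled_frame(informative=1, sep=6.0, seed=2)
        splits = make_split_plan(y, NestedSplitPlan(n_outer=4, seed=2))
        gains = feature_selection_round(x, y, splits, reps=3, num_rounds=50, seed=2)
        assert gains.index[0] == "f0"
        assert gains.iloc[0] > 2 * gains.iloc[1]

    def test_label_permutation_removes_consistent_winner(self):
        x, y = _labeled_frame(informative=1, sep=6.0, seed=3)
        winners = []
        for rep in range(4):
            rng = np.random.default_rng(rep)
            y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            splits = make_split_plan(y_perm, NestedSplitPlan(n_outer=3, seed=rep))
            gains = feature_selection_round(
                x, y_perm, splits, reps=2, num_rounds=30, seed=rep
            )
            winners.append(gains.index[0])
        assert len(set(winners)) > 1  # no feature wins across independent shuffles


class TestTuneHyperparameters:
    def test_single_point_grid_returned(self):
        x, y = _labeled_frame(seed=4)
        tuned = tune_hyperparameters(
            x, y, grid={"max_depth": [3], "eta": [0.2]}, cv_folds=3, cv_repeats=1, seed=0
        )
        assert tuned["max_depth"] == 3 and tuned["eta"] == 0.2

    def test_stable_under_fixed_seed(self):
        x, y = _labeled_frame(informative=2, seed=5)
        grid = {"max_depth": [2, 4], "eta": [0.1, 0.3], "num_boost_round": [10]}
        t1 = tune_hyperparameters(x, y, grid=grid, cv_folds=3, cv_repeats=1, seed=6)
        t2 = tune_hyperparameters(x, y, grid=grid, cv_folds=3, cv_repeats=1, seed=6)
        assert t1 == t2

    def test_empty_grid_rejected(self):
        x, y = _labeled_frame()
        with pytest.raises(ValueError):
            tune_hyperparameters(x, y, grid={"max_depth": []})


class TestFinalEnsemble:
    def test_reduced_plan_model_count(self):
        x, y = _labeled_frame(informative=2, sep=3.0, seed=6)
        plan = NestedSplitPlan(n_outer=4, cv_folds=3, cv_repeats=2, seed=6)
        splits = make_split_plan(y, plan)
        ens = fit_final_ensemble(x, y, splits, CHEAP, plan)
        assert len(ens.models) == 4 * 3 * 2 == plan.model_count
        assert ens.selected_genes == list(x.columns)
        assert len(ens.training_metrics) == plan.model_count

    def test_strong_signal_training_recall_complete(self):
        x, y = _labeled_frame(informative=3, sep=5.0, seed=7)
        plan = NestedSplitPlan(n_outer=5, cv_folds=3, cv_repeats=2, seed=7)
        splits = make_split_plan(y, plan)
        ens = fit_final_ensemble(x, y, splits, CHEAP, plan)
        pred = predict(ens, x)
        recall = ((pred.calls == "responder") & (y == 1)).sum() / (y == 1).sum()
        assert recall == 1.0

    def test_mismatched_split_count_rejected(self):
        x, y = _labeled_frame()
        plan = NestedSplitPlan(n_outer=4, cv_folds=3, cv_repeats=1)
        splits = make_split_plan(y, NestedSplitPlan(n_outer=3))
        with pytest.raises(ValueError, match="split plan"):
            fit_final_ensemble(x, y, splits, CHEAP, plan)

    def test_save_load_round_trip(self, tmp_path):
        x, y = _labeled_frame(informative=1, seed=8)
        plan = NestedSplitPlan(n_outer=2, cv_folds=3, cv_repeats=1, seed=8)
        splits = make_split_plan(y, plan)
        ens = fit_final_ensemble(x, y, splits, CHEAP, plan)
        ens.save(tmp_path / "ens")
        back = type(ens).load(tmp_path / "ens")
        assert back.selected_genes == ens.selected_genes
        assert back.split_plan == plan
        np.testing.assert_allclose(
            predict(back, x).modes.to_numpy(), predict(ens, x).modes.to_numpy()
        )


class TestPrediction:
    def test_point_mass_mode_is_the_value(self):
        assert density_mode(np.full(2000, 0.8)) == pytest.approx(0.8)

    def test_bimodal_mode_tracks_majority_peak(self):
        probs = np.concatenate([np.full(1500, 0.1), np.full(500, 0.9)])
        mode = density_mode(probs)
        assert abs(mode - 0.1) < 0.05

    def test_boundary_mode_called_non_responder(self):
        x, y = _labeled_frame(informative=1, seed=9)
        plan = NestedSplitPlan(n_outer=2, cv_folds=3, cv_repeats=1, seed=9)
        splits = make_split_plan(y, plan)
        ens = fit_final_ensemble(x, y, splits, CHEAP, plan)
        pred = predict(ens, x)
        boundary = pred.modes <= 0.5
        assert (pred.calls[boundary] == "non-responder").all()

    def test_missing_signature_genes_rejected(self):
        x, y = _labeled_frame(informative=1, seed=10)
        plan = NestedSplitPlan(n_outer=2, cv_folds=3, cv_repeats=1, seed=10)
        splits = make_split_plan(y, plan)
        ens = fit_final_ensemble(x, y, splits, CHEAP, plan)
        with pytest.raises(MissingFeatureError, match="f0"):
            predict(ens, x.drop(columns=["f0"]))
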