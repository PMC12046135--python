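"""Brain-age CV prediction, linear bias correction, metrics, TreeSHAP."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bagpa import brainage
from bagpa.synthgen import GenerativeConfig, generate_cohort


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(GenerativeConfig(n_participants=2000, n_noise_idps=30, seed=17))


@pytest.fixture(scope="module")
def cv_result(cohort):
    return brainage.fit_cv_predict(
        cohort.table, cohort.truth.informative_idp_ids, folds=5, seed=3
    )


class TestBiasCorrection:
    def test_perfect_prediction_needs_no_correction(self):
        x = np.linspace(40, 80, 120)
        folds = np.tile(np.arange(3), 40)
        corrected, fc = brainage.bias_correct(x, x, folds)
        for a, b, _ in fc:
            assert a == pytest.approx(0.0, abs=1e-10)
            assert b == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(corrected, x, atol=1e-9)

    def test_known_linear_bias_recovered_exactly(self):
        # y = 0.5 x + 20  =>  a = -0.5, b = 20, corrected = x, BAG = 0
        x = np.linspace(40, 80, 200)
        y = 0.5 * x + 20
        folds = np.repeat(np.arange(4), 50)
        corrected, fc = brainage.bias_correct(y, x, folds)
        for a, b, _ in fc:
            assert a == pytest.approx(-0.5, abs=1e-8)
            assert b == pytest.approx(20.0, abs=1e-8)
        np.testing.assert_allclose(corrected - x, 0.0, atol=1e-8)

    def test_correction_is_idempotent(self, cv_result):
        corrected, _ = brainage.bias_correct(cv_result.predictions, cv_result.ages, cv_result.fold_id)
        _, fc2 = brainage.bias_correct(corrected, cv_result.ages, cv_result.fold_id)
        for a, b, _ in fc2:
            assert abs(a) < 0.02
            assert abs(b) < 0.5

    def test_test_fold_mode_and_none_mode(self):
        x = np.linspace(40, 80, 90)
        y = 0.8 * x + 5
        folds = np.repeat(np.arange(3), 30)
        corrected, _ = brainage.bias_correct(y, x, folds, mode="test_fold")
        np.testing.assert_allclose(corrected, x, atol=1e-8)
        untouched, fc = brainage.bias_correct(y, x, folds, mode="none")
        np.testing.assert_array_equal(untouched, y)
        assert all(a == 0 and b == 0 for a, b, _ in fc)

    def test_zero_age_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            brainage.bias_correct(np.ones(20), np.full(20, 60.0), np.repeat([0, 1], 10))


class TestFitCVPredict:
    def test_constant_target_predicted_exactly(self, cohort):
        t = cohort.table.head(300).copy()
        t["const_age"] = 55.0
        cv = brainage.fit_cv_predict(t, cohort.truth.informative_idp_ids[:5], target="const_age", folds=3)
        np.testing.assert_allclose(cv.predictions, 55.0, atol=1e-9)

    def test_every_participant_predicted_out_of_fold_once(self, cv_result):
        assert len(cv_result.predictions) == 2000
        counts = np.bincount(cv_result.fold_id)
        assert counts.sum() == 2000 and len(counts) == 5

    def test_fold_assignment_stable_under_seed(self, cohort):
        a = brainage.fit_cv_predict(cohort.table.head(400), cohort.truth.informative_idp_ids[:4], folds=4, seed=9)
        b = brainage.fit_cv_predict(cohort.table.head(400), cohort.truth.informative_idp_ids[:4], folds=4, seed=9)
        np.testing.assert_array_equal(a.fold_id, b.fold_id)
        np.testing.assert_array_equal(a.predictions, b.predictions)

    def test_nonfinite_features_named(self, cohort):
        t = cohort.table.head(100).copy()
        t.loc[3, "idp_info_000"] = np.nan
        with pytest.raises(ValueError, match="idp_info_000"):
            brainage.fit_cv_predict(t, ["idp_info_000", "idp_info_001"], folds=3)

    def test_shuffled_target_has_no_skill(self, cohort, rng):
        t = cohort.table.head(1000).copy()
        t["age"] = rng.permutation(t["age"].to_numpy())
        cv = brainage.fit_cv_predict(t, cohort.truth.informative_idp_ids, folds=5, seed=1)
        m = brainage.compute_metrics(cv.predictions, cv.ages, bootstrap_reps=10)
        assert m["r2"][0] <= 0.05

    def test_hyperparameter_search_runs_and_is_deterministic(self, cohort):
        t = cohort.table.head(500)
        feats = cohort.truth.informative_idp_ids[:6]
        a = brainage.fit_cv_predict(t, feats, folds=3, hp_budget=3, seed=2)
        b = brainage.fit_cv_predict(t, feats, folds=3, hp_budget=3, seed=2)
        np.testing.assert_array_equal(a.predictions, b.predictions)


class TestMetrics:
    def test_perfect_fit_degenerate(self):
        x = np.linspace(40, 80, 50)
        m = brainage.compute_metrics(x, x, bootstrap_reps=100)
        assert m["mae"] == (0.0, 0.0, 0.0)
        assert m["rmse"] == (0.0, 0.0, 0.0)
        assert m["r2"][0] == pytest.approx(1.0)

    def test_alternating_unit_errors(self):
        x = np.linspace(40, 80, 100)
        preds = x + np.where(np.arange(100) % 2 == 0, 1.0, -1.0)
        m = brainage.compute_metrics(preds, x, bootstrap_reps=50)
        assert m["mae"][0] == pytest.approx(1.0)
        assert m["rmse"][0] == pytest.approx(1.0)

    def test_r2_identity_with_rmse_and_variance(self, cv_result):
        m = brainage.compute_metrics(cv_result.predictions, cv_result.ages, bootstrap_reps=10)
        var = np.mean((cv_result.ages - cv_result.ages.mean()) ** 2)
        assert m["r2"][0] == pytest.approx(1 - m["rmse"][0] ** 2 / var, abs=1e-10)
        assert m["mae"][0] <= m["rmse"][0]

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            brainage.compute_metrics(np.array([1.0]), np.array([1.0]))


class TestShap:
    def test_local_accuracy_and_dummy_feature(self, cohort):
        t = cohort.table.head(600).copy()
        t["idp_dummy"] = 1.0
        feats = cohort.truth.informative_idp_ids[:5] + ["idp_dummy"]
        cv = brainage.fit_cv_predict(t, feats, folds=3, seed=4)
        expl = brainage.explain_shap(cv.models, t, feats, fold_assignment=cv.fold_id)
        recon = expl.base_values + expl.values.sum(axis=1)
        np.testing.assert_allclose(recon, cv.predictions, atol=1e-6)
        dummy_idx = feats.index("idp_dummy")
        np.testing.assert_allclose(expl.values[:, dummy_idx], 0.0, atol=1e-12)

    def test_global_ranking_tracks_permutation_ranking(self):
        """When one feature is planted clearly strongest, SHAP and
        permutation importance agree on it in most seeded runs."""
        from bagpa import featsel

        feats = ["idp_strong"] + [f"idp_weak_{j}" for j in range(4)]
        agree = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            age = rng.uniform(45, 80, 800)
            z = (age - age.mean()) / age.std()
            t = pd.DataFrame({"age": age, "idp_strong": z + rng.normal(0, 0.3, 800)})
            for j in range(4):
                t[f"idp_weak_{j}"] = z + rng.normal(0, 2.0, 800)
            cv = brainage.fit_cv_predict(t, feats, folds=3, seed=seed)
            expl = brainage.explain_shap(cv.models, t, feats, fold_assignment=cv.fold_id)
            perm = featsel.permutation_rerank(t, feats, cv_folds=3, n_repeats=3, seed=seed)
            agree += (expl.global_ranking.index[0] == "idp_strong" == perm.index[0])
        assert agree >= 4

    def test_non_tree_model_rejected(self, cohort):
        from sklearn.linear_model import LinearRegression

        with pytest.raises(TypeError):
            brainage.explain_shap([LinearRegression()], cohort.table.head(10),
                                  cohort.truth.informative_idp_ids[:2])


class TestExternalValidation:
    def test_id_overlap_rejected(self, cohort):
        with pytest.raises(ValueError, match="overlap"):
            brainage.external_validate(cohort.table, cohort.table,
                                       cohort.truth.informative_idp_ids)

    def test_iid_test_mae_close_to_cv_mae(self):
        cfg = GenerativeConfig(n_participants=3000, n_noise_idps=10, seed=23)
        coh = generate_cohort(cfg)
        feats = coh.truth.informative_idp_ids
        train = coh.table.iloc[:2000].reset_index(drop=True)
        test = coh.table.iloc[2000:].reset_index(drop=True)
        res = brainage.external_validate(train, test, feats, folds=5, bootstrap_reps=50, seed=5)
        cv = brainage.fit_cv_predict(train, feats, folds=5, seed=5)
        corrected, _ = brainage.bias_correct(cv.predictions, cv.ages, cv.fold_id)
        cv_mae = np.mean(np.abs(corrected - cv.ages))
        assert abs(res["metrics"]["mae"][0] - cv_mae) / cv_mae < 0.15


def test_pipeline_orthogonality_and_mae_ceiling(cohort):
    res = brainage.brain_age_pipeline(
        cohort.table, cohort.truth.informative_idp_ids, folds=5, bootstrap_reps=100, seed=6
    )
    assert res.spearman_bag_age_before < -0.2
    assert abs(res.spearman_bag_age_after) < 0.05
    np.testing.assert_allclose(res.bag, res.corrected_age - cohort.table["age"], atol=1e-12)
    assert res.metrics["mae"][0] <= res.metrics["rmse"][0]
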