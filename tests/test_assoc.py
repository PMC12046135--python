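"""GAM dose-response, quartile contrasts, IDP scans and FDR control."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bagpa import assoc, pa, synthgen
from bagpa._mgcv import fit_gam_mgcv


@pytest.fixture(scope="module")
def ushape_table():
    cfg = synthgen.GenerativeConfig(n_participants=4000, seed=51)
    coh = synthgen.generate_cohort(cfg)
    t = coh.table.copy()
    t["bag"] = coh.truth.true_bag
    return t, coh


class TestFitGam:
    def test_linear_effect_recovers_edf_near_one_and_ols_slope(self, rng):
        n = 2000
        x = rng.lognormal(2.0, 0.4, n)
        y = -0.3 * x + rng.normal(0, 1, n)
        d = pd.DataFrame({"x": x, "y": y})
        fit = assoc.fit_gam(d, "x", "y", k_grid=(10,), seed=1)
        assert 0.9 <= fit.edf <= 1.5
        # penalized smooth collapses to the OLS line
        ols_slope = np.polyfit(x, y, 1)[0]
        c = fit.fitted_curve
        gam_slope = np.polyfit(c["x"], c["fit"], 1)[0]
        assert gam_slope == pytest.approx(ols_slope, abs=1e-3)
        assert fit.p_value < 0.05

    def test_planted_ushape_recovered(self, ushape_table):
        t, coh = ushape_table
        fit = assoc.fit_gam(t, "mvpa_h_wk", "bag",
                            covariates=["age", "sex", "education", "townsend"], seed=2)
        assert fit.edf > 2
        assert fit.p_value < 0.05
        truth = synthgen.planted_pa_optimum(coh.config)
        assert abs(fit.argmin - truth) / truth < 0.15

    def test_edf_bounds_and_curve_ci_bracket(self, ushape_table):
        t, _ = ushape_table
        fit = assoc.fit_gam(t.head(1500), "lpa_h_wk", "bag", k_grid=(8,), seed=3)
        assert 1.0 <= fit.edf <= fit.k - 1
        c = fit.fitted_curve
        assert (c["lo"] <= c["fit"]).all() and (c["fit"] <= c["hi"]).all()

    def test_aliased_covariates_named(self, ushape_table):
        t, _ = ushape_table
        t2 = t.head(200).copy()
        t2["age_copy"] = t2["age"]
        with pytest.raises(ValueError, match="age_copy"):
            assoc.fit_gam(t2, "mvpa_h_wk", "bag", covariates=["age", "age_copy"])

    def test_null_smooth_pvalues_calibrated(self):
        """Under independence the smooth-term test keeps its nominal 5% size.

        The approximate test for a penalized smooth is known to be only
        roughly uniform away from the tail, so mid-scale uniformity is
        checked coarsely (KS statistic) while the operating tail — what
        significance calls and FDR consume — is held to the nominal band.
        """
        frames = []
        for s in range(200):
            r = np.random.default_rng(s)
            frames.append(pd.DataFrame({"x": r.normal(0, 1, 300), "y": r.normal(0, 1, 300)}))
        res = fit_gam_mgcv(frames, "x", "y", k_grid=(10,), curve=False, seed=0)
        p = np.array([r["p_value"] for r in res])
        assert 0.025 <= (p < 0.05).mean() <= 0.075
        assert stats.kstest(p, "uniform").statistic < 0.15
        assert p.min() > 0 and p.max() < 1


class TestQuartileModel:
    def test_monotone_negative_dose_response_detected(self):
        cfg = synthgen.GenerativeConfig(
            n_participants=4000,
            seed=53,
            u_shape={"pa_optimum": 8.2, "curvature": 0.0},
            mediation={"alpha_pa_to_bag": -0.10, "beta_bag_to_outcome": 0.3,
                       "direct_pa_to_outcome": -0.5},
        )
        coh = synthgen.generate_cohort(cfg)
        t = coh.table.copy()
        t["bag"] = coh.truth.true_bag
        q = pa.assign_quartiles(t["mvpa_h_wk"].to_numpy())
        fit = assoc.fit_quartile_model(t, q, "bag", covariates=["age", "sex"])
        assert fit.betas.loc["Q4", "beta"] < 0
        assert fit.betas.loc["Q4", "hi"] < 0  # CI excludes 0
        assert fit.smd < 0 and fit.wilcoxon_p < 0.05

    def test_reference_quartile_beta_zero_and_ci_contains_point(self, ushape_table):
        t, _ = ushape_table
        q = pa.assign_quartiles(t["mpa_h_wk"].to_numpy())
        fit = assoc.fit_quartile_model(t, q, "bag", covariates=["age"])
        assert fit.betas.loc["Q1", "beta"] == 0.0
        for lev in ("Q2", "Q3", "Q4"):
            assert fit.betas.loc[lev, "lo"] <= fit.betas.loc[lev, "beta"] <= fit.betas.loc[lev, "hi"]

    def test_betas_equal_group_mean_differences_without_covariates(self, ushape_table):
        t, _ = ushape_table
        q = pa.assign_quartiles(t["mvpa_h_wk"].to_numpy())
        fit = assoc.fit_quartile_model(t, q, "bag", covariates=[])
        bag = t["bag"].to_numpy()
        ref = bag[q == "Q1"].mean()
        for lev in ("Q2", "Q3", "Q4"):
            diff = bag[q == lev].mean() - ref
            assert fit.betas.loc[lev, "beta"] == pytest.approx(diff, abs=1e-6)

    def test_smd_of_identical_groups_is_zero(self):
        t = pd.DataFrame({"bag": np.tile(np.arange(40, dtype=float), 4)})
        q = np.repeat(["Q1", "Q2", "Q3", "Q4"], 40)
        fit = assoc.fit_quartile_model(t, q, "bag", covariates=[])
        assert fit.smd == pytest.approx(0.0, abs=1e-12)

    def test_empty_quartile_errors(self, ushape_table):
        t, _ = ushape_table
        q = np.repeat(["Q1", "Q2", "Q3"], len(t) // 3 + 1)[: len(t)]
        with pytest.raises(ValueError, match="Q4"):
            assoc.fit_quartile_model(t, q, "bag")


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        assert assoc.fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_bh_step_up_arithmetic(self):
        np.testing.assert_allclose(assoc.fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(assoc.fdr_adjust(np.ones(10)), 1.0)

    def test_q_at_least_p_and_monotone(self, rng):
        p = rng.uniform(size=50)
        q = assoc.fdr_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            assoc.fdr_adjust([0.5, 1.2])


class TestScan:
    def test_self_regression_beta_one(self, ushape_table):
        t, _ = ushape_table
        t2 = t.head(500).copy()
        t2["idp_self"] = t2["mvpa_h_wk"]
        out = assoc.scan_idp_associations(t2, ["mvpa_h_wk"], ["idp_self"], covariates=[])
        assert out["beta"].iloc[0] == pytest.approx(1.0)

    def test_matches_statsmodels_ols(self, ushape_table):
        import statsmodels.api as sm
        from bagpa._design import covariate_matrix

        t, _ = ushape_table
        t2 = t.head(800)
        covs = ["age", "sex"]
        idps = ["idp_info_000", "idp_info_001", "idp_noise_000"]
        out = assoc.scan_idp_associations(t2, ["mpa_h_wk"], idps, covariates=covs)
        C = covariate_matrix(t2, covs)
        xz = (t2["mpa_h_wk"] - t2["mpa_h_wk"].mean()) / t2["mpa_h_wk"].std(ddof=1)
        for _, row in out.iterrows():
            yz = (t2[row["idp"]] - t2[row["idp"]].mean()) / t2[row["idp"]].std(ddof=1)
            X = pd.concat([xz.rename("x"), C], axis=1)
            fit = sm.OLS(yz.to_numpy(), X.astype(float)).fit()
            assert row["beta"] == pytest.approx(fit.params["x"], abs=1e-10)
            assert row["p"] == pytest.approx(fit.pvalues["x"], abs=1e-10)

    def test_planted_negative_effect_recovered(self, rng):
        n = 3000
        x = rng.lognormal(2, 0.4, n)
        d = pd.DataFrame({"pa": x})
        for j in range(30):
            d[f"idp_null_{j}"] = rng.normal(size=n)
        d["idp_hit"] = -0.2 * (x - x.mean()) / x.std() + rng.normal(0, 1, n)
        out = assoc.scan_idp_associations(d, ["pa"], [c for c in d if c.startswith("idp")])
        hit = out[out["idp"] == "idp_hit"].iloc[0]
        assert hit["beta"] < 0 and hit["q"] < 0.05

    def test_constant_idp_skipped_with_warning(self, ushape_table):
        t, _ = ushape_table
        t2 = t.head(300).copy()
        t2["idp_const"] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            out = assoc.scan_idp_associations(t2, ["mvpa_h_wk"], ["idp_const", "idp_info_000"])
        assert list(out["idp"]) == ["idp_info_000"]

    def test_gam_columns_present_when_requested(self, ushape_table):
        t, _ = ushape_table
        out = assoc.scan_idp_associations(
            t.head(800), ["mvpa_h_wk"], ["idp_info_000", "idp_info_001"],
            covariates=["age"], include_gam=True, k_grid=(6,),
        )
        assert {"edf", "f_stat", "p_gam", "q_gam"} <= set(out.columns)
        assert out["edf"].notna().all()
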