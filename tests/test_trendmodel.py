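"""Model frame assembly, the mixed model, AICc, stepwise selection, Wald
tests, and pseudo-R2."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fastslow.synthdata import SimConfig, simulate_model_frame
from fastslow.trendmodel import (
    COVER_COLS, FitResult, ModelSpec, aicc, assemble_model_frame,
    build_full_spec, fit_lmm, pseudo_r2, stepwise_aicc, wald_single,
    wald_type3,
)
from tests.conftest import truth_frame


def small_frame(seed=0, n=200, beta=None, **kw):
    cfg = SimConfig(n_species=25, n_populations=n, n_sites=30, seed=seed,
                    **({"beta": beta} if beta is not None else {}), **kw)
    frame, truth = simulate_model_frame(cfg, lambda_noise_sd=0.01)
    return frame, truth


class TestAssemble:
    def _parts(self):
        lam = pd.DataFrame({"population_id": ["p1", "p2"],
                            "species": ["A a", "B b"],
                            "location_id": ["s1", "s2"],
                            "mean_lambda": [0.01, -0.02]})
        env = pd.DataFrame({"population_id": ["p1", "p2"],
                            "delta_t": [0.02, 0.03],
                            **{c: [0.001, -0.001] for c in COVER_COLS}})
        scores = pd.DataFrame({"species": ["A a", "B b"],
                               "pc1": [1.0, -1.0]})
        return lam, env, scores

    def test_complete_overlap_preserves_rows(self):
        lam, env, scores = self._parts()
        frame, drops = assemble_model_frame(lam, env, scores)
        assert len(frame) == 2 and drops.empty

    def test_missing_score_dropped_and_reported(self):
        lam, env, scores = self._parts()
        frame, drops = assemble_model_frame(lam, env, scores.iloc[:1])
        assert len(frame) == 1
        assert drops["reason"].str.contains("pc1").all()

    def test_disjoint_keys_empty_frame_full_report(self):
        lam, env, scores = self._parts()
        env["population_id"] = ["x1", "x2"]
        frame, drops = assemble_model_frame(lam, env, scores)
        assert frame.empty and len(drops) == 2

    def test_duplicate_population_rejected(self):
        lam, env, scores = self._parts()
        lam2 = pd.concat([lam, lam.iloc[:1]])
        with pytest.raises(ValueError, match="duplicate"):
            assemble_model_frame(lam2, env, scores)


class TestSpec:
    def test_full_spec_counts(self):
        assert len(build_full_spec().fixed_terms) == 35  # N=8
        assert len(build_full_spec(cover_cols=["lc_cropland"]).fixed_terms) == 7

    def test_marginality_enforced(self):
        with pytest.raises(ValueError, match="marginality"):
            ModelSpec(("delta_t", "delta_t:pc1"))

    def test_droppable_excludes_interaction_parents(self):
        spec = ModelSpec(("delta_t", "pc1", "delta_t:pc1"))
        assert spec.droppable() == ["delta_t:pc1"]

    def test_full_spec_marginality_holds(self):
        spec = build_full_spec()
        for t in spec.fixed_terms:
            spec.without  # construction itself verifies marginality
        # dropping a main effect under its interactions is rejected
        with pytest.raises(ValueError, match="marginality"):
            spec.without("pc1")


class TestFitLMM:
    # generate from the same structure we fit, so the random effects have
    # nothing systematic to absorb
    BETA3 = {"Intercept": 0.002, "delta_t": 0.3, "pc1": 0.01,
             "lc_cropland": -5.0}

    def test_zero_variance_components_match_ols(self):
        frame, _ = small_frame(seed=1, beta=self.BETA3,
                               sigma_species=0.0, sigma_site=0.0)
        spec = ModelSpec(("delta_t", "pc1", "lc_cropland"))
        fit = fit_lmm(frame, spec, "reml")
        assert fit.vcomp["species"] < 1e-5 and fit.vcomp["location_id"] < 1e-5
        import statsmodels.api as sm
        X = sm.add_constant(frame[["delta_t", "pc1", "lc_cropland"]])
        ols = sm.OLS(frame["mean_lambda"], X).fit()
        # near-zero variance components: GLS collapses to OLS
        assert np.allclose(fit.params.to_numpy()[1:],
                           ols.params.to_numpy()[1:], rtol=2e-3, atol=1e-5)

    def test_duplicated_frame_shrinks_se_not_estimates(self):
        frame, _ = small_frame(seed=2, beta=self.BETA3,
                               sigma_species=0.0, sigma_site=0.0)
        spec = ModelSpec(("delta_t", "pc1", "lc_cropland"))
        fit1 = fit_lmm(frame, spec, "reml")
        dup = pd.concat([frame, frame], ignore_index=True)
        dup["population_id"] = np.arange(len(dup)).astype(str)
        fit2 = fit_lmm(dup, spec, "reml")
        assert np.allclose(fit1.params["pc1"], fit2.params["pc1"], atol=5e-4)
        assert fit2.se["pc1"] < fit1.se["pc1"]

    def test_closed_cover_block_aliased_deterministically(self):
        frame, _ = small_frame(seed=3)
        fit = fit_lmm(frame, build_full_spec(), "reml")
        # closure makes each cover block rank-deficient by one; the last
        # class in spec order is the aliased one
        assert "lc_water" in fit.aliased
        assert "delta_t:pc1:lc_water" in fit.aliased

    def test_single_level_random_factor_rejected(self):
        frame, _ = small_frame(seed=4)
        frame["location_id"] = "one"
        with pytest.raises(ValueError, match="levels"):
            fit_lmm(frame, ModelSpec(("pc1",)), "reml")


class TestAicc:
    def test_hand_arithmetic_correction(self):
        # k=3, n=10: correction = 2*3*4/6 = 4
        assert aicc(-5.0, n=10, k=3) == pytest.approx(10 + 6 + 4)

    def test_limit_to_aic(self):
        a = aicc(-100.0, n=10 ** 9, k=5)
        assert a == pytest.approx(200 + 10, abs=1e-3)

    def test_decreases_with_n_at_fixed_k(self):
        vals = [aicc(-50.0, n=n, k=4) for n in (20, 50, 200)]
        assert vals == sorted(vals, reverse=True)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            aicc(-5.0, n=4, k=3)

    def test_k_counts_fixed_and_variance_components(self):
        frame, _ = small_frame(seed=5)
        fit = fit_lmm(frame, ModelSpec(("pc1",)), "reml")
        assert fit.k == 2 + 3  # intercept+pc1, two vc + residual


class TestWald:
    def test_single_coefficient_equals_squared_z(self):
        chi2, p = wald_single(-1.4974, 0.6943)
        assert chi2 == pytest.approx((1.4974 / 0.6943) ** 2)
        assert p == pytest.approx(stats.chi2.sf(chi2, 1))

    def test_type3_matches_params_and_se(self):
        frame, _ = small_frame(seed=6)
        fit = fit_lmm(frame, ModelSpec(("delta_t", "pc1")), "reml")
        w = wald_type3(fit).set_index("term")
        for t in ("delta_t", "pc1"):
            expect = (fit.params[t] / fit.se[t]) ** 2
            assert w.loc[t, "chi2"] == pytest.approx(expect, rel=1e-9)
            assert w.loc[t, "df"] == 1


class TestPseudoR2:
    def test_conditional_at_least_marginal(self):
        frame, _ = small_frame(seed=7)
        fit = fit_lmm(frame, ModelSpec(("pc1", "lc_cropland")), "reml")
        marg, cond = pseudo_r2(fit)
        assert 0 <= marg <= cond <= 1

    def test_known_variance_decomposition_recovered(self):
        """With a strong single fixed effect and known sigmas, the marginal
        fraction matches var(beta*x)/(var(beta*x)+sig_sp^2+sig_site^2+sig^2)."""
        beta = {"Intercept": 0.0, "pc1": 0.05}
        cfg = SimConfig(n_species=60, n_populations=800, n_sites=60, seed=8,
                        beta=beta, sigma_species=0.02, sigma_site=0.02)
        frame, truth = simulate_model_frame(cfg, lambda_noise_sd=0.03)
        fit = fit_lmm(frame, ModelSpec(("pc1",)), "reml")
        marg, cond = pseudo_r2(fit)
        var_f = np.var(0.05 * frame["pc1"].to_numpy())
        expect_m = var_f / (var_f + 0.02 ** 2 + 0.02 ** 2 + 0.03 ** 2)
        expect_c = (var_f + 0.02 ** 2 + 0.02 ** 2) / (
            var_f + 0.02 ** 2 + 0.02 ** 2 + 0.03 ** 2)
        assert marg == pytest.approx(expect_m, abs=0.07)
        assert cond == pytest.approx(expect_c, abs=0.07)


class TestStepwise:
    def test_planted_interaction_retained(self):
        beta = {"Intercept": 0.002, "pc1": 0.006, "lc_cropland": -2.0,
                "pc1:lc_cropland": 10.0}
        frame, _ = small_frame(seed=9, n=250, beta=beta)
        full = build_full_spec(cover_cols=["lc_cropland", "lc_bare_soil"])
        spec, fit, path = stepwise_aicc(frame, full)
        for t in ("pc1", "lc_cropland", "pc1:lc_cropland"):
            assert t in spec.fixed_terms

    def test_final_spec_subset_and_marginal(self):
        frame, _ = small_frame(seed=10, n=200)
        full = build_full_spec(cover_cols=["lc_cropland", "lc_bare_soil"])
        spec, fit, path = stepwise_aicc(frame, full)
        assert set(spec.fixed_terms) <= set(full.fixed_terms)
        ModelSpec(spec.fixed_terms)  # marginality re-validated
        assert fit.method == "reml"
        # path AICc values are non-increasing over ML drop steps
        ml_steps = [p["aicc"] for p in path if p["action"] in ("start", "drop")]
        assert all(b <= a + 1e-9 for a, b in zip(ml_steps, ml_steps[1:]))

    def test_noise_prunes_most_terms(self):
        frame, _ = small_frame(seed=11, n=250, beta={"Intercept": 0.0})
        full = build_full_spec(cover_cols=["lc_cropland", "lc_bare_soil"])
        spec, _, _ = stepwise_aicc(frame, full)
        assert len(spec.fixed_terms) < len(full.fixed_terms)
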