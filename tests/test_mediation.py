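"""Two-way mediation decomposition, delta-method CIs and the MC oracle."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from drmediate.mediation import (
    MediationModel,
    MediatorModel,
    OutcomeModel,
    delta_method_ci,
    fit_mediation_models,
    mc_counterfactual_oracle,
    proportion_mediated,
    two_way_decompose,
)
from drmediate.synthetic import GenerationConfig, generate_cohort, true_effects


def _toy_models(alpha0=2.0, alpha1=0.5, sigma=1.0, t0=0.0, t1=1.0, t2=2.0, t3=0.1,
                m_var=None, y_var=None):
    """Hand-built mediator/outcome models with no covariates."""
    mcols = ["const", "exposure_score"]
    ycols = ["const", "exposure_score", "mediator_score", "exposure_x_mediator"]
    mcov = pd.DataFrame(np.zeros((2, 2)) if m_var is None else m_var,
                        index=mcols, columns=mcols)
    ycov = pd.DataFrame(np.zeros((4, 4)) if y_var is None else y_var,
                        index=ycols, columns=ycols)
    mm = MediatorModel(alpha0=alpha0, alpha1=alpha1,
                       alpha2=pd.Series(dtype=float), sigma_m=sigma, cov=mcov)
    om = OutcomeModel(theta0=t0, theta1=t1, theta2=t2, theta3=t3,
                      theta4=pd.Series(dtype=float), cov=ycov)
    return mm, om


_EMPTY_CBAR = pd.Series(dtype=float)


class TestTwoWayDecompose:
    def test_hand_worked_example(self):
        mm, om = _toy_models()
        res = two_way_decompose(mm, om, 0.0, 1.0, _EMPTY_CBAR)
        # E[M|a0=0] = 2 -> pde = (1 + 0.1*2)*1 = 1.2; tie = (2 + 0.1*1)*0.5 = 1.05
        assert res.pde == pytest.approx(1.2)
        assert res.tie == pytest.approx(1.05)
        assert res.te == pytest.approx(2.25)
        assert res.pm == pytest.approx(1.05 / 2.25)

    def test_no_interaction_is_product_of_coefficients(self):
        mm, om = _toy_models(t3=0.0)
        res = two_way_decompose(mm, om, 1.0, 3.0, _EMPTY_CBAR)
        assert res.tie == pytest.approx(om.theta2 * mm.alpha1 * 2.0)
        assert res.pde == pytest.approx(om.theta1 * 2.0)  # exact with theta3 = 0

    def test_zero_mediator_path(self):
        mm, om = _toy_models(alpha1=0.0)
        res = two_way_decompose(mm, om, 0.0, 1.0, _EMPTY_CBAR)
        assert res.tie == 0.0
        assert res.pm == 0.0

    def test_equal_exposure_levels_rejected(self):
        mm, om = _toy_models()
        with pytest.raises(ValueError, match="must differ"):
            two_way_decompose(mm, om, 1.0, 1.0, _EMPTY_CBAR)

    def test_opposite_signs_flagged(self):
        mm, om = _toy_models(t1=1.0, t2=-3.0, t3=0.0, alpha1=0.2)
        res = two_way_decompose(mm, om, 0.0, 1.0, _EMPTY_CBAR)
        assert res.pm_flag is not None

    @settings(max_examples=60, derandomize=True)
    @given(st.floats(-2, 2), st.floats(-2, 2), st.floats(-1, 1), st.floats(-1, 1),
           st.floats(-2, 2), st.floats(0.25, 3))
    def test_identity_holds_to_machine_precision(self, t1, t2, t3, a1c, a0, delta):
        mm, om = _toy_models(alpha1=a1c, t1=t1, t2=t2, t3=t3)
        res = two_way_decompose(mm, om, a0, a0 + delta, _EMPTY_CBAR)
        assert res.te == pytest.approx(res.pde + res.tie, abs=1e-12)

    def test_recentering_covariates_is_invariant(self, latent_cohort):
        t = latent_cohort.iloc[:4000].copy()
        res1 = MediationModel(t, "smfq_w3", a0=3.0, a1=5.0).fit().result
        shifted = t.copy()
        shifted["iq"] = shifted["iq"] - 100.0  # recenter; cbar recomputed in fit
        res2 = MediationModel(shifted, "smfq_w3", a0=3.0, a1=5.0).fit().result
        assert res2.te == pytest.approx(res1.te, rel=1e-8)
        assert res2.pde == pytest.approx(res1.pde, rel=1e-8)
        assert res2.tie == pytest.approx(res1.tie, rel=1e-8)


class TestFitMediationModels:
    def test_generator_coefficients_recovered(self, latent_config, latent_cohort):
        mm, om = fit_mediation_models(latent_cohort, "smfq_w3")
        cfg = latent_config
        assert abs(mm.alpha1 - cfg.alpha1) < 3 * np.sqrt(mm.cov.loc["exposure_score", "exposure_score"])
        for attr, name in (("theta1", "exposure_score"), ("theta2", "mediator_score"),
                           ("theta3", "exposure_x_mediator")):
            se = np.sqrt(om.cov.loc[name, name])
            assert abs(getattr(om, attr) - getattr(cfg, attr)["smfq"]) < 3 * se, attr

    def test_zero_interaction_recovered(self):
        cfg = GenerationConfig(n_subjects=20000, seed=37, discretize=False)
        cfg.theta3 = {o: 0.0 for o in cfg.theta3}
        t = generate_cohort(cfg)
        _, om = fit_mediation_models(t, "anxiety_w3")
        se = np.sqrt(om.cov.loc["exposure_x_mediator", "exposure_x_mediator"])
        assert abs(om.theta3) < 3 * se

    def test_duplicated_mediator_covariate_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="collinear"):
            fit_mediation_models(small_cohort, "smfq_w3",
                                 covariates=["age", "mediator_score"])

    def test_missing_cells_rejected(self, small_cohort):
        t = small_cohort.copy()
        t.loc[5, "iq"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_mediation_models(t, "smfq_w3")


class TestDeltaMethod:
    def test_zero_coefficient_variance_gives_point_cis(self):
        mm, om = _toy_models()
        ses, cis = delta_method_ci(mm, om, 0.0, 1.0, _EMPTY_CBAR)
        assert all(s == 0.0 for s in ses.values())
        for eff, (lo, hi) in cis.items():
            assert lo == hi

    def test_sobel_formula_recovered_without_interaction(self, rng):
        n = 2000
        a = rng.normal(0, 1.5, n)
        m = 0.6 * a + rng.normal(0, 1, n)
        y = 0.5 * a + 1.2 * m + rng.normal(0, 1, n)
        Xm = sm.add_constant(pd.DataFrame({"exposure_score": a}))
        mfit = sm.OLS(m, Xm).fit()
        Xy = sm.add_constant(pd.DataFrame({"exposure_score": a, "mediator_score": m}))
        yfit = sm.OLS(y, Xy).fit()

        mcols = ["const", "exposure_score"]
        ycols = ["const", "exposure_score", "mediator_score", "exposure_x_mediator"]
        mcov = pd.DataFrame(mfit.cov_params().to_numpy(), index=mcols, columns=mcols)
        ycov = pd.DataFrame(0.0, index=ycols, columns=ycols)
        ycov.iloc[:3, :3] = yfit.cov_params().to_numpy()  # theta3 block fixed at 0
        mm = MediatorModel(float(mfit.params.iloc[0]), float(mfit.params.iloc[1]),
                           pd.Series(dtype=float), float(np.sqrt(mfit.scale)), mcov)
        om = OutcomeModel(float(yfit.params.iloc[0]), float(yfit.params.iloc[1]),
                          float(yfit.params.iloc[2]), 0.0, pd.Series(dtype=float), ycov)

        ses, _ = delta_method_ci(mm, om, 0.0, 1.0, _EMPTY_CBAR)
        var_a1 = mcov.loc["exposure_score", "exposure_score"]
        var_t2 = ycov.loc["mediator_score", "mediator_score"]
        sobel = np.sqrt(om.theta2**2 * var_a1 + mm.alpha1**2 * var_t2)
        assert ses["tie"] == pytest.approx(sobel, rel=1e-10)

    def test_delta_and_bootstrap_cis_agree(self, latent_cohort):
        t = latent_cohort.iloc[:4000]
        res = MediationModel(t, "smfq_w3", a0=3.3, a1=5.5).fit()
        boot = res.bootstrap_ci(n_boot=2000, seed=3)
        for eff in ("te", "pde", "tie"):
            dlo, dhi = res.result.ci[eff]
            blo, bhi = boot[eff]
            width = dhi - dlo
            assert abs(dlo - blo) < 0.15 * width, eff
            assert abs(dhi - bhi) < 0.15 * width, eff


class TestMCOracle:
    def test_matches_closed_forms_within_3_mc_ses(self):
        mm, om = _toy_models(sigma=1.5)
        res = two_way_decompose(mm, om, 0.0, 2.0, _EMPTY_CBAR)
        mc = mc_counterfactual_oracle(mm, om, _EMPTY_CBAR, 0.0, 2.0,
                                      n_draws=100_000, seed=1)
        assert abs(mc.nde - res.pde) < 3 * max(mc.nde_se, 1e-12)
        assert abs(mc.nie - res.tie) < 3 * max(mc.nie_se, 1e-12)

    def test_vanishing_mediator_noise_is_exact(self):
        mm, om = _toy_models(sigma=1e-12)
        res = two_way_decompose(mm, om, 0.0, 1.0, _EMPTY_CBAR)
        mc = mc_counterfactual_oracle(mm, om, _EMPTY_CBAR, 0.0, 1.0,
                                      n_draws=2000, seed=2)
        assert mc.nde == pytest.approx(res.pde, abs=1e-9)
        assert mc.nie == pytest.approx(res.tie, abs=1e-9)

    def test_reproducible_under_fixed_seed(self):
        mm, om = _toy_models()
        a = mc_counterfactual_oracle(mm, om, _EMPTY_CBAR, 0.0, 1.0, 5000, seed=9)
        b = mc_counterfactual_oracle(mm, om, _EMPTY_CBAR, 0.0, 1.0, 5000, seed=9)
        assert (a.nde, a.nie) == (b.nde, b.nie)

    def test_too_few_draws_rejected(self):
        mm, om = _toy_models()
        with pytest.raises(ValueError, match="n_draws"):
            mc_counterfactual_oracle(mm, om, _EMPTY_CBAR, 0.0, 1.0, 10, seed=0)


class TestProportionMediated:
    @pytest.mark.parametrize("te,tie,expected", [
        (0.5, 0.0, 0.0),
        (0.5, 0.5, 100.0),
        (0.26, 0.08, pytest.approx(100 * 0.08 / 0.26)),
    ])
    def test_values(self, te, tie, expected):
        assert proportion_mediated(te, tie) == expected

    def test_zero_total_effect_signaled(self):
        with pytest.raises(ZeroDivisionError):
            proportion_mediated(0.0, 0.1)


class TestModelSurface:
    def test_default_contrast_is_mean_to_mean_plus_sd(self, small_cohort):
        model = MediationModel(small_cohort, "smfq_w3")
        mean = small_cohort["exposure_score"].mean()
        sd = small_cohort["exposure_score"].std(ddof=1)
        assert model.a0 == pytest.approx(mean)
        assert model.a1 == pytest.approx(mean + sd)

    def test_latent_truth_recovered(self, latent_config, latent_cohort):
        res = MediationModel(latent_cohort, "smfq_w3", a0=3.3, a1=5.5).fit()
        truth = true_effects(latent_config, 3.3, 5.5, outcome="smfq")
        for eff in ("te", "pde", "tie"):
            lo, hi = res.result.ci[eff]
            est, se = getattr(res.result, eff), res.result.se[eff]
            assert abs(est - getattr(truth, eff)) < 3 * se, eff

    def test_gender_stratified_fits_drop_stratifier(self, small_cohort):
        model = MediationModel(small_cohort, "anxiety_w3")
        strata = model.fit_stratified("gender")
        assert set(strata) == {0.0, 1.0}
        for res in strata.values():
            assert "gender" not in res.model.covariates
            assert res.result.a0 == pytest.approx(model.a0)

    def test_summary_reports_effects_and_pm(self, small_cohort):
        res = MediationModel(small_cohort, "smfq_w3").fit()
        s = res.summary()
        assert list(s["effect"]) == ["te", "pde", "tie"]
        assert s.attrs["proportion_mediated_pct"] == pytest.approx(
            res.proportion_mediated
        )
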