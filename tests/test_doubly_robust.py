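"""Propensity weighting, DR standardization, bootstrap, RERI/RRR, E-values."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from drmediate._glm import SeparationError, fit_logistic
from drmediate.doubly_robust import (
    DoublyRobustModel,
    bootstrap_ci,
    dr_standardize,
    e_value,
    fit_propensity,
    reri_rrr,
)
from drmediate.synthetic import DRGenerationConfig, generate_dr_cohort


class TestFastLogistic:
    def test_matches_statsmodels_glm(self, rng):
        n = 800
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        y = rng.binomial(1, expit(X @ np.array([-0.5, 0.8, -0.4, 0.2])))
        w = rng.uniform(0.5, 2.0, n)
        beta = fit_logistic(X, y, sample_weight=w)
        ref = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w).fit()
        np.testing.assert_allclose(beta, ref.params, rtol=1e-7, atol=1e-9)


class TestFitPropensity:
    def test_constant_only_weight_is_inverse_prevalence(self):
        t = pd.DataFrame({"treatment": [1] * 25 + [0] * 75})
        w = fit_propensity(t, [])
        assert w.weight[0] == pytest.approx(1 / 0.25)
        assert w.weight[-1] == pytest.approx(1 / 0.75)

    def test_saturated_binary_covariate_matches_stratum_fractions(self):
        t = pd.DataFrame({
            "c": [0] * 100 + [1] * 100,
            "treatment": [1] * 20 + [0] * 80 + [1] * 60 + [0] * 40,
        })
        w = fit_propensity(t, ["c"])
        assert w.propensity[0] == pytest.approx(0.2, abs=1e-6)
        assert w.propensity[-1] == pytest.approx(0.6, abs=1e-6)

    def test_independent_covariates_give_marginal_prevalence(self, rng):
        n = 20000
        t = pd.DataFrame({"c": rng.normal(size=n), "treatment": rng.binomial(1, 0.3, n)})
        w = fit_propensity(t, ["c"])
        assert np.all(np.abs(w.propensity - 0.3) < 0.05)

    def test_mean_weight_near_two_per_arm(self):
        tab, _ = generate_dr_cohort(DRGenerationConfig(n_subjects=5000, seed=3))
        covs = ["gender", "iq", "loneliness", "time_gaming", "problematic_internet"]
        w = fit_propensity(tab, covs)
        treated = tab["treatment"] == 1
        # unstabilized IPW: each arm's weights sum to ~n, so overall mean ~2
        assert w.weight[treated].sum() == pytest.approx(len(tab), rel=0.15)
        assert w.weight[~treated].sum() == pytest.approx(len(tab), rel=0.15)

    def test_separation_signaled_with_count(self):
        t = pd.DataFrame({"c": np.r_[np.zeros(20), np.ones(20)],
                          "treatment": np.r_[np.zeros(20), np.ones(20)]})
        with pytest.raises(SeparationError):
            fit_propensity(t, ["c"])

    def test_empty_arm_rejected(self):
        t = pd.DataFrame({"c": [0.0, 1.0], "treatment": [1, 1]})
        with pytest.raises(ValueError, match="empty arm"):
            fit_propensity(t, ["c"])


class TestDRStandardize:
    def test_saturated_equals_crude_2x2(self):
        t = pd.DataFrame({
            "treatment": [1] * 200 + [0] * 400,
            "outcome": [1] * 40 + [0] * 160 + [1] * 40 + [0] * 360,
        })
        w = fit_propensity(t, [])
        res = dr_standardize(t, w, "outcome", [])
        crude = 40 / 200 - 40 / 400
        assert res.rd == pytest.approx(crude, abs=1e-9)
        assert res.rr == pytest.approx((40 / 200) / (40 / 400), abs=1e-7)

    def test_uniform_weights_reduce_to_plain_gformula(self, rng):
        n = 600
        c = rng.normal(size=n)
        t = rng.binomial(1, 0.4, n)
        y = rng.binomial(1, expit(-1 + 0.8 * t + 0.5 * c))
        tab = pd.DataFrame({"c": c, "treatment": t, "outcome": y})
        res = dr_standardize(tab, None, "outcome", ["c"])
        # independent oracle: statsmodels logistic + manual standardization
        X = sm.add_constant(tab[["treatment", "c"]])
        fit = sm.GLM(tab["outcome"], X, family=sm.families.Binomial()).fit()
        X1, X0 = X.copy(), X.copy()
        X1["treatment"], X0["treatment"] = 1.0, 0.0
        r1, r0 = fit.predict(X1).mean(), fit.predict(X0).mean()
        assert res.risk1 == pytest.approx(r1, abs=1e-8)
        assert res.risk0 == pytest.approx(r0, abs=1e-8)

    def test_counterfactual_oracle_recovery(self):
        cfg = DRGenerationConfig(n_subjects=20000, seed=9)
        tab, truth = generate_dr_cohort(cfg)
        covs = sorted(set(cfg.propensity_coefs) | set(cfg.outcome_coefs))
        model = DoublyRobustModel(tab, "outcome", "treatment", covariates=covs)
        res = model.fit(n_boot=200, seed=5)
        se_rd = (res.result.rd_ci[1] - res.result.rd_ci[0]) / (2 * 1.96)
        assert abs(res.rd - truth.rd) < 3 * se_rd
        se_logrr = (np.log(res.result.rr_ci[1]) - np.log(res.result.rr_ci[0])) / (2 * 1.96)
        assert abs(np.log(res.rr) - np.log(truth.rr)) < 3 * se_logrr

    def test_all_zero_outcome_degenerate(self):
        t = pd.DataFrame({"treatment": [0, 1, 0, 1], "outcome": [0, 0, 0, 0]})
        res = dr_standardize(t, None, "outcome", [])
        assert (res.risk1, res.risk0, res.rd, res.rr) == (0.0, 0.0, 0.0, None)


class TestBootstrapCI:
    def test_degenerate_estimator_gives_point_interval(self, small_cohort):
        ci = bootstrap_ci(lambda t: {"c": 3.14}, small_cohort, 50, seed=0)
        assert ci["c"] == (3.14, 3.14)

    def test_fixed_seed_reproducible(self, small_cohort):
        est = lambda t: {"m": float(t["smfq_w3"].mean())}
        assert bootstrap_ci(est, small_cohort, 100, seed=7) == \
               bootstrap_ci(est, small_cohort, 100, seed=7)

    def test_excess_failures_escalate(self, small_cohort):
        def bad(t):
            raise ValueError("no")
        with pytest.raises(RuntimeError, match="replicates failed"):
            bootstrap_ci(bad, small_cohort, 20, seed=0)


class TestReriRrr:
    @staticmethod
    def _joint_table(risks: dict, n_per_cell=1000):
        """Deterministic 2x2x{case} table with exact joint risks."""
        frames = []
        for (t, g), r in risks.items():
            k = int(round(n_per_cell * r))
            frames.append(pd.DataFrame({
                "treatment": t, "gender": 1 - g,  # g=1 means non-reference (girls)
                "outcome": [1] * k + [0] * (n_per_cell - k),
            }))
        return pd.concat(frames, ignore_index=True)

    def test_joint_null(self):
        t = self._joint_table({(0, 0): 0.1, (1, 0): 0.1, (0, 1): 0.1, (1, 1): 0.1})
        res = reri_rrr(t, "outcome", covariates=[])
        assert res.reri == pytest.approx(0.0, abs=1e-7)
        assert res.rrr == pytest.approx(1.0, abs=1e-7)

    def test_hand_computed_values(self):
        # rr10=1.5, rr01=1.2, rr11=2.0 -> RERI=0.3, RRR=2/1.8
        t = self._joint_table({(0, 0): 0.10, (1, 0): 0.15, (0, 1): 0.12, (1, 1): 0.20})
        res = reri_rrr(t, "outcome", covariates=[])
        assert res.rr10 == pytest.approx(1.5, abs=1e-6)
        assert res.rr01 == pytest.approx(1.2, abs=1e-6)
        assert res.rr11 == pytest.approx(2.0, abs=1e-6)
        assert res.reri == pytest.approx(0.3, abs=1e-6)
        assert res.rrr == pytest.approx(2.0 / 1.8, abs=1e-6)

    def test_exact_multiplicativity_gives_unit_rrr(self):
        t = self._joint_table({(0, 0): 0.10, (1, 0): 0.15, (0, 1): 0.20, (1, 1): 0.30})
        res = reri_rrr(t, "outcome", covariates=[])
        assert res.rrr == pytest.approx(1.0, abs=1e-6)

    def test_empty_category_rejected(self):
        t = self._joint_table({(0, 0): 0.1, (1, 0): 0.1, (0, 1): 0.1, (1, 1): 0.1})
        t = t[~((t.treatment == 1) & (t.gender == 0))]
        with pytest.raises(ValueError, match="empty joint category"):
            reri_rrr(t, "outcome", covariates=[])


class TestEValue:
    @pytest.mark.parametrize("rr,expected", [
        (1.62, 2.62), (1.98, 3.37), (1.54, 2.45),
    ])
    def test_point_evalues_round_to_published_convention(self, rr, expected):
        assert round(e_value(rr).evalue_point, 2) == expected

    def test_null_is_one(self):
        assert e_value(1.0).evalue_point == pytest.approx(1.0)

    def test_protective_rr_inverted(self):
        assert e_value(0.5).evalue_point == pytest.approx(2 + np.sqrt(2))

    def test_monotone_and_dominates_rr(self):
        rrs = np.linspace(1.0, 5.0, 40)
        evs = [e_value(r).evalue_point for r in rrs]
        assert np.all(np.diff(evs) > 0)
        assert np.all(np.array(evs) >= rrs - 1e-12)

    def test_ci_crossing_null_gives_one(self):
        assert e_value(1.5, 0.9, 2.1).evalue_ci == 1.0

    def test_ci_bound_closer_to_null_used(self):
        res = e_value(1.62, 1.25, 2.05)
        assert res.evalue_ci == pytest.approx(1.25 + np.sqrt(1.25 * 0.25))

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValueError):
            e_value(0.0)


class TestModelSurface:
    def test_summary_and_evalue(self):
        tab, _ = generate_dr_cohort(DRGenerationConfig(n_subjects=2500, seed=15))
        covs = ["gender", "iq", "loneliness", "time_gaming", "problematic_internet"]
        res = DoublyRobustModel(tab, "outcome", "treatment", covariates=covs).fit(
            n_boot=100, seed=2
        )
        s = res.summary()
        assert set(s["quantity"]) == {"risk1", "risk0", "rd", "rr"}
        assert res.e_value().evalue_point >= 1.0
        lo, hi = res.result.rd_ci
        assert lo <= res.rd <= hi
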