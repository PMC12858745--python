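"""Registered analysis models: likelihood-oracle agreement, covariate
screening, descriptive summaries and effect disentangling."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import scipy.optimize as opt
from scipy.special import expit

from earpiece import analyses, derive, synth
from earpiece.derive import TTS_LEVELS


@pytest.fixture(scope="module")
def small_derived(curve=None):
    from earpiece import dosimetry

    cohort = synth.generate_cohort(synth.GeneratorConfig(n=700), seed=88)
    return derive.attach_derived(
        cohort.participants, cohort.segments, dosimetry.default_calibration(), seed=88
    )


# ---------------------------------------------------------------------------
# likelihood oracles: direct numerical optimisation of the written likelihood
# ---------------------------------------------------------------------------

def _logit_nll(beta, y, X):
    eta = X @ beta
    return -np.sum(y * eta - np.logaddexp(0.0, eta))


def _ordinal_nll(theta, y_codes, x, n_levels):
    slope = theta[0]
    cuts = np.concatenate([[theta[1]], theta[1] + np.cumsum(np.exp(theta[2:]))])
    eta = slope * x
    upper = np.where(y_codes < n_levels - 1, expit(cuts[np.minimum(y_codes, n_levels - 2)] - eta), 1.0)
    lower = np.where(y_codes > 0, expit(cuts[y_codes - 1] - eta), 0.0)
    return -np.sum(np.log(np.maximum(upper - lower, 1e-300)))


class TestLikelihoodOracles:
    def test_logistic_fit_matches_direct_mle(self, small_derived):
        sample, _ = derive.analysis_sample(small_derived, "RQ4")
        fr = analyses.rq4_logistic(sample, include_age=True)
        df = sample.dropna(subset=["tin_long"])
        y = df["tin_long"].to_numpy(float)
        X = np.column_stack(
            [np.ones(len(df)), (df["device_use"] != "nonuser").to_numpy(float),
             df["age"].to_numpy(float)]
        )
        res = opt.minimize(
            _logit_nll, np.zeros(3), args=(y, X), method="BFGS",
            options={"gtol": 1e-12, "maxiter": 500},
        )
        # statsmodels reports odds ratios; compare on the log scale
        assert np.log(fr.term("user").estimate) == pytest.approx(res.x[1], abs=1e-6)
        assert np.log(fr.term("age").estimate) == pytest.approx(res.x[2], abs=1e-6)

    def test_ordinal_fit_matches_direct_mle(self, small_derived):
        sample, _ = derive.analysis_sample(small_derived, "RQ3")
        fr = analyses.rq3_ordinal(sample, include_age=False)
        df = sample.dropna(subset=["tts_prop", "volume_average"])
        y_codes = pd.Categorical(df["tts_prop"], categories=TTS_LEVELS, ordered=True).codes
        x = df["volume_average"].to_numpy(float)
        x_c = x - x.mean()  # centring improves conditioning; slope unchanged
        start = np.zeros(1 + 4)
        start[1] = -1.0
        res = opt.minimize(
            _ordinal_nll, start, args=(y_codes, x_c, 5), method="BFGS",
            options={"gtol": 1e-10, "maxiter": 2000},
        )
        assert res.success or np.linalg.norm(res.jac) < 1e-4
        assert fr.term("volume_average").estimate == pytest.approx(res.x[0], abs=1e-5)


# ---------------------------------------------------------------------------
# covariate screening rule
# ---------------------------------------------------------------------------

class TestCovariateRule:
    def _frame(self, n, confounded, rng):
        user = rng.random(n) < 0.5
        age = rng.normal(55, 8, n)
        if confounded:
            age = age - 3.0 * user
        p = expit(-1.8 + (0.02 * (age - 55) if confounded else 0.0))
        tin = rng.random(n) < p
        return pd.DataFrame({"user": user, "age": age, "tin_long": tin})

    def test_confounder_included(self, rng):
        df = self._frame(4000, confounded=True, rng=rng)
        include, log = analyses.covariate_rule(df, "age", "user", "tin_long")
        assert include
        assert log["p_vs_exposure"] < 0.05 and log["p_vs_outcome"] < 0.05

    def test_independent_candidate_excluded(self, rng):
        df = self._frame(4000, confounded=False, rng=rng)
        include, log = analyses.covariate_rule(df, "age", "user", "tin_long")
        assert not include

    def test_decision_always_logged(self, small_derived):
        sample, _ = derive.analysis_sample(small_derived, "RQ4")
        fr = analyses.rq4_logistic(sample)
        assert fr.covariate_log["candidate"] == "age"
        assert "p_vs_exposure" in fr.covariate_log
        assert fr.covariate_included == fr.covariate_log["included"]
        assert "unadjusted" in fr.extra  # both fits always reported


# ---------------------------------------------------------------------------
# descriptive analyses
# ---------------------------------------------------------------------------

class TestDescriptives:
    def test_rq1_strict_exceedance(self):
        df = pd.DataFrame(
            {
                "weekly_level": [85.0] * 10,
                "exposure_hours": [100.0] * 10,
                "weeks_of_use": [47.0] * 10,
                "avg_level_during_exposure": [95.0] * 10,
            }
        )
        out = analyses.rq1_describe(df)
        assert out["frac_above_action_value"] == 0.0
        assert out["median_weekly_level"] == 85.0

    def test_rq1_fraction_matches_construction(self):
        levels = np.concatenate([np.full(76, 90.0), np.full(24, 80.0)])
        df = pd.DataFrame(
            {
                "weekly_level": levels,
                "exposure_hours": np.full(100, 100.0),
                "weeks_of_use": np.full(100, 47.0),
                "avg_level_during_exposure": np.full(100, 95.0),
            }
        )
        out = analyses.rq1_describe(df)
        assert out["frac_above_action_value"] == pytest.approx(0.76)

    def test_rq1_empty(self):
        df = pd.DataFrame(
            {"weekly_level": [np.nan], "exposure_hours": [0.0],
             "weeks_of_use": [0.0], "avg_level_during_exposure": [np.nan]}
        )
        assert analyses.rq1_describe(df) == {"n": 0}

    def test_rq2_table_and_summary(self, small_derived):
        sample, _ = derive.analysis_sample(small_derived, "RQ3")
        table, summary = analyses.rq2_describe(sample)
        assert list(table["response"]) == TTS_LEVELS
        assert summary["pct_ever"] == pytest.approx(
            100 - table.loc[0, "proportion_pct"]
        )
        assert (table["ci_low_pct"] <= table["proportion_pct"]).all()


# ---------------------------------------------------------------------------
# model behaviour on constructed cohorts
# ---------------------------------------------------------------------------

class TestModelBehaviour:
    def test_rq3_degenerate_design_raises(self, small_derived):
        sample, _ = derive.analysis_sample(small_derived, "RQ3")
        sample = sample.copy()
        sample["volume_average"] = 70.0
        with pytest.raises(ValueError):
            analyses.rq3_ordinal(sample)

    def test_rq3_positive_slope_recovered(self):
        from earpiece import dosimetry

        cfg = synth.GeneratorConfig(n=2000)
        cohort = synth.generate_cohort(cfg, seed=3)
        df = derive.attach_derived(
            cohort.participants, cohort.segments, dosimetry.default_calibration(), seed=3
        )
        fr = analyses.run_analysis(df, "RQ3")
        e = fr.term("volume_average")
        assert e.estimate > 0 and e.p < 0.05
        assert e.ci_low <= cfg.tts_slope <= e.ci_high

    def test_rq6_disentangles_ear_bias_from_exposure(self, rng):
        # tinnitus prefers the left ear regardless of which ear is exposed:
        # the ear term should fire, the exposure term should not
        n = 500
        ids = [f"p{i}" for i in range(n)]
        exposed_side = np.where(rng.random(n) < 0.5, "right", "left")
        tin_side = np.where(rng.random(n) < 0.70, "left", "right")
        rows = []
        for ear in ("right", "left"):
            rows.append(
                pd.DataFrame(
                    {"participant_id": ids, "ear": ear,
                     "exposed": exposed_side == ear, "tin_present": tin_side == ear}
                )
            )
        ears = pd.concat(rows, ignore_index=True)
        fr = analyses.rq6_earwise(ears)
        ear_term = fr.term("ear_right")
        exp_term = fr.term("exposed")
        assert ear_term.ci_high < 1.0  # right ear disfavoured
        assert exp_term.ci_low <= 1.0 <= exp_term.ci_high

    def test_rq6_concordance_drives_exposure_term(self):
        ears = synth.generate_earwise_null(400, seed=10)
        # rebuild with concordance 0.8 by flipping tinnitus sides (fresh
        # stream, independent of the generator's own draws)
        rng = np.random.default_rng(1010)
        wide = ears.pivot(index="participant_id", columns="ear", values="exposed")
        exposed_side = np.where(wide["right"], "right", "left")
        tin_side = np.where(
            rng.random(len(wide)) < 0.8, exposed_side,
            np.where(exposed_side == "right", "left", "right"),
        )
        rows = []
        for ear in ("right", "left"):
            rows.append(
                pd.DataFrame(
                    {"participant_id": wide.index, "ear": ear,
                     "exposed": exposed_side == ear, "tin_present": tin_side == ear}
                )
            )
        fr = analyses.rq6_earwise(pd.concat(rows, ignore_index=True))
        e = fr.term("exposed")
        truth = 0.8 / 0.2  # conditional odds of the tinnitus ear being exposed
        assert e.p < 0.05
        assert e.ci_low <= truth <= e.ci_high

    def test_rq6_pooled_method_estimates_marginal_odds(self):
        ears = synth.generate_earwise_null(600, seed=4)
        fr = analyses.rq6_earwise(ears, method="pooled")
        e = fr.term("exposed")
        assert e.ci_low <= 1.0 <= e.ci_high
        with pytest.raises(ValueError):
            analyses.rq6_earwise(ears, method="bogus")

    def test_rq7_planted_deficit_recovered(self):
        from earpiece import dosimetry

        cfg = synth.GeneratorConfig(n=3000, din_exposure_effect=1.0)
        cohort = synth.generate_cohort(cfg, seed=21)
        df = derive.attach_derived(
            cohort.participants, cohort.segments, dosimetry.default_calibration(), seed=21
        )
        fr = analyses.run_analysis(df, "RQ7")
        e = fr.term("user")
        assert e.p < 0.05
        assert e.ci_low <= 1.0 <= e.ci_high

    def test_rq7_side_effect_does_not_masquerade_as_use(self):
        # right ears better by 0.5 dB, exposure effect zero: the side term
        # should absorb the asymmetry and leave the use term null
        from earpiece import dosimetry

        cfg = synth.GeneratorConfig(n=3000, right_ear_advantage=0.5)
        cohort = synth.generate_cohort(cfg, seed=55)
        df = derive.attach_derived(
            cohort.participants, cohort.segments, dosimetry.default_calibration(), seed=55
        )
        fr = analyses.run_analysis(df, "RQ7")
        side = fr.term("side_right")
        use = fr.term("user")
        assert side.p < 0.05
        assert use.ci_low <= 0.0 <= use.ci_high

    def test_results_reproducible(self, derived):
        a = analyses.run_analysis(derived, "RQ4")
        b = analyses.run_analysis(derived, "RQ4")
        assert a.to_dict() == b.to_dict()

    def test_exclusion_log_accounts_for_n(self, derived):
        fr = analyses.run_analysis(derived, "RQ5")
        log = fr.exclusion_log
        assert log["input"] - log["excluded_nonuser"] == log["analysed"]
        assert fr.n_used <= log["analysed"]  # listwise deletion may drop more
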