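"""Mixed-model estimation: oracles, ICC, Omega^2, contrast, moderation, power."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from _oracles import gls_fixed_effects, make_occasions
from paskit import multilevel as ml
from paskit.errors import EstimationError, InputError, UndefinedStatisticError


class TestFitNull:
    def test_icc_is_variance_ratio_small(self, rng):
        df = make_occasions(rng, n_persons=150, n_occ=20, beta=(13.5, 0, 0),
                            sds=(1.0, 0, 0), resid_sd=3.0, p_single=0, p_group=0)
        fit = ml.fit_null(df)
        assert fit.icc == pytest.approx(1.0 / 10.0, abs=0.03)

    def test_intercept_only_design_echoes_study_icc(self, rng):
        # person SD 3.29 with residual SD 10.53 => ICC = 3.29^2/(3.29^2+10.53^2) ~ 0.089
        df = make_occasions(rng, n_persons=250, n_occ=25, beta=(13.5, 0, 0),
                            sds=(3.29, 0, 0), resid_sd=10.53, p_single=0, p_group=0)
        fit = ml.fit_null(df)
        expected = 3.29**2 / (3.29**2 + 10.53**2)
        assert fit.icc == pytest.approx(expected, abs=0.02)
        # internal consistency: icc recomputed from the components
        tau0 = fit.re_sd["intercept"] ** 2
        assert fit.icc == pytest.approx(tau0 / (tau0 + fit.resid_var), abs=1e-12)

    def test_constant_outcome_flagged(self):
        df = pd.DataFrame({"person_id": ["A"] * 3 + ["B"] * 3, "offendedness": [5.0] * 6})
        with pytest.raises(EstimationError):
            ml.fit_null(df)

    def test_singleton_data_rejected(self):
        df = pd.DataFrame({"person_id": ["A", "B"], "offendedness": [1.0, 2.0]})
        with pytest.raises(EstimationError):
            ml.fit_null(df)


class TestFitSaturated:
    def test_fixed_effects_match_gls_oracle(self, rng):
        df = make_occasions(rng, n_persons=6, n_occ=12, p_single=0.4, p_group=0.2)
        fit = ml.fit_saturated(df)
        beta = gls_fixed_effects(
            df,
            fit.re_sd["intercept"] ** 2,
            fit.re_sd["single_chat"] ** 2,
            fit.re_sd["group_chat"] ** 2,
            fit.resid_var,
        )
        got = fit.fixed["estimate"][["Intercept", "single_chat", "group_chat"]].to_numpy()
        assert np.allclose(got, beta, atol=1e-6)

    def test_zero_variance_slopes_estimated_near_zero(self, rng):
        df = make_occasions(rng, n_persons=100, n_occ=40, sds=(3.0, 0.0, 0.0), resid_sd=5.0)
        fit = ml.fit_saturated(df)
        assert fit.re_sd["single_chat"] < 1.0
        assert fit.re_sd["group_chat"] < 1.0

    def test_missing_event_type_inestimable(self, rng):
        df = make_occasions(rng, n_persons=10, n_occ=10, p_single=0.4, p_group=0.0)
        with pytest.raises(EstimationError):
            ml.fit_saturated(df)

    def test_level2_centering_absorbs_constant_shifts(self, rng):
        occ = make_occasions(rng, n_persons=40, n_occ=25)
        persons = pd.DataFrame(
            {
                "person_id": sorted(occ["person_id"].unique()),
                "sex": rng.integers(1, 3, 40),
                "age": rng.normal(26, 9, 40),
                "self_esteem": rng.standard_normal(40),
            }
        )
        fit1 = ml.fit_saturated(occ, persons)
        shifted = persons.assign(age=persons["age"] + 100.0)
        fit2 = ml.fit_saturated(occ, shifted)
        assert np.allclose(
            fit1.fixed["estimate"].to_numpy(), fit2.fixed["estimate"].to_numpy(), atol=1e-6
        )

    def test_collinear_level2_design_named(self, rng):
        occ = make_occasions(rng, n_persons=20, n_occ=10)
        base = rng.standard_normal(20)
        persons = pd.DataFrame(
            {
                "person_id": sorted(occ["person_id"].unique()),
                "self_esteem": base,
                "narcissism": 2.0 * base,  # exact collinearity
            }
        )
        with pytest.raises(EstimationError, match="collinear"):
            ml.fit_saturated(occ, persons)

    def test_fixed_effects_match_lme4(self, rng, tmp_path):
        """Cross-check against an independent REML implementation (lme4)."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        df = make_occasions(rng, n_persons=30, n_occ=14)
        csv = tmp_path / "occ.csv"
        df.to_csv(csv, index=False)
        script = (
            f"d <- read.csv('{csv}');"
            "m <- lme4::lmer(offendedness ~ single_chat + group_chat"
            " + (1 | person_id) + (0 + single_chat | person_id)"
            " + (0 + group_chat | person_id), data = d, REML = TRUE);"
            "cat(sprintf('%.10f\\n', lme4::fixef(m)))"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        theirs = [float(v) for v in out.stdout.strip().splitlines()[-3:]]
        fit = ml.fit_saturated(df)
        ours = fit.fixed["estimate"][["Intercept", "single_chat", "group_chat"]].to_numpy()
        assert np.allclose(ours, theirs, atol=2e-3)


class TestOmegaSquaredAndContrast:
    def test_full_equals_null_gives_zero(self, rng):
        df = make_occasions(rng, n_persons=20, n_occ=10, p_single=0, p_group=0,
                            beta=(13.5, 0, 0))
        null = ml.fit_null(df)
        assert ml.omega_squared(null, null) == 0.0

    def test_halved_residual_variance(self, rng):
        df = make_occasions(rng, n_persons=10, n_occ=10)
        null = ml.fit_null(df)
        full = ml.fit_null(df)
        full.resid_var = null.resid_var / 2.0
        assert ml.omega_squared(full, null) == pytest.approx(0.5)

    def test_mismatched_data_rejected(self, rng):
        a = ml.fit_null(make_occasions(rng, n_persons=10, n_occ=10))
        b = ml.fit_null(make_occasions(rng, n_persons=10, n_occ=11))
        with pytest.raises(InputError):
            ml.omega_squared(a, b)

    def test_equal_slopes_give_zero_contrast(self, rng):
        df = make_occasions(rng, n_persons=20, n_occ=12)
        fit = ml.fit_saturated(df)
        fit.fixed.loc["group_chat", "estimate"] = fit.fixed.loc["single_chat", "estimate"]
        res = ml.contrast_group_vs_single(fit)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_contrast_needs_both_dummies(self, rng):
        null = ml.fit_null(make_occasions(rng, n_persons=10, n_occ=10))
        with pytest.raises(InputError):
            ml.contrast_group_vs_single(null)


class TestModerationScan:
    def _tables(self, rng, interaction=0.0, n_persons=24):
        rows = []
        mod = rng.standard_normal(n_persons)
        for i in range(n_persons):
            r0 = rng.normal(0, 2.0)
            for _ in range(12):
                s = int(rng.random() < 0.5)
                y = 10 + r0 + (5 + interaction * mod[i]) * s + rng.normal(0, 4.0)
                rows.append({"person_id": f"P{i}", "offendedness": y,
                             "single_chat": s, "group_chat": 0})
        # a few group events so the saturated model is estimable
        for i in range(n_persons):
            rows.append({"person_id": f"P{i}", "offendedness": 20 + rng.normal(0, 4),
                         "single_chat": 0, "group_chat": 1})
        occ = pd.DataFrame(rows)
        persons = pd.DataFrame({"person_id": [f"P{i}" for i in range(n_persons)],
                                "self_esteem": mod})
        return occ, persons

    def test_interaction_terms_reported(self, rng):
        occ, persons = self._tables(rng)
        table = ml.moderation_scan(occ, persons)
        assert set(table["dummy"]) == {"single_chat", "group_chat"}
        assert (table["moderator"] == "self_esteem").all()
        assert table["pvalue"].between(0, 1).all()

    def test_null_moderator_rarely_rejects(self, rng):
        hits = total = 0
        for _ in range(25):
            occ, persons = self._tables(rng, interaction=0.0)
            tab = ml.moderation_scan(occ, persons)
            row = tab[tab["dummy"] == "single_chat"].iloc[0]
            hits += row["pvalue"] < 0.05
            total += 1
        assert hits / total <= 0.20  # ~alpha, generous Monte-Carlo margin

    def test_strong_moderator_usually_detected(self, rng):
        hits = total = 0
        for _ in range(10):
            occ, persons = self._tables(rng, interaction=4.0)
            tab = ml.moderation_scan(occ, persons)
            row = tab[tab["dummy"] == "single_chat"].iloc[0]
            hits += row["pvalue"] < 0.05
            total += 1
        assert hits / total >= 0.6

    def test_constant_moderator_rejected(self, rng):
        occ, _ = self._tables(rng)
        persons = pd.DataFrame({"person_id": occ["person_id"].unique(),
                                "self_esteem": 1.0})
        with pytest.raises(UndefinedStatisticError):
            ml.moderation_scan(occ, persons)


class TestPower:
    def test_null_effect_power_is_alpha(self):
        rng = np.random.default_rng(11)
        p = ml.estimate_power(30, 0.0, alpha=0.05, obs_per_person=14,
                              n_sims=2000, rng=rng)
        assert p == pytest.approx(0.05, abs=0.02)

    def test_enormous_effect_hits_search_floor(self):
        res = ml.power_min_n(effect_size=10.0, rng_seed=3, n_min=4)
        assert res["min_n"] == 4

    def test_min_n_monotone_in_effect(self):
        big = ml.power_min_n(effect_size=0.8, rng_seed=3)
        small = ml.power_min_n(effect_size=0.3, rng_seed=3)
        assert small["min_n"] >= big["min_n"]
        assert small["power"] >= 0.8

    def test_unreachable_target_is_explicit(self):
        with pytest.raises(EstimationError):
            ml.power_min_n(effect_size=0.01, rng_seed=3, n_cap=16, n_sims=200)

    def test_medium_effect_fortnight_design_near_reported_planning_n(self):
        res = ml.power_min_n(effect_size=0.3, alpha=0.05, obs_per_person=14,
                             power_target=0.8, rng_seed=1)
        # qualitative agreement with the planning figure of ~23 participants
        assert 10 <= res["min_n"] <= 45


class TestRecoveryInvariants:
    def test_fixed_effects_unbiased_over_replicates(self, ostracism_recovery):
        s = ostracism_recovery.summary()
        for name in ("beta_baseline", "beta_single", "beta_group"):
            row = s.loc[name]
            assert abs(row["bias"]) <= 3 * row["mc_se"], (name, row.to_dict())

    def test_random_effect_sds_recovered(self, ostracism_recovery):
        s = ostracism_recovery.summary()
        for name in ("sd_intercept", "sd_single_slope", "sd_group_slope"):
            row = s.loc[name]
            assert abs(row["bias"]) <= 3 * row["mc_se"], (name, row.to_dict())

    def test_residual_sd_recovered(self, ostracism_recovery):
        row = ostracism_recovery.summary().loc["residual_sd"]
        assert abs(row["bias"]) <= 3 * row["mc_se"]
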