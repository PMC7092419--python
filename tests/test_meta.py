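"""Two-stage meta-analysis: stage-1 logistic ORs, DL pooling, REML
meta-regression, against closed-form, profile-likelihood and metafor
oracles."""

import numpy as np
import pandas as pd
import pytest

from smoketrends.errors import ConfigurationError, DataError, StudyExclusionError
from smoketrends.harmonize import SmokingDefinition, harmonize_records
from smoketrends.meta import (StudyEffect, dl_pool, first_stage_fit,
                              fit_all_studies, forest_table, meta_regress)
from smoketrends.survey_synth import (PrevalenceSurface, SexParams,
                                      SurveyDesign, generate_survey)


def study_2x2(n_low_smk, n_low, n_high_smk, n_high, age=40):
    rows = []
    for edu, smk, n in (("low", True, n_low_smk), ("low", False, n_low - n_low_smk),
                        ("high", True, n_high_smk), ("high", False, n_high - n_high_smk)):
        rows += [{"survey": "S", "year": 2000, "age": age, "education": edu,
                  "current_smoker": smk}] * n
    return pd.DataFrame(rows)


class TestFirstStage:
    def test_closed_form_2x2(self):
        # single age band: MLE equals the classic 2x2 odds ratio, variance
        # the Woolf 1/a+1/b+1/c+1/d
        eff = first_stage_fit(study_2x2(30, 100, 10, 100))
        assert eff.effect == pytest.approx(np.log(30 * 90 / (70 * 10)), abs=1e-4)
        assert eff.variance == pytest.approx(1/30 + 1/70 + 1/10 + 1/90, rel=1e-3)

    def test_no_association_gives_zero(self):
        eff = first_stage_fit(study_2x2(25, 100, 25, 100))
        assert eff.effect == pytest.approx(0.0, abs=1e-10)

    def test_separation_is_excluded(self):
        with pytest.raises(StudyExclusionError):
            first_stage_fit(study_2x2(100, 100, 10, 100))

    def test_absent_category_is_excluded(self):
        df = study_2x2(30, 100, 10, 100)
        with pytest.raises(StudyExclusionError):
            first_stage_fit(df[df.education != "high"])

    def test_profile_likelihood_grid_oracle(self):
        """Age-adjusted log OR agrees with an independent profile-likelihood
        grid search to 1e-4 on a small study."""
        rng = np.random.default_rng(7)
        n = 200
        age = rng.integers(20, 60, n)
        edu = rng.choice(["low", "high"], n)
        lp = -0.4 + 0.9 * (edu == "low") + 0.02 * (age - 40)
        smk = rng.random(n) < 1 / (1 + np.exp(-lp))
        df = pd.DataFrame({"survey": "S", "year": 2000, "age": age,
                           "education": edu, "current_smoker": smk})
        eff = first_stage_fit(df)

        bands = sorted(set((age // 10) * 10))
        x_edu = (edu == "low").astype(float)
        dummies = np.column_stack([(age // 10) * 10 == b for b in bands[1:]]).astype(float)
        y = smk.astype(float)

        def profile_nll(beta):
            def nll_nuis(theta):
                a, g = theta[0], theta[1:]
                eta = a + beta * x_edu + dummies @ g
                return float(np.sum(np.log1p(np.exp(eta)) - y * eta))
            from scipy.optimize import minimize
            r = minimize(nll_nuis, np.zeros(1 + dummies.shape[1]), method="BFGS")
            return r.fun

        lo, hi = eff.effect - 0.5, eff.effect + 0.5
        for _ in range(3):  # coarse-to-fine grid refinement
            grid = np.linspace(lo, hi, 41)
            vals = [profile_nll(b) for b in grid]
            i = int(np.argmin(vals))
            lo, hi = grid[max(0, i - 1)], grid[min(len(grid) - 1, i + 1)]
        best = (lo + hi) / 2
        assert eff.effect == pytest.approx(best, abs=1e-4)

    def test_fit_all_studies_logs_exclusions(self):
        good = study_2x2(30, 100, 10, 100)
        bad = study_2x2(100, 100, 10, 100).assign(survey="BAD")
        effects, excluded = fit_all_studies(pd.concat([good, bad]))
        assert [e.study for e in effects] == ["S"]
        assert "BAD" in excluded and "separation" in excluded["BAD"]


class TestDLPool:
    def test_two_study_hand_oracle(self):
        eff = [StudyEffect("a", 0.0, 0.1), StudyEffect("b", 1.0, 0.1)]
        p = dl_pool(eff)
        assert p.q == pytest.approx(5.0, abs=1e-12)
        assert p.tau2 == pytest.approx(0.4, abs=1e-12)
        assert p.i2 == pytest.approx(0.8, abs=1e-12)
        assert p.effect == pytest.approx(0.5, abs=1e-12)

    def test_identical_effects_are_homogeneous(self):
        eff = [StudyEffect(s, 0.5, 0.1) for s in "abc"]
        p = dl_pool(eff)
        assert p.effect == pytest.approx(0.5)
        assert p.q == pytest.approx(0.0, abs=1e-12)
        assert p.tau2 == 0.0 and p.i2 == 0.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        eff = [StudyEffect(str(i), rng.normal(), rng.uniform(0.01, 0.3))
               for i in range(8)]
        a = dl_pool(eff)
        b = dl_pool(eff[::-1])
        assert a.effect == pytest.approx(b.effect, abs=1e-14)
        assert a.tau2 == pytest.approx(b.tau2, abs=1e-14)

    def test_single_study_passthrough(self):
        p = dl_pool([StudyEffect("a", 0.3, 0.04)])
        assert p.effect == 0.3 and p.tau2 == 0.0 and np.isnan(p.i2)

    def test_empty_is_error(self):
        with pytest.raises(DataError):
            dl_pool([])

    def test_matches_metafor_on_fixture(self):
        # frozen from R metafor 4.8: rma(yi, vi, method="DL")
        y, v = [0.2, 0.5, 0.1, 0.8, 0.4], [0.05, 0.08, 0.04, 0.1, 0.06]
        p = dl_pool([StudyEffect(str(i), a, b) for i, (a, b) in enumerate(zip(y, v))])
        assert p.effect == pytest.approx(0.330758377682, abs=1e-9)
        assert p.se == pytest.approx(0.113651524073, abs=1e-9)
        assert p.tau2 == pytest.approx(0.004736048265, abs=1e-9)
        assert p.q == pytest.approx(4.310891089109, abs=1e-9)
        assert p.i2 == pytest.approx(0.07211759301791, abs=1e-9)

    def test_reduces_to_fixed_effect_when_homogeneous(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            v = rng.uniform(0.05, 0.5, 6)
            y = rng.normal(0.2, 0.01, 6)  # spread well below sampling error
            eff = [StudyEffect(str(i), a, b) for i, (a, b) in enumerate(zip(y, v))]
            p = dl_pool(eff)
            if p.tau2 == 0.0:
                w = 1 / v
                assert p.effect == pytest.approx(float(w @ y / w.sum()), abs=1e-14)
                assert p.se == pytest.approx(float(np.sqrt(1 / w.sum())), abs=1e-14)

    def test_random_effects_se_never_below_fixed_effect(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            k = rng.integers(2, 10)
            v = rng.uniform(0.01, 0.5, k)
            y = rng.normal(0, 1, k)
            p = dl_pool([StudyEffect(str(i), a, b)
                         for i, (a, b) in enumerate(zip(y, v))])
            assert p.se >= float(np.sqrt(1 / (1 / v).sum())) - 1e-12


class TestMetaRegression:
    def test_exactly_linear_equal_variance_equals_ols(self):
        yr = np.arange(2000, 2010, dtype=float)
        y = 1.0 - 0.02 * (yr - 2000)
        eff = [StudyEffect(str(i), yi, 0.05, x) for i, (yi, x) in enumerate(zip(y, yr))]
        f = meta_regress(eff)
        assert f.slope == pytest.approx(-0.02, abs=1e-10)
        assert f.tau2 == pytest.approx(0.0, abs=1e-10)

    def test_matches_metafor_reml_on_fixture(self):
        # frozen from R metafor 4.8: rma(yi, vi, mods=~yr, method="REML", test="z")
        y, v, yr = [0.2, 0.5, 0.1, 0.8, 0.4], [0.05, 0.08, 0.04, 0.1, 0.06], [1, 2, 3, 4, 5]
        eff = [StudyEffect(str(i), a, b, x)
               for i, (a, b, x) in enumerate(zip(y, v, yr))]
        f = meta_regress(eff)
        assert f.tau2 == pytest.approx(0.013614792500, abs=1e-5)
        assert f.slope == pytest.approx(0.061420996425, abs=1e-6)
        assert f.slope_se == pytest.approx(0.085705804179, abs=1e-6)
        assert f.p_value == pytest.approx(0.473590575331, abs=1e-5)

    def test_mm_matches_metafor_dl_on_fixture(self):
        # frozen from R metafor 4.8: rma(yi, vi, mods=~yr, method="DL")
        y, v, yr = [0.2, 0.5, 0.1, 0.8, 0.4], [0.05, 0.08, 0.04, 0.1, 0.06], [1, 2, 3, 4, 5]
        eff = [StudyEffect(str(i), a, b, x)
               for i, (a, b, x) in enumerate(zip(y, v, yr))]
        f = meta_regress(eff, tau2_method="mm")
        assert f.tau2 == pytest.approx(0.014664634146, abs=1e-9)
        assert f.slope == pytest.approx(0.061517996916, abs=1e-9)

    def test_too_few_studies_rejected(self):
        eff = [StudyEffect("a", 0.1, 0.05, 1.0), StudyEffect("b", 0.2, 0.05, 2.0)]
        with pytest.raises(ConfigurationError):
            meta_regress(eff)

    def test_constant_covariate_rejected(self):
        eff = [StudyEffect(s, 0.1, 0.05, 2000.0) for s in "abcd"]
        with pytest.raises(ConfigurationError):
            meta_regress(eff)

    def test_slope_recovery_within_two_se(self):
        """k=17 studies, true slope -0.01/yr, within-study variance 0.002:
        the REML slope lands within 2 SE of truth in >= 95% of replicates."""
        rng = np.random.default_rng(2024)
        years = np.linspace(1996.0, 2016.0, 17)
        hits = 0
        reps = 500
        for _ in range(reps):
            y = 0.6 - 0.01 * (years - 1996) + rng.normal(0, np.sqrt(0.002), 17)
            eff = [StudyEffect(str(i), yi, 0.002, x)
                   for i, (yi, x) in enumerate(zip(y, years))]
            f = meta_regress(eff)
            hits += abs(f.slope - (-0.01)) < 2 * f.slope_se
        assert hits / reps >= 0.95


class TestForestTable:
    def test_single_study_equals_pooled(self):
        eff = [StudyEffect("a", 0.4, 0.02)]
        tbl = forest_table(eff, dl_pool(eff))
        assert tbl.loc[0, "or"] == pytest.approx(tbl.loc[1, "or"])

    def test_weights_sum_to_100(self):
        rng = np.random.default_rng(1)
        eff = [StudyEffect(str(i), rng.normal(), rng.uniform(0.01, 0.2))
               for i in range(6)]
        tbl = forest_table(eff, dl_pool(eff))
        assert tbl.iloc[:-1]["weight_pct"].sum() == pytest.approx(100.0)

    def test_growing_gradient_inflates_heterogeneity(self):
        """A gradient that widens across rounds (the female pattern) yields
        far higher I-squared than a flat gradient (the male pattern)."""
        rng = np.random.default_rng(5)

        def rounds(grad_by_round):
            effects = []
            for i, g in enumerate(grad_by_round):
                sp = SexParams(base_logodds=-1.0, age_offsets=(0, 0, 0, 0),
                               edu_low=g, edu_secondary=g / 2)
                surf = PrevalenceSurface(male=sp, female=sp)
                d = SurveyDesign(f"R{i}", 2000 + i, (18, 79), 3000)
                rec = generate_survey(d, surf, int(rng.integers(2**31)))
                rec = harmonize_records(rec, SmokingDefinition("who_current"))
                effects.append(first_stage_fit(rec))
            return dl_pool(effects)

        flat = rounds(np.full(10, np.log(3.5)))
        growing = rounds(np.linspace(np.log(1.0), np.log(4.0), 10))
        assert growing.i2 > flat.i2
        assert growing.i2 > 0.5
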