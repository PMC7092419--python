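"""Counterfactual avoided-deaths model: lag profile, multipliers,
cell arithmetic and generator self-consistency."""

import numpy as np
import pandas as pd
import pytest

from smoketrends.attribution import (AttributionResult, HazardProfile,
                                     PrevalencePath, avoided_deaths,
                                     mortality_multiplier, residual_excess)
from smoketrends.errors import ConfigurationError, DataError
from smoketrends.survey_synth import (PrevalenceSurface, generate_mortality,
                                      path_from_surface)


class TestResidualExcess:
    @pytest.mark.parametrize("tau,expected", [
        (0.0, 1.0),       # full excess at quit
        (5.0, 0.3),       # ~70% of the excess gone after 5 years
        (2.5, 0.65),      # linear interpolation between the knots
        (10.0, 0.0),      # back to never-smoker risk
        (25.0, 0.0),
    ])
    def test_lag_profile(self, tau, expected):
        assert residual_excess(tau) == pytest.approx(expected, abs=1e-12)

    def test_negative_lag_rejected(self):
        with pytest.raises(ConfigurationError):
            residual_excess(-1.0)

    def test_profile_validation(self):
        with pytest.raises(ConfigurationError):
            HazardProfile(lag_knots=((0.0, 1.0), (5.0, 0.5), (10.0, 0.6)))
        with pytest.raises(ConfigurationError):
            HazardProfile(lag_knots=((0.0, 0.9), (10.0, 0.0)))
        with pytest.raises(ConfigurationError):
            HazardProfile(hr={"15-49": 0.8})


class TestMortalityMultiplier:
    def test_no_smoking_no_excess(self):
        assert mortality_multiplier(0.0, np.zeros(10), 2.0) == 1.0

    def test_current_only_and_attributable_fraction(self):
        m = mortality_multiplier(0.6, np.zeros(10), 2.0)
        assert m == pytest.approx(1.6)
        assert (m - 1) / m == pytest.approx(0.6 / 1.6)  # PAF = 0.375

    def test_former_contributes_residual_excess(self):
        former = np.zeros(10)
        former[5] = 0.1  # quit 5 years ago -> 30% residual excess
        assert mortality_multiplier(0.5, former, 2.0) == pytest.approx(1.53)

    def test_hr_below_one_rejected(self):
        with pytest.raises(ConfigurationError):
            mortality_multiplier(0.5, np.zeros(10), 0.9)


def one_cell_inputs(p_obs, p_cf, deaths=1000.0, year=2010, band="50-64"):
    path = lambda p: PrevalencePath(years=[year], age_bands=(band,),
                                    current=[[p]], former=np.zeros((1, 1, 10)))
    sched = pd.DataFrame([{"year": year, "sex": "male", "age_group": band,
                           "cause": "cvd", "deaths": deaths, "population": 1e6}])
    return sched, path(p_obs), path(p_cf)


class TestAvoidedDeaths:
    def test_hand_arithmetic_single_cell(self):
        sched, obs, cf = one_cell_inputs(0.5, 0.6)
        profile = HazardProfile(hr={"50-64": 2.0})
        res = avoided_deaths(sched, obs, cf, profile)
        # D0 = 1000/1.5; avoided = D0 * (1.6 - 1.5)
        assert res.total_avoided == pytest.approx(1000 / 1.5 * 0.1)

    def test_identical_paths_avoid_nothing(self):
        sched, obs, _ = one_cell_inputs(0.5, 0.6)
        res = avoided_deaths(sched, obs, obs, HazardProfile(hr={"50-64": 2.0}))
        assert res.total_avoided == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_prevalence_gap_and_hr(self):
        def total(p_cf, hr):
            sched, obs, cf = one_cell_inputs(0.4, p_cf)
            return avoided_deaths(sched, obs, cf,
                                  HazardProfile(hr={"50-64": hr})).total_avoided
        assert 0 < total(0.5, 2.0) < total(0.6, 2.0) < total(0.7, 2.0)
        assert total(0.6, 1.5) < total(0.6, 2.0) < total(0.6, 3.0)

    def test_grid_mismatch_rejected(self):
        sched, obs, _ = one_cell_inputs(0.5, 0.6)
        other = PrevalencePath(years=[2010], age_bands=("65+",),
                               current=[[0.5]], former=np.zeros((1, 1, 10)))
        with pytest.raises(DataError):
            avoided_deaths(sched, obs, other, HazardProfile())

    def test_band_refinement_invariance(self):
        """Splitting a band in two (same prevalence, HR, and half the deaths
        and population each) leaves total avoided deaths unchanged."""
        profile_a = HazardProfile(hr={"A": 2.0})
        profile_b = HazardProfile(hr={"A1": 2.0, "A2": 2.0})
        mk = lambda bands, p: PrevalencePath(
            years=[2010], age_bands=bands,
            current=np.full((1, len(bands)), p),
            former=np.zeros((1, len(bands), 10)))
        sched_a = pd.DataFrame([{"year": 2010, "sex": "male", "age_group": "A",
                                 "cause": "cvd", "deaths": 1000.0, "population": 1e6}])
        sched_b = pd.DataFrame([
            {"year": 2010, "sex": "male", "age_group": b, "cause": "cvd",
             "deaths": 500.0, "population": 5e5} for b in ("A1", "A2")])
        ra = avoided_deaths(sched_a, mk(("A",), 0.5), mk(("A",), 0.6), profile_a)
        rb = avoided_deaths(sched_b, mk(("A1", "A2"), 0.5),
                            mk(("A1", "A2"), 0.6), profile_b)
        assert ra.total_avoided == pytest.approx(rb.total_avoided, abs=1e-9)

    def test_generator_self_consistency(self):
        """On schedules built by the generator from a known declining path,
        avoided deaths recover the generator's built-in difference between
        counterfactual and observed expectations to < 0.1%."""
        surface = PrevalenceSurface.default()
        profile = HazardProfile()
        path = path_from_surface(surface, range(2007, 2017))
        cf = path.frozen(2007)
        rates = {"15-49": 0.001, "50-64": 0.008, "65+": 0.04}
        pops = {"15-49": 2e7, "50-64": 1e7, "65+": 5e6}
        sched_obs = generate_mortality(rates, path, profile, pops)
        sched_cf = generate_mortality(rates, cf, profile, pops)
        builtin = float(sched_cf["deaths"].sum() - sched_obs["deaths"].sum())
        res = avoided_deaths(sched_obs, path, cf, profile, base_year=2007)
        assert res.total_avoided == pytest.approx(builtin, rel=1e-3)
        # in the synthetic world the smoking decline is the only mortality
        # change, so it accounts for the whole observed reduction
        assert res.pct_of_observed_reduction == pytest.approx(100.0, rel=1e-6)

    def test_shares_are_valid_percentages(self):
        surface = PrevalenceSurface.default()
        profile = HazardProfile()
        path = path_from_surface(surface, range(2007, 2017))
        sched = generate_mortality({"15-49": 0.001, "50-64": 0.008, "65+": 0.04},
                                   path, profile,
                                   {"15-49": 2e7, "50-64": 1e7, "65+": 5e6})
        res = avoided_deaths(sched, path, path.frozen(2007), profile,
                             base_year=2007)
        for v in (res.share_under_65, res.pct_of_counterfactual_deaths,
                  res.pct_of_observed_deaths):
            assert 0.0 <= v <= 100.0
        assert res.cells["avoided"].sum() == pytest.approx(res.total_avoided)
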