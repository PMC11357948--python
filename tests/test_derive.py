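"""Derived variables: menarche imputation, MPH, BMI, SDS, milestone gains."""

import datetime as dt
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from qeps_puberty.derive import (
    AGE_ONLY_OFFSET,
    DAYS_PER_YEAR,
    MenarcheReport,
    SDSReference,
    adult_height,
    bmi_max,
    cohort_summary,
    compute_milestones,
    diffh_mph,
    impute_menarche_age,
    menarche_growth_vars,
    mph_sds,
    pubertal_gains,
    to_sds,
)
from qeps_puberty.model import QEPSParams, age_at_p_fraction, eval_velocity
from .conftest import random_params


class TestImputation:
    def test_age_only_adds_fixed_offset(self):
        rep = MenarcheReport("age_only", dt.date(1990, 3, 1), reported_age=13)
        assert impute_menarche_age(rep) == pytest.approx(13.193)
        assert AGE_ONLY_OFFSET == 0.193

    def test_year_month_uses_mid_month(self):
        rep = MenarcheReport("year_month", dt.date(1990, 3, 15), year=2003, month=5)
        expected = (dt.date(2003, 5, 15) - dt.date(1990, 3, 15)).days / DAYS_PER_YEAR
        age = impute_menarche_age(rep)
        assert age == pytest.approx(expected)
        assert round(age, 2) == 13.17

    def test_year_only_uses_mid_year(self):
        rep = MenarcheReport("year_only", dt.date(1990, 3, 15), year=2003)
        expected = (dt.date(2003, 7, 2) - dt.date(1990, 3, 15)).days / DAYS_PER_YEAR
        assert impute_menarche_age(rep) == pytest.approx(expected)

    def test_year_age_full_year_overlap_gives_midyear(self):
        # born on Jan 1: the 13th year of life covers exactly calendar 2003,
        # so the overlap midpoint is July 2 and the age about 13.5
        rep = MenarcheReport(
            "year_age", dt.date(1990, 1, 1), year=2003, reported_age=13
        )
        assert impute_menarche_age(rep) == pytest.approx(13.5, abs=0.01)

    def test_year_age_partial_overlap(self):
        # born mid-year: being 13 during 2003 is only possible Jul-Dec 2003
        rep = MenarcheReport(
            "year_age", dt.date(1990, 7, 1), year=2003, reported_age=13
        )
        age = impute_menarche_age(rep)
        lo = (dt.date(2003, 7, 1) - dt.date(1990, 7, 1)).days / DAYS_PER_YEAR
        hi = (dt.date(2004, 1, 1) - dt.date(1990, 7, 1)).days / DAYS_PER_YEAR
        assert lo < age < hi

    def test_year_before_birth_is_consistency_error(self):
        rep = MenarcheReport("year_only", dt.date(1990, 3, 15), year=1989)
        with pytest.raises(ValueError, match="precedes"):
            impute_menarche_age(rep)

    def test_out_of_range_imputed_age_rejected(self):
        rep = MenarcheReport("year_month", dt.date(1990, 3, 15), year=1993, month=5)
        with pytest.raises(ValueError, match="outside"):
            impute_menarche_age(rep)

    def test_modes_partition_every_valid_report(self):
        # every mode yields exactly one age for a consistent report
        birth = dt.date(1990, 6, 10)
        reports = [
            MenarcheReport("year_month", birth, year=2003, month=2),
            MenarcheReport("year_only", birth, year=2003),
            MenarcheReport("year_age", birth, year=2003, reported_age=12),
            MenarcheReport("age_only", birth, reported_age=12),
        ]
        ages = [impute_menarche_age(r) for r in reports]
        assert all(6 <= a <= 20 for a in ages)

    def test_report_field_validation(self):
        with pytest.raises(ValueError):
            MenarcheReport("year_month", dt.date(1990, 1, 1), year=2003)  # no month
        with pytest.raises(ValueError):
            MenarcheReport("nonsense", dt.date(1990, 1, 1), year=2003)
        with pytest.raises(ValueError):
            MenarcheReport("age_only", dt.date(1990, 1, 1), reported_age=25)


class TestParentalHeight:
    @pytest.mark.parametrize(
        "m, f, expected",
        [(1.0, 0.0, 0.5), (0.0, 0.0, 0.0), (-2.86, 2.64, -0.11)],
    )
    def test_mph_is_parental_mean(self, m, f, expected):
        assert mph_sds(m, f) == pytest.approx(expected)

    def test_missing_parent_propagates(self):
        assert np.isnan(mph_sds(float("nan"), 1.0))
        assert np.isnan(diffh_mph(0.5, float("nan")))

    @pytest.mark.parametrize("h, m, expected", [(0.5, 0.5, 0.0), (1.2, 0.5, 0.7)])
    def test_diffh_examples(self, h, m, expected):
        assert diffh_mph(h, m) == pytest.approx(expected)

    def test_diffh_matches_subtraction_oracle(self, rng):
        pairs = rng.normal(0, 1, (100, 2))
        for h, m in pairs:
            assert diffh_mph(h, m) == pytest.approx(h - m)


class TestBmiMax:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["age_years", "height_cm", "weight_kg"])

    def test_single_observation(self):
        df = self._frame([(5.0, 100.0, 16.0)])
        assert bmi_max(df) == pytest.approx(16.0)

    def test_window_is_inclusive_and_excludes_earlier(self):
        df = self._frame(
            [(3.4, 100.0, 19.0), (5.0, 100.0, 16.0), (6.0, 100.0, 17.0)]
        )
        assert bmi_max(df) == pytest.approx(17.0)
        # boundary ages belong to the window
        df2 = self._frame([(3.5, 100.0, 18.0), (7.0, 100.0, 12.0)])
        assert bmi_max(df2) == pytest.approx(18.0)

    def test_empty_window_gives_missing(self):
        df = self._frame([(2.0, 90.0, 14.0), (9.0, 130.0, 28.0)])
        assert np.isnan(bmi_max(df))

    def test_matches_brute_force_oracle(self, rng):
        ages = rng.uniform(0.5, 10.0, 40)
        heights = rng.uniform(80, 140, 40)
        weights = rng.uniform(10, 40, 40)
        df = self._frame(list(zip(ages, heights, weights)))
        mask = (ages >= 3.5) & (ages <= 7.0)
        oracle = np.max(weights[mask] / (heights[mask] / 100.0) ** 2)
        assert bmi_max(df) == pytest.approx(oracle)


class TestSds:
    @pytest.fixture
    def ref(self):
        return SDSReference(
            "height", ages=(0.0, 5.0, 10.0, 18.0),
            means=(50.0, 110.0, 140.0, 167.0), sds=(2.0, 4.5, 5.5, 6.2),
        )

    def test_mean_maps_to_zero_and_sd_to_one(self, ref):
        assert to_sds(110.0, 5.0, ref) == pytest.approx(0.0)
        assert to_sds(114.5, 5.0, ref) == pytest.approx(1.0)

    def test_interpolates_between_nodes(self, ref):
        assert to_sds(125.0, 7.5, ref) == pytest.approx(0.0)

    def test_refuses_extrapolation(self, ref):
        assert np.isnan(to_sds(170.0, 20.0, ref))

    def test_round_trip(self, ref):
        z = to_sds(118.0, 6.0, ref)
        mean = np.interp(6.0, ref.ages, ref.means)
        sd = np.interp(6.0, ref.ages, ref.sds)
        assert to_sds(mean + z * sd, 6.0, ref) == pytest.approx(z)

    def test_invalid_reference_rejected(self):
        with pytest.raises(ValueError):
            SDSReference("x", ages=(1.0, 1.0), means=(0, 0), sds=(1, 1))
        with pytest.raises(ValueError):
            SDSReference("x", ages=(1.0, 2.0), means=(0, 0), sds=(1, 0))


class TestAdultHeight:
    def test_model_estimate_when_taller(self):
        assert adult_height(168.0, [160.0, 167.2]) == pytest.approx(168.0)

    def test_measured_wins_when_it_exceeds_model(self):
        assert adult_height(168.0, [160.0, 168.9]) == pytest.approx(168.9)

    def test_matches_max_oracle(self, rng):
        for _ in range(50):
            tmax = rng.uniform(150, 185)
            measured = rng.uniform(140, 190, 10)
            assert adult_height(tmax, measured) == max(tmax, measured.max())


class TestGains:
    def test_pmax_zero(self, consts):
        p0 = QEPSParams(62, 98, 0.0, 1.0, 1.0, 12.0)
        g = pubertal_gains(p0, consts)
        assert g["ppubgain"] == pytest.approx(0.0, abs=1e-12)
        assert g["deltapubgain"] == pytest.approx(-g["qespubgain"])

    def test_additivity_identity_on_random_params(self, consts, rng):
        for params in random_params(rng, 1000):
            g = pubertal_gains(params, consts)
            assert g["tpubgain"] == pytest.approx(
                g["ppubgain"] + g["qespubgain"], abs=1e-9
            )

    def test_gains_match_velocity_quadrature(self, typical_params, consts):
        a5 = age_at_p_fraction(0.05, typical_params, consts)
        a100 = age_at_p_fraction(consts.pEnd, typical_params, consts)
        g = pubertal_gains(typical_params, consts)
        for comp, key in [("P", "ppubgain"), ("QES", "qespubgain"), ("T", "tpubgain")]:
            integral, _ = quad(
                lambda t: eval_velocity(float(t), typical_params, consts)[comp],
                a5, a100, limit=400,
            )
            assert integral == pytest.approx(g[key], abs=1e-3)

    def test_ppubgain_close_to_pmax(self, consts, rng):
        # with the 99.9% cutoff the P gain over the pubertal window captures
        # nearly the whole specific pubertal height gain
        for params in random_params(rng, 50):
            g = pubertal_gains(params, consts)
            assert g["ppubgain"] <= params.Pmax + 1e-12
            assert params.Pmax - g["ppubgain"] < 0.15 * params.Pmax + 1e-12


class TestMenarcheVars:
    def test_p_percent_at_landmarks(self, typical_params, consts):
        a50 = age_at_p_fraction(0.5, typical_params, consts)
        a95 = age_at_p_fraction(0.95, typical_params, consts)
        v50 = menarche_growth_vars(typical_params, consts, a50, 176.0)
        v95 = menarche_growth_vars(typical_params, consts, a95, 176.0)
        assert v50["p_percent_menarche"] == pytest.approx(50.0)
        assert v95["p_percent_menarche"] == pytest.approx(95.0)

    def test_postmenarcheal_gain_is_difference(self, typical_params, consts):
        v = menarche_growth_vars(typical_params, consts, 13.0, 170.0)
        assert v["postmenarcheal_gain"] == pytest.approx(170.0 - v["t_agemenarche"])

    def test_negative_gain_floored_with_warning(self, typical_params, consts):
        with pytest.warns(RuntimeWarning, match="floored"):
            v = menarche_growth_vars(typical_params, consts, 20.0, 100.0)
        assert v["postmenarcheal_gain"] == 0.0

    def test_missing_menarche_propagates(self, typical_params, consts):
        v = menarche_growth_vars(typical_params, consts, float("nan"), 170.0)
        assert all(np.isnan(x) for x in v.values())

    def test_p_percent_increases_with_menarche_age(self, typical_params, consts):
        ages = np.linspace(9.0, 16.0, 30)
        pcts = [
            menarche_growth_vars(typical_params, consts, a, 175.0)[
                "p_percent_menarche"
            ]
            for a in ages
        ]
        assert all(b > a for a, b in zip(pcts, pcts[1:]))


class TestMilestoneSet:
    def test_age_ordering(self, typical_params, consts):
        ms = compute_milestones(typical_params, consts, 13.0, [168.0])
        assert ms.ageP5 < ms.ageP50 < ms.ageP95 < ms.ageP99 < ms.ageP100
        assert ms.Tpubgain == pytest.approx(ms.Ppubgain + ms.QESpubgain, abs=1e-9)
        assert 0 <= ms.p_percent_menarche <= 100
        assert ms.postmenarcheal_gain >= 0

    def test_cohort_summary_counts_and_percentages(self):
        # 109 of 793 before midpuberty and 97 of 793 before the P velocity
        # peak reproduce the published 13.7% and 12.2%
        n = 793
        agep50 = np.full(n, 12.0)
        agep_phv = np.full(n, 11.9)
        menarche = np.full(n, 13.0)
        menarche[:109] = 11.95  # before AgeP50 only
        menarche[:97] = 11.5  # before both landmarks
        table = pd.DataFrame(
            {"age_menarche": menarche, "agep50": agep50, "agep_phv": agep_phv}
        )
        s = cohort_summary(table)
        assert s["n_menarche_before_agep50"] == 109
        assert round(s["pct_menarche_before_agep50"], 1) == 13.7
        assert s["n_menarche_before_agep_phv"] == 97
        assert round(s["pct_menarche_before_agep_phv"], 1) == 12.2
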