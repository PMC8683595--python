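"""Natural-history building blocks: incidence, growth, mortality, survival."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import norm

from densescreen import natural_history as nh
from densescreen.natural_history import LifeTable
from densescreen.params import GrowthParams, IncidenceParams, SelfDetectParams, SurvivalParams


class TestIncidence:
    def test_presence_fraction_matches_numerical_cdf_oracle(self):
        """f = L * P(onset > 20) / P(20 < onset <= 75), with the normal CDF
        evaluated by numerical integration of the density."""
        inc = IncidenceParams()

        def phi(z):  # independent CDF evaluation
            return 0.5 + quad(norm.pdf, 0, z)[0] * np.sign(z) if z >= 0 else 1 - phi(-z)

        z20 = (20 - 67.9) / 21.1
        z75 = (75 - 67.9) / 21.1
        expected = 0.202 * (1 - phi(z20)) / (phi(z75) - phi(z20))
        assert nh.presence_fraction(inc, "d") == pytest.approx(expected, rel=1e-10)

    def test_cumulative_incidence_to_horizon_equals_lifetime_risk(self, rng):
        """Monte-Carlo cumulative incidence to age 75 equals the configured
        lifetime risk within 3 binomial SEs at n = 1e5 (both categories)."""
        inc = IncidenceParams()
        n = 100_000
        for cat, risk in (("c", 0.155), ("d", 0.202)):
            f = nh.presence_fraction(inc, cat)
            has = rng.random(n) < f
            onset = nh.onset_age_from_uniform(inc, rng.random(n))
            frac = np.mean(has & (onset <= 75.0))
            se = np.sqrt(risk * (1 - risk) / n)
            assert abs(frac - risk) < 3 * se

    def test_zero_risk_never_produces_tumor(self, rng):
        inc = IncidenceParams(lifetime_risk={"c": 0.0, "d": 0.202})
        assert all(nh.sample_tumor(inc, "c", rng) is None for _ in range(200))

    def test_onset_respects_truncation_bound(self, rng):
        inc = IncidenceParams()
        ages = nh.onset_age_from_uniform(inc, rng.random(10_000))
        assert np.all(ages >= inc.min_onset_age)

    def test_unknown_category_raises(self, rng):
        with pytest.raises(KeyError):
            nh.sample_tumor(IncidenceParams(), "x", rng)

    def test_unattainable_risk_raises(self):
        inc = IncidenceParams(lifetime_risk={"c": 0.80, "d": 0.202})
        with pytest.raises(ValueError):
            nh.presence_fraction(inc, "c")


class TestGrowth:
    def test_diameter_at_onset_is_d0(self):
        g = GrowthParams()
        assert nh.diameter_at_age(60.0, 157.0, 60.0, g) == pytest.approx(0.1)

    def test_three_tvdt_doubles_diameter(self):
        g = GrowthParams()
        dt_years = 3 * 157.0 / nh.DAYS_PER_YEAR
        d = nh.diameter_at_age(60.0, 157.0, 60.0 + dt_years, g)
        assert d == pytest.approx(0.2, rel=1e-12)

    @given(
        tvdt=st.floats(40.0, 400.0),
        t=st.floats(0.0, 15.0),
        onset=st.floats(25.0, 80.0),
    )
    def test_doubling_law_exact_below_cap(self, tvdt, t, onset):
        """d(t + 3 TVDT) / d(t) == 2 exactly wherever the cap is not hit."""
        g = GrowthParams()
        step = 3 * tvdt / nh.DAYS_PER_YEAR
        d1 = nh.diameter_at_age(onset, tvdt, onset + t, g)
        d2 = nh.diameter_at_age(onset, tvdt, onset + t + step, g)
        if d2 < g.max_diameter:
            assert d2 / d1 == pytest.approx(2.0, rel=1e-9)

    def test_growth_inversion_against_brentq_oracle(self):
        """Time to reach 18.17 mm from 0.1 mm at TVDT 157 d is ~3536 days;
        cross-check the closed form against numeric root finding."""
        g = GrowthParams()
        target = 18.17
        age = nh.age_at_diameter(60.0, 157.0, target, g)
        dt_days = (age - 60.0) * nh.DAYS_PER_YEAR
        assert dt_days == pytest.approx(3 * 157 * np.log2(target / 0.1), rel=1e-9)
        assert dt_days == pytest.approx(3536, abs=5)
        root = brentq(
            lambda t: nh.diameter_at_age(60.0, 157.0, 60.0 + t, g) - target, 0, 40
        )
        assert age - 60.0 == pytest.approx(root, abs=1e-6)

    def test_age_before_onset_raises(self):
        with pytest.raises(ValueError):
            nh.diameter_at_age(60.0, 157.0, 59.0, GrowthParams())

    def test_cap_never_reached_gives_inf(self):
        g = GrowthParams()
        assert nh.age_at_diameter(60.0, 157.0, g.max_diameter, g) == np.inf

    def test_tvdt_moment_matching(self, rng):
        z = rng.standard_normal(200_000)
        x = nh.lognormal_from_mean_sd(157.0, 25.0, z)
        assert np.mean(x) == pytest.approx(157.0, rel=0.01)
        assert np.std(x) == pytest.approx(25.0, rel=0.03)

    def test_piecewise_rule_continuous_and_consistent(self, rng):
        """Piecewise growth is continuous at the age-group boundaries and
        reduces to the single-TVDT law when all groups share one TVDT."""
        g = GrowthParams(tvdt_rule="piecewise")
        z = rng.standard_normal(50)
        onset = np.full(50, 45.0)
        tvdt = nh.sample_tvdt(onset, z, g)
        eps = 1e-6
        for b in (50.0, 70.0):
            lo = nh.diameter_at_age(onset, tvdt, b - eps, g, check=False)
            hi = nh.diameter_at_age(onset, tvdt, b + eps, g, check=False)
            np.testing.assert_allclose(lo, hi, rtol=1e-4)
        # degenerate: identical TVDT in all groups == onset rule
        g_eq = GrowthParams(
            tvdt_mean_days=[157.0] * 3, tvdt_sd_days=[25.0] * 3, tvdt_rule="piecewise"
        )
        g_on = GrowthParams(
            tvdt_mean_days=[157.0] * 3, tvdt_sd_days=[25.0] * 3, tvdt_rule="onset"
        )
        tv_eq = nh.sample_tvdt(onset, z, g_eq)
        tv_on = nh.sample_tvdt(onset, z, g_on)
        d_eq = nh.diameter_at_age(onset, tv_eq, 72.0, g_eq)
        d_on = nh.diameter_at_age(onset, tv_on, 72.0, g_on)
        np.testing.assert_allclose(d_eq, d_on, rtol=1e-9)

    def test_piecewise_inversion_roundtrip(self, rng):
        g = GrowthParams(tvdt_rule="piecewise")
        onset = np.array([45.0, 55.0, 68.0, 72.0])
        tvdt = nh.sample_tvdt(onset, rng.standard_normal(4), g)
        target = np.array([5.0, 18.0, 40.0, 90.0])
        age = nh.age_at_diameter(onset, tvdt, target, g)
        d = nh.diameter_at_age(onset, tvdt, age, g, check=False)
        np.testing.assert_allclose(d, target, rtol=1e-6)


class TestSelfDetection:
    def test_threshold_median_is_exp_log_mean(self, rng):
        """Simulated median self-detection diameter ~ e^2.9 = 18.17 mm."""
        z = rng.standard_normal(100_000)
        d = nh.sample_self_detection_diameter(SelfDetectParams(), z)
        assert np.median(d) == pytest.approx(np.exp(2.9), rel=0.01)

    def test_threshold_at_onset_diameter_detects_at_onset(self):
        g = GrowthParams()
        assert nh.self_detection_age(60.0, 157.0, g.onset_diameter, g) == pytest.approx(60.0)

    @given(st.floats(1.0, 100.0), st.floats(1.05, 1.5))
    def test_larger_threshold_detects_strictly_later(self, thresh, factor):
        g = GrowthParams()
        if thresh * factor >= g.max_diameter:
            return
        a1 = nh.self_detection_age(60.0, 157.0, thresh, g)
        a2 = nh.self_detection_age(60.0, 157.0, thresh * factor, g)
        assert a2 > a1

    def test_smaller_tvdt_detects_earlier(self):
        g = GrowthParams()
        ages = [nh.self_detection_age(60.0, tv, 18.0, g) for tv in (80.0, 157.0, 188.0)]
        assert ages == sorted(ages)


class TestLifeTable:
    def test_everyone_dies_at_max_age_when_hazard_zero(self, rng):
        lt = LifeTable(np.array([0.0] * 10 + [1.0]))
        assert nh.sample_other_cause_death_age(lt, rng, 0) == 10
        years = lt.death_years_from_uniform(0, rng.random(100))
        assert np.all(years == 10)

    def test_certain_death_in_first_year(self, rng):
        lt = LifeTable(np.ones(11))
        assert nh.sample_other_cause_death_age(lt, rng, 3) == 3

    def test_sampler_mean_matches_life_expectancy_integral(self, life_table, rng):
        """Mean sampled death age (mid-year) equals the deterministic
        expectation of the same q(a) sequence within Monte-Carlo error."""
        years = life_table.death_years_from_uniform(50, rng.random(100_000))
        expected = life_table.expected_death_age(50)
        assert np.mean(years + 0.5) == pytest.approx(expected, abs=0.12)

    def test_sampler_reproduces_survival_curve(self, life_table, rng):
        """Kolmogorov distance between empirical and exact death-year CDF
        shrinks to sampling noise at n = 1e5."""
        n = 100_000
        years = life_table.death_years_from_uniform(50, rng.random(n))
        cdf = life_table.death_year_cdf(50)
        ages = np.arange(50, 50 + len(cdf))
        emp = np.searchsorted(np.sort(years), ages, side="right") / n
        assert np.max(np.abs(emp - cdf)) < 1.63 / np.sqrt(n) * 3

    def test_csv_roundtrip(self, life_table, tmp_path):
        path = tmp_path / "lt.csv"
        life_table.to_csv(path)
        back = LifeTable.from_csv(path)
        np.testing.assert_allclose(back.q, life_table.q)

    @pytest.mark.parametrize(
        "q",
        [np.array([0.1]), np.array([0.1, 0.5]), np.array([0.1, 1.5, 1.0]),
         np.array([-0.1, 1.0])],
    )
    def test_malformed_tables_rejected(self, q):
        with pytest.raises(ValueError):
            LifeTable(q)

    def test_noncontiguous_ages_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("age,q\n0,0.1\n2,1.0\n")
        with pytest.raises(ValueError):
            LifeTable.from_csv(path)


class TestSurvival:
    def test_size_class_boundaries(self):
        sp = SurvivalParams()
        assert list(nh.size_class(np.array([5.0, 19.9, 20.0, 50.0, 50.1]), sp)) == [
            0, 0, 1, 1, 2,
        ]

    def test_zero_death_probability_always_cured(self, rng):
        sp = SurvivalParams(death_prob=[0.0, 0.0, 0.0])
        assert all(
            nh.breast_cancer_outcome(sp, 10.0, 60.0, rng) is None for _ in range(300)
        )

    def test_certain_immediate_death_at_detection_age(self, rng):
        sp = SurvivalParams(death_prob=[1.0, 1.0, 1.0], mean_years=[1e-9] * 3)
        age = nh.breast_cancer_outcome(sp, 30.0, 60.0, rng)
        assert age == pytest.approx(60.0, abs=1e-6)

    def test_empirical_death_fraction_matches_probability(self, rng):
        """Per-class death frequency over 1e5 draws equals the configured
        probability within 3 binomial SEs."""
        sp = SurvivalParams(death_prob=[0.3, 0.6, 0.9])
        n = 100_000
        for cls, diam in ((0, 10.0), (1, 30.0), (2, 60.0)):
            dies, _ = nh.bc_death_from_uniforms(
                sp, np.full(n, diam), np.full(n, 60.0), rng.random(n), rng.random(n)
            )
            p = sp.death_prob[cls]
            assert abs(np.mean(dies) - p) < 3 * np.sqrt(p * (1 - p) / n)
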