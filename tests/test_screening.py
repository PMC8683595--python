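"""Scenario grammar and the screening engine."""

import math

import numpy as np
import pytest

from densescreen import economics
from densescreen import screening as scr
from densescreen.params import MammographyParams, ParameterSet
from densescreen.screening import Block, Scenario, build_schedule
from densescreen.synthetic_data import generate_cohort, generate_life_table


@pytest.fixture(scope="module")
def tumor_free_cohort(life_table):
    p = ParameterSet()
    p.incidence.lifetime_risk = {"c": 0.0, "d": 0.0}
    return generate_cohort(4_000, 7, p, life_table), p


class TestMammographySensitivity:
    def test_matches_independent_logistic_evaluation(self):
        p = MammographyParams()
        d, m = 10.0, 0.40
        x = p.beta0 + p.beta1 * d + p.beta2 * m + p.beta3 * m / d**2
        expected = (1 - p.systematic_error) / (1 + math.exp(-x))
        assert scr.mammography_sensitivity(d, m, p) == pytest.approx(expected, rel=1e-12)

    def test_systematic_error_caps_sensitivity(self):
        p = MammographyParams()
        assert scr.mammography_sensitivity(1e4, 0.0, p) == pytest.approx(0.90, abs=1e-9)

    def test_full_systematic_error_blinds_the_test(self):
        p = MammographyParams(systematic_error=1.0)
        assert scr.mammography_sensitivity(15.0, 0.2, p) == 0.0

    def test_density_reduces_sensitivity(self):
        p = MammographyParams()
        assert scr.mammography_sensitivity(10.0, 0.83, p) < scr.mammography_sensitivity(
            10.0, 0.06, p
        )

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            scr.mammography_sensitivity(0.0, 0.4, MammographyParams())


class TestScheduleGrammar:
    def test_biennial_mammography_has_13_rounds(self, presets):
        sched = build_schedule(presets["reference"], "c")
        assert [a for a, _ in sched] == list(range(50, 75, 2))
        assert {m for _, m in sched} == {"mammography"}

    def test_strategy_a_dense_stratum_switches_modalities(self, presets):
        sched = build_schedule(presets["A"], "d")
        assert len(sched) == 13
        assert sched[:8] == [(a, "ap_mri") for a in range(50, 65, 2)]
        assert sched[8:] == [(a, "mammography") for a in range(66, 75, 2)]

    def test_combined_strategy_interleaves(self, presets):
        sched = build_schedule(presets["H"], "d")
        assert len(sched) == 13 + 6
        assert (51, "ap_mri") in sched and (50, "mammography") in sched

    def test_interval_variants(self, presets):
        assert [a for a, _ in build_schedule(presets["A-3"], "d")] == [
            50, 53, 56, 59, 62, 65, 66, 69, 72,
        ]
        assert [a for a, _ in build_schedule(presets["F-4"], "c")] == [
            50, 54, 58, 62, 66, 70, 74,
        ]

    def test_empty_block_list_gives_empty_schedule(self):
        assert build_schedule(Scenario("x", {"c": [], "d": []}), "c") == []

    def test_overlapping_same_modality_blocks_rejected(self):
        s = Scenario(
            "bad",
            {"c": [Block(50, 60, 2, "mammography"), Block(58, 70, 2, "mammography")],
             "d": []},
        )
        with pytest.raises(ValueError):
            build_schedule(s, "c")

    def test_same_age_dual_modality_rejected(self):
        s = Scenario(
            "bad",
            {"c": [Block(50, 74, 2, "mammography"), Block(50, 70, 2, "ap_mri")],
             "d": []},
        )
        with pytest.raises(ValueError):
            build_schedule(s, "c")


class TestEngine:
    def test_zero_participation_means_no_screening(self, small_cohort, params, presets):
        s = Scenario("noshow", presets["reference"].blocks, participation=0.0)
        out = scr.simulate_scenario(small_cohort, s, params)
        assert out.n_attended.sum() == 0
        assert out.fp_count.sum() == 0
        assert out.dose_mgy.sum() == 0
        assert not out.induced.any()
        assert set(np.unique(out.mode)) <= {0, 2}  # only self-detection

    def test_false_positive_rate_matches_one_minus_specificity(self, tumor_free_cohort, presets):
        """Among attended rounds of tumour-free women the per-round FP rate
        is 1 - specificity: 0.11 mammography, 0.13 AP-MRI (3 MC SEs)."""
        cohort, p = tumor_free_cohort
        for name, rate in (("reference", 0.11), ("F", 0.13)):
            out = scr.simulate_scenario(cohort, presets[name], p)
            rounds = out.n_attended.sum()
            fp = out.fp_count.sum()
            se = np.sqrt(rate * (1 - rate) / rounds)
            assert abs(fp / rounds - rate) < 3 * se, name

    def test_expected_fp_count_for_full_attendance(self, tumor_free_cohort, presets):
        """A tumour-free woman attending all 13 mammography rounds expects
        13 x 0.11 = 1.43 false positives."""
        cohort, p = tumor_free_cohort
        p_full = p.copy()
        p_full.policy.participation = 1.0
        out = scr.simulate_scenario(cohort, presets["reference"], p_full)
        survivors = cohort.oc_death_age > 74.0  # attended all 13 rounds
        mean_fp = out.fp_count[survivors].mean()
        se = np.sqrt(13 * 0.11 * 0.89 / survivors.sum())
        assert abs(mean_fp - 1.43) < 3 * se

    def test_mri_only_strategy_has_no_dose_and_no_induction(self, small_cohort, params, presets):
        out = scr.simulate_scenario(small_cohort, presets["F"], params)
        assert np.all(out.dose_mgy == 0.0)
        assert not out.induced.any()

    def test_screen_detection_monotone_in_sensitivity(self, small_cohort, params, presets):
        """With common random numbers, raising AP-MRI sensitivity never
        loses a screen detection."""
        lo = params.with_value("ap_mri.sensitivity", 0.6)
        hi = params.with_value("ap_mri.sensitivity", 0.95)
        out_lo = scr.simulate_scenario(small_cohort, presets["F"], lo)
        out_hi = scr.simulate_scenario(small_cohort, presets["F"], hi)
        assert ((out_hi.mode == 1) & (out_lo.mode == 1)).sum() == (out_lo.mode == 1).sum()
        assert (out_hi.mode == 1).sum() >= (out_lo.mode == 1).sum()

    def test_screening_finds_tumors_earlier_than_self_detection(
        self, small_cohort, params, presets
    ):
        out = scr.simulate_scenario(small_cohort, presets["reference"], params)
        d_screen = out.det_diam[out.mode == 1]
        d_self = out.det_diam[out.mode == 2]
        assert d_screen.mean() < d_self.mean()

    def test_engine_is_deterministic(self, small_cohort, params, presets):
        a = scr.simulate_scenario(small_cohort, presets["A"], params)
        b = scr.simulate_scenario(small_cohort, presets["A"], params)
        np.testing.assert_array_equal(a.mode, b.mode)
        np.testing.assert_array_equal(a.det_age, b.det_age)
        np.testing.assert_array_equal(a.fp_count, b.fp_count)
        np.testing.assert_allclose(a.disc_screen_cost, b.disc_screen_cost)

    def test_detection_stops_screening(self, small_cohort, params, presets):
        out = scr.simulate_scenario(small_cohort, presets["reference"], params, collect_records=True)
        detected_at_round = out.result_codes == scr.RES_TP
        assert detected_at_round.sum(axis=1).max() <= 1  # at most one TP per woman

    def test_attendance_mode_per_woman(self, small_cohort, params, presets):
        p = params.copy()
        p.policy.attendance_mode = "per_woman"
        out = scr.simulate_scenario(small_cohort, presets["reference"], p)
        attenders = (out.n_attended > 0).mean()
        assert abs(attenders - 0.80) < 0.03  # never-attenders sit at ~20%

    def test_dynamic_stratum_assignment_runs(self, small_cohort, params, presets):
        p = params.copy()
        p.policy.stratum_assignment = "dynamic"
        out = scr.simulate_scenario(small_cohort, presets["A"], p)
        assert out.mode.shape == (small_cohort.n,)


class TestPerWomanAccounting:
    def test_history_costs_agree_with_engine(self, params, life_table, presets):
        """Dual route: per-woman event-log cost accumulation equals the
        engine's vectorised discounted cost."""
        cohort = generate_cohort(300, 99, params, life_table)
        out = scr.simulate_scenario(cohort, presets["A"], params, collect_records=True)
        life = economics.resolve_outcomes(cohort, out, params)
        for i in range(cohort.n):
            hist = scr.extract_history(cohort, out, i)
            got = economics.accumulate_costs(
                hist, params.costs, params.discount, params.survival,
                mammography_cost=params.mammography.cost,
                ap_mri_cost=params.ap_mri.cost,
                ap_mri_extra=params.ap_mri.extra_cost,
            )
            assert got == pytest.approx(life.disc_cost[i], rel=1e-9, abs=1e-9)
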