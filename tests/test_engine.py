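"""Cohort engine: transition dynamics vs matrix oracles, conservation, summaries."""

import numpy as np
import pytest

from activecea import state_space as ss
from activecea.config import InterventionSpec
from activecea.engine import N_CYCLES, run_cohort, summarise
from activecea.sampling import make_parameter_draw, simulation_rng

from conftest import constant_draw, single_person_inputs

EMPTY = frozenset()
DM = frozenset({"DM"})
SPEC5 = InterventionSpec(duration_years=5)


class TestToyChainOracle:
    """Collapsed 3-state chain (healthy, one disease, dead) vs explicit
    transition-matrix powers."""

    P_INC, P_DIE0, P_DIE1 = 0.1, 0.05, 0.15

    def matrix(self):
        return np.array(
            [
                [
                    (1 - self.P_DIE0) * (1 - self.P_INC),
                    (1 - self.P_DIE0) * self.P_INC,
                    self.P_DIE0,
                ],
                [0.0, 1 - self.P_DIE1, self.P_DIE1],
                [0.0, 0.0, 1.0],
            ]
        )

    def test_occupancies_match_matrix_powers(self, default_inputs):
        inputs = single_person_inputs(default_inputs, age=30)
        draw = constant_draw(
            incidence={(EMPTY, "DM"): self.P_INC},
            death={EMPTY: self.P_DIE0, DM: self.P_DIE1},
        )
        trace = run_cohort(inputs, draw, "standard_care", SPEC5)
        M = self.matrix()
        v = np.array([1.0, 0.0, 0.0])
        healthy = trace.occupancy[:, :, :, [0, 1]].sum(axis=(0, 2, 3))
        diseased_states = [
            ss.STATE_INDEX[ss.HealthState(DM, False)],
            ss.STATE_INDEX[ss.HealthState(DM, True)],
        ]
        diseased = trace.occupancy[:, :, :, diseased_states].sum(axis=(0, 2, 3))
        dead = trace.dead.sum(axis=0)
        for t in range(N_CYCLES + 1):
            expected = v @ np.linalg.matrix_power(M, t)
            assert healthy[t] == pytest.approx(expected[0], abs=1e-12)
            assert diseased[t] == pytest.approx(expected[1], abs=1e-12)
            assert dead[t] == pytest.approx(expected[2], abs=1e-12)
        # no other state is ever occupied
        others = [
            i
            for i, s in enumerate(ss.ALIVE_STATES)
            if s.combo not in (EMPTY, DM)
        ]
        assert trace.occupancy[:, :, :, others].sum() == 0.0


class TestStepDynamics:
    def test_zero_probabilities_only_age(self, default_inputs):
        inputs = single_person_inputs(default_inputs, age=40)
        trace = run_cohort(inputs, constant_draw(), "standard_care", SPEC5)
        for t in range(5):
            # mass stays 1 in the healthy state, advancing one age per cycle
            assert trace.occupancy[0, t, 10 + t, 0] == 1.0
            assert trace.occupancy[0, t].sum() == 1.0

    def test_certain_death_absorbs_in_one_cycle(self, default_inputs):
        trace = run_cohort(
            default_inputs, constant_draw(death=1.0), "standard_care", SPEC5
        )
        assert trace.occupancy[:, 1:].sum() == 0.0
        assert trace.dead[:, 1].sum() == pytest.approx(trace.entrants)

    def test_mass_conserved_and_everyone_exits(self, default_inputs):
        draw = make_parameter_draw(default_inputs, simulation_rng(3, 0))
        trace = run_cohort(default_inputs, draw, "standard_care", SPEC5)
        trace.check_conservation()
        alive = trace.alive_mass().sum(axis=0)
        assert np.all(np.diff(alive) <= 1e-9)  # no births
        # horizon: everyone dead or exited at age 100 by the last cycle
        final = trace.occupancy[:, -1]
        assert final[:, :-1, :].sum() == pytest.approx(0.0, abs=1e-9)
        assert trace.dead[:, -1].sum() + trace.exited[:, -1].sum() + final.sum() == (
            pytest.approx(trace.entrants)
        )

    def test_higher_mortality_weakly_reduces_life_years(self, default_inputs):
        lo = constant_draw(death=0.02)
        hi = constant_draw(death=0.04)
        t_lo = run_cohort(default_inputs, lo, "standard_care", SPEC5)
        t_hi = run_cohort(default_inputs, hi, "standard_care", SPEC5)
        s_lo = summarise(t_lo, lo, SPEC5, "standard_care", default_inputs)
        s_hi = summarise(t_hi, hi, SPEC5, "standard_care", default_inputs)
        assert s_hi.total_life_years < s_lo.total_life_years

    def test_excess_competing_risks_renormalised_with_warning(
        self, default_inputs, caplog
    ):
        import logging

        draw = constant_draw(incidence=0.3, death=0.0)  # healthy: 4 x 0.3 > 1
        with caplog.at_level(logging.WARNING, logger="activecea.engine"):
            trace = run_cohort(default_inputs, draw, "standard_care", SPEC5)
        assert any("renormalising" in r.message for r in caplog.records)
        trace.check_conservation()


class TestDepressionRepartition:
    def test_prevalence_split_each_cycle(self, default_inputs):
        draw = constant_draw(depression=0.25)
        trace = run_cohort(default_inputs, draw, "standard_care", SPEC5)
        occ = trace.occupancy
        # cycle 0: entrants are not depressed
        assert occ[:, 0, :, 1::2].sum() == 0.0
        for t in (1, 10, 30):
            alive = occ[:, t].sum()
            dep = occ[:, t, :, 1::2].sum()
            assert dep / alive == pytest.approx(0.25, abs=1e-12)


class TestSummaries:
    def test_qalys_equal_discounted_life_years_at_unit_utility(self, default_inputs):
        draw = constant_draw(death=0.03, utility=1.0)
        trace = run_cohort(default_inputs, draw, "standard_care", SPEC5)
        s0 = summarise(
            trace, draw, SPEC5, "standard_care", default_inputs, discount_rate_qalys=0.0
        )
        assert s0.qalys_discounted == pytest.approx(s0.total_life_years, rel=1e-12)

    def test_qaly_is_utility_times_life_years_at_constant_utility(self, default_inputs):
        draw = constant_draw(death=0.03, utility=0.8)
        trace = run_cohort(default_inputs, draw, "standard_care", SPEC5)
        s = summarise(
            trace, draw, SPEC5, "standard_care", default_inputs, discount_rate_qalys=0.0
        )
        assert s.qalys_discounted == pytest.approx(0.8 * s.total_life_years, rel=1e-12)

    def test_hcc_and_discounting_match_hand_computed_present_value(self, default_inputs):
        # one person, no death: cost 100/year; survival certain, so the
        # half-cycle-corrected occupancy is 1 every cycle until age-100 exit
        inputs = single_person_inputs(default_inputs, age=30)
        draw = constant_draw(cost=100.0, utility=0.8)
        trace = run_cohort(inputs, draw, "standard_care", SPEC5)
        s = summarise(
            trace, draw, SPEC5, "standard_care", inputs, discount_rate_costs=0.035
        )
        expected = 1000.0 * sum(100.0 * 1.035**-t for t in range(70))
        assert s.cost_utilisation == pytest.approx(expected, rel=1e-12)

    def test_hcc_discounted_cost_with_mortality_vs_spreadsheet_oracle(
        self, default_inputs
    ):
        # death probability 0.5: occupancy halves each cycle; present value of
        # a 100/year stream over half-cycle-corrected occupancy, spreadsheet style
        inputs = single_person_inputs(default_inputs, age=30)
        draw = constant_draw(death=0.5, cost=100.0)
        trace = run_cohort(inputs, draw, "standard_care", SPEC5)
        s = summarise(
            trace, draw, SPEC5, "standard_care", inputs, discount_rate_costs=0.035
        )
        occ = [0.5**t for t in range(71)]
        expected = 1000.0 * sum(
            100.0 * 0.5 * (occ[t] + occ[t + 1]) * 1.035**-t for t in range(70)
        )
        assert s.cost_utilisation == pytest.approx(expected, rel=1e-12)

    def test_life_year_classes_sum_to_total(self, default_inputs):
        draw = make_parameter_draw(default_inputs, simulation_rng(3, 1))
        trace = run_cohort(default_inputs, draw, "standard_care", SPEC5)
        s = summarise(trace, draw, SPEC5, "standard_care", default_inputs)
        parts = (
            s.life_years_disease_free
            + s.life_years_single
            + s.life_years_dual
            + s.life_years_triple
            + s.life_years_quadruple
        )
        assert parts == pytest.approx(s.total_life_years, rel=1e-12)
        assert s.life_years_depressed < s.total_life_years


class TestIntervention:
    def test_null_or_gives_identical_traces(self, default_inputs):
        draw = make_parameter_draw(default_inputs, simulation_rng(3, 2))
        draw.or_draw = 1.0
        t_i = run_cohort(default_inputs, draw, "intervention", SPEC5)
        t_c = run_cohort(default_inputs, draw, "standard_care", SPEC5)
        assert np.array_equal(t_i.occupancy, t_c.occupancy)
        assert np.array_equal(t_i.dead, t_c.dead)

    def test_duration_zero_has_no_intervention_costs(self, default_inputs):
        spec0 = InterventionSpec(duration_years=0)
        draw = make_parameter_draw(default_inputs, simulation_rng(3, 2))
        trace = run_cohort(default_inputs, draw, "intervention", spec0)
        s = summarise(trace, draw, spec0, "intervention", default_inputs)
        assert s.cost_intervention_total == 0.0

    def test_intervention_reduces_incidence_during_duration(self, default_inputs):
        draw = make_parameter_draw(default_inputs, simulation_rng(3, 2))
        draw.or_draw = 1.42
        t_i = run_cohort(default_inputs, draw, "intervention", SPEC5)
        t_c = run_cohort(default_inputs, draw, "standard_care", SPEC5)
        healthy_i = t_i.occupancy[:, 1:6, :, [0, 1]].sum()
        healthy_c = t_c.occupancy[:, 1:6, :, [0, 1]].sum()
        assert healthy_i > healthy_c

    def test_rejects_unknown_scenario(self, default_inputs):
        draw = constant_draw()
        with pytest.raises(ValueError, match="scenario"):
            run_cohort(default_inputs, draw, "placebo", SPEC5)
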