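import numpy as np
import pytest

import prediasim as ps
from prediasim.transitions import HealthState


def certain_death_table():
    return ps.LifeTable(ages=np.arange(0, 121),
                        qx=np.ones(121))


def immortal_table():
    qx = np.zeros(121)
    qx[-1] = 1.0
    return ps.LifeTable(ages=np.arange(0, 121), qx=qx)


def no_disease(params):
    """All disease flows switched off."""
    p = params.copy()
    p.epi.p_npg_to_igt = 0.0
    p.epi.p_igt_to_npg = 0.0
    p.epi.p_igt_to_dm2_by_band = [(0, None, 0.0)]
    p.epi.p_dm2_to_cvd_anchors = [(0, 51, 0.0), (76, None, 0.0)]
    return p.validate()


class TestSimulateIndividual:
    def test_immediate_death_half_life_year(self, params):
        p = no_disease(params)
        person = ps.Individual(id=0, current_age=45)
        out = ps.simulate_individual(person, p, certain_death_table(),
                                     np.random.default_rng(0))
        assert out.acc_ly_undiscounted == 0.5
        assert out.death_cycle == 1
        assert not out.alive

    def test_degenerate_stay_accrues_flat_utility(self, params):
        p = no_disease(params)
        p.settings.discount_rate_effects = 0.0
        p.utilities.age_decrement_per_year = 0.0
        person = ps.Individual(id=0, current_age=45, state=HealthState.IGT)
        out = ps.simulate_individual(person, p, immortal_table(),
                                     np.random.default_rng(0))
        assert out.acc_ly_undiscounted == 30
        assert out.acc_qaly_discounted == pytest.approx(30 * 0.931)

    def test_two_cycle_geometric_discounting(self, params):
        p = no_disease(params)
        p.settings.horizon_mode = "lifetime"
        p.settings.max_age = 46  # entry 45 -> exactly two cycles
        p.utilities.u_igt_at45 = 1.0
        p.utilities.age_decrement_per_year = 0.0
        p.validate()
        person = ps.Individual(id=0, current_age=45, state=HealthState.IGT)
        out = ps.simulate_individual(person, p, immortal_table(),
                                     np.random.default_rng(0))
        assert out.acc_qaly_discounted == pytest.approx(
            1 / 1.03 + 1 / 1.03 ** 2, abs=1e-12)

    def test_onset_cycles_ordered(self, params, lifetable):
        rng_seed = 0
        for i in range(200):
            person = ps.Individual(id=i, current_age=60)
            out = ps.simulate_individual(
                person, params, lifetable,
                np.random.default_rng((rng_seed, i)))
            if out.cvd_onset_cycle is not None:
                assert out.dm2_onset_cycle <= out.cvd_onset_cycle
            if out.death_cycle is not None and out.cvd_onset_cycle:
                assert out.cvd_onset_cycle <= out.death_cycle


class TestSimulateArm:
    def test_same_seed_identical(self, params, lifetable):
        p = params.copy()
        p.settings.cohort_size = 300
        a = ps.simulate_arm("control", p, lifetable, seed=11)
        b = ps.simulate_arm("control", p, lifetable, seed=11)
        assert a == b

    def test_empty_cohort_rejected(self, params, lifetable):
        with pytest.raises(ValueError):
            ps.simulate_arm("control", params, lifetable, seed=1, cohort=[])

    def test_qaly_bounded_by_ly(self, params, lifetable):
        p = params.copy()
        p.settings.cohort_size = 500
        for arm in ("control", "intervention"):
            res = ps.simulate_arm(arm, p, lifetable, seed=5)
            assert res.mean_qaly <= res.mean_ly


class TestRunBaseCase:
    def test_incrementals_exact(self, params, lifetable):
        p = params.copy()
        p.settings.cohort_size = 400
        run = ps.run_base_case(p, lifetable, seed=7)
        assert run.incr_qaly == (run.intervention.mean_qaly
                                 - run.control.mean_qaly)
        assert run.incr_cost == (run.intervention.mean_cost
                                 - run.control.mean_cost)

    def test_null_intervention_no_effect(self, params, lifetable):
        p = params.copy()
        p.settings.cohort_size = 2000
        p.epi.hr_dm2_by_band = [(0, None, 1.0)]
        p.epi.hr_cvd_event = 1.0
        p.epi.hr_dm2_mortality = 1.0
        p.epi.hr_cvd_mortality = 1.0
        p.costs.intervention_total = 0.0
        p.costs.annual_screening = 0.0
        p.validate()
        run = ps.run_base_case(p, lifetable, seed=13)
        se = np.hypot(run.control.se_qaly, run.intervention.se_qaly)
        assert abs(run.incr_qaly) < 3 * se
        se_c = np.hypot(run.control.se_cost, run.intervention.se_cost)
        assert abs(run.incr_cost) < 3 * se_c

    def test_to_frame_roundtrip(self, params, lifetable):
        p = params.copy()
        p.settings.cohort_size = 100
        df = ps.run_base_case(p, lifetable, seed=3).to_frame()
        assert {"incr_qaly", "incr_cost", "icer"} <= set(df.columns)
        assert len(df) == 2


class TestCohortOracle:
    def test_certain_death_half_year(self, params):
        p = no_disease(params)
        ly, cost, qaly = ps.cohort_oracle(p, certain_death_table(), 45)
        # death probabilities are capped at 1 - 1e-9, leaving a sliver
        assert ly == pytest.approx(0.5, abs=1e-7)

    def test_discounted_not_more_than_undiscounted(self, params, lifetable):
        ly, cost, qaly = ps.cohort_oracle(params, lifetable, 45)
        p0 = params.copy()
        p0.settings.discount_rate_costs = 0.0
        p0.settings.discount_rate_effects = 0.0
        ly0, cost0, qaly0 = ps.cohort_oracle(p0, lifetable, 45)
        assert qaly <= qaly0 and cost <= cost0
        assert ly == pytest.approx(ly0)  # life-years are never discounted

    def test_agrees_with_microsim(self, params, lifetable):
        """Monte-Carlo means converge on the deterministic expectation
        when utilities are made memoryless (the central correctness
        check; the large-n version runs with the acceptance suite)."""
        n = 4000
        ly, cost, qaly = ps.cohort_oracle(params, lifetable, 45)
        cohort = [ps.Individual(id=i, current_age=45) for i in range(n)]
        arm = ps.simulate_arm("control", params, lifetable, seed=17,
                              cohort=cohort, memoryless_utilities=True)
        assert abs(arm.mean_ly - ly) < 3 * arm.se_ly
        assert abs(arm.mean_cost - cost) < 3 * arm.se_cost
        assert abs(arm.mean_qaly - qaly) < 3 * arm.se_qaly

    def test_oracle_matches_lifetable_expectancy(self, params, lifetable):
        """With every disease flow off, the model is the life table."""
        p = no_disease(params)
        p.settings.horizon_mode = "lifetime"
        p.settings.max_age = 120
        p.validate()
        ly, _, _ = ps.cohort_oracle(p, lifetable, 0,
                                    entry_state=HealthState.NPG)
        assert ly == pytest.approx(lifetable.life_expectancy(0), abs=0.1)


class TestValidate:
    def test_report_structure_and_directions(self, params, lifetable):
        p = params.copy()
        p.settings.cohort_size = 1500
        report = ps.validate(p, lifetable, seed=23)
        metrics = set(report["metric"])
        assert {"cum_incidence_dm2", "cum_incidence_death",
                "delay_dm2_onset", "delay_cvd_onset",
                "model_life_expectancy_age0", "lifetable_e0"} <= metrics

        def get(metric, arm):
            rows = report[(report.metric == metric) & (report.arm == arm)]
            return float(rows.value.iloc[0])

        # the intervention lowers mortality (effect ratios < 1)
        assert get("cum_incidence_death", "intervention") < get(
            "cum_incidence_death", "control")
        assert get("delay_dm2_onset", "difference") > 0
        assert abs(get("model_life_expectancy_age0", "model")
                   - get("lifetable_e0", "reference")) < 0.1
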