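import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import prediasim as ps
from prediasim.transitions import (ALLOWED_PROGRESSION, LIVING_STATES,
                                   HealthState, TransitionContext)

probs = st.floats(min_value=0.0, max_value=0.95)


class TestAnnualization:
    def test_published_igt_dm2_annualization(self):
        """30-year cumulative incidence of 97.1% annualizes to the
        published 0.1113 annual probability."""
        assert round(ps.annual_probability(0.971, 30), 4) == 0.1113

    def test_identity_at_one_year(self):
        assert ps.annual_probability(0.37, 1) == pytest.approx(0.37,
                                                               abs=1e-12)

    def test_zero_risk(self):
        assert ps.annual_probability(0.0, 10) == 0.0

    def test_certain_risk_rejected(self):
        with pytest.raises(ValueError):
            ps.annual_probability(1.0, 10)

    @settings(deadline=None)
    @given(pt=probs, t=st.integers(min_value=1, max_value=50))
    def test_compounding_inverts_annualization(self, pt, t):
        p = ps.annual_probability(pt, t)
        assert 1 - (1 - p) ** t == pytest.approx(pt, abs=1e-10)


class TestRateConversion:
    def test_known_rate(self):
        assert ps.prob_to_rate(0.1410) == pytest.approx(-math.log(0.859),
                                                        abs=1e-12)

    def test_zero(self):
        assert ps.prob_to_rate(0.0) == 0.0
        assert ps.rate_to_prob(0.0) == 0.0

    @settings(deadline=None)
    @given(p=probs)
    def test_mutually_inverse(self, p):
        assert ps.rate_to_prob(ps.prob_to_rate(p)) == pytest.approx(
            p, abs=1e-12)

    def test_certain_probability_rejected(self):
        with pytest.raises(ValueError):
            ps.prob_to_rate(1.0)


class TestHazardRatio:
    def test_intervention_dm2_onset(self):
        # 0.1410 under HR 0.57, on the rate scale
        assert ps.apply_hazard_ratio(0.1410, 0.57) == pytest.approx(
            0.08299, abs=5e-6)

    def test_unit_hr_preserves(self):
        assert ps.apply_hazard_ratio(0.3, 1.0) == pytest.approx(0.3,
                                                                abs=1e-12)

    @settings(deadline=None)
    @given(p=st.floats(min_value=1e-6, max_value=0.95),
           hr=st.floats(min_value=0.05, max_value=5.0))
    def test_monotone_in_hr(self, p, hr):
        out = ps.apply_hazard_ratio(p, hr)
        if hr < 1:
            assert out < p
        elif hr > 1:
            assert out > p

    def test_mortality_chain_reproduces_intervention_cumulative(self):
        """Annualizing the 30-year control all-cause mortality (56.3%),
        applying the intervention hazard ratio 0.74 and compounding back
        over 30 years lands on the published 45.7% within rounding."""
        p_ann = ps.annual_probability(0.563, 30)
        p_int = ps.apply_hazard_ratio(p_ann, 0.74)
        cum = 1 - (1 - p_int) ** 30
        assert cum == pytest.approx(0.457, abs=0.002)


class TestBandLookup:
    def test_published_bands(self, params):
        bands = params.epi.p_igt_to_dm2_by_band
        assert ps.band_lookup(bands, 50) == 0.1410
        assert ps.band_lookup(bands, 70) == 0.1113

    def test_boundary_inclusive(self, params):
        bands = params.epi.p_igt_to_dm2_by_band
        assert ps.band_lookup(bands, 65) == 0.1410
        assert ps.band_lookup(bands, 66) == 0.1113

    def test_uncovered_age(self):
        with pytest.raises(ValueError):
            ps.band_lookup([(45, 65, 0.1)], 70)


class TestMortality:
    def test_background_passthrough(self, params, flat_lifetable):
        for arm in ("control", "intervention"):
            ctx = TransitionContext(arm=arm, age=50, state=HealthState.NPG)
            assert ps.mortality_probability(
                ctx, flat_lifetable, params.epi) == 0.01

    def test_dm2_control_rate_doubling(self, params, flat_lifetable):
        ctx = TransitionContext(arm="control", age=50, state=HealthState.DM2)
        assert ps.mortality_probability(
            ctx, flat_lifetable, params.epi) == pytest.approx(
                ps.rate_to_prob(2.0 * ps.prob_to_rate(0.01)), abs=1e-12)

    def test_cvd_intervention_product(self, params, flat_lifetable):
        ctx = TransitionContext(arm="intervention", age=50,
                                state=HealthState.CVD)
        expected = ps.rate_to_prob(2.13 * 0.67 * ps.prob_to_rate(0.01))
        assert ps.mortality_probability(
            ctx, flat_lifetable, params.epi) == pytest.approx(expected,
                                                              abs=1e-12)
        assert expected == pytest.approx(0.014240, abs=5e-7)

    def test_death_state_rejected(self, params, flat_lifetable):
        with pytest.raises(ValueError):
            ps.mortality_probability(
                TransitionContext(arm="control", age=50,
                                  state=HealthState.DEATH),
                flat_lifetable, params.epi)


class TestTransitionRows:
    def test_igt_control_composition(self, params, lifetable):
        ctx = TransitionContext(arm="control", age=50, state=HealthState.IGT)
        row = ps.build_transition_row(ctx, params, lifetable)
        q = ps.mortality_probability(ctx, lifetable, params.epi)
        assert row[HealthState.DM2] == pytest.approx((1 - q) * 0.1410,
                                                     abs=1e-12)
        assert row[HealthState.NPG] == pytest.approx((1 - q) * 0.192,
                                                     abs=1e-12)

    def test_igt_intervention_uses_hr(self, params, lifetable):
        ctx = TransitionContext(arm="intervention", age=50,
                                state=HealthState.IGT)
        row = ps.build_transition_row(ctx, params, lifetable)
        q = ps.mortality_probability(ctx, lifetable, params.epi)
        expected = (1 - q) * ps.apply_hazard_ratio(0.1410, 0.57)
        assert row[HealthState.DM2] == pytest.approx(expected, abs=1e-12)

    def test_death_absorbing(self, params, lifetable):
        ctx = TransitionContext(arm="control", age=50,
                                state=HealthState.DEATH)
        row = ps.build_transition_row(ctx, params, lifetable)
        assert row[HealthState.DEATH] == 1.0
        assert sum(row.values()) == 1.0

    @settings(deadline=None, max_examples=200)
    @given(age=st.integers(min_value=25, max_value=110),
           state=st.sampled_from(LIVING_STATES),
           arm=st.sampled_from(["control", "intervention"]))
    def test_rows_sum_to_one_with_allowed_edges_only(
            self, params, lifetable, age, state, arm):
        ctx = TransitionContext(arm=arm, age=age, state=state)
        row = ps.build_transition_row(ctx, params, lifetable)
        assert sum(row.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(p >= 0 for p in row.values())
        allowed = set(ALLOWED_PROGRESSION[state]) | {state, HealthState.DEATH}
        for dest, p in row.items():
            if dest not in allowed:
                assert p == 0.0

    def test_export_csv(self, params, lifetable, tmp_path):
        path = tmp_path / "rows.csv"
        ps.transitions.export_transition_table(params, lifetable, path,
                                               ages=range(45, 48))
        header = path.read_text().splitlines()[0]
        assert header == "state,age,arm,dest,prob"
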