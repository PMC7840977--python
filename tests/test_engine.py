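"""Projection engine: rate decomposition, annual cycle, matrix-oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tobaccohia import (
    Scenario,
    build_state_rates,
    decompose_incidence,
    decompose_mortality,
    run_simulation,
    step_year,
)
from tobaccohia.engine import initial_state

from _oracles import build_one_year_matrix, state_vector


class TestDecomposition:
    def test_hand_arithmetic_incidence(self):
        # denom = 0.6 + 0.2*10 + 0.2*2 = 3.0
        i_n, i_c, i_f = decompose_incidence(0.0017, 0.6, 0.2, 0.2, 10.0, 2.0)
        assert i_n == pytest.approx(0.0017 / 3.0, rel=1e-12)
        assert i_c == pytest.approx(10 * 0.0017 / 3.0, rel=1e-12)
        assert i_f == pytest.approx(2 * 0.0017 / 3.0, rel=1e-12)
        assert 0.6 * i_n + 0.2 * i_c + 0.2 * i_f == pytest.approx(0.0017, rel=1e-12)

    def test_hand_arithmetic_mortality(self):
        # denom = 0.5 + 0.2*2.07 + 0.3*1.535 = 1.3745
        m_n, m_c, m_f = decompose_mortality(0.01, 0.5, 0.2, 0.3, 2.07, 1.535)
        assert m_n == pytest.approx(0.01 / 1.3745, rel=1e-12)
        assert m_c == pytest.approx(0.0207 / 1.3745, rel=1e-12)

    def test_no_effect_limit(self):
        assert decompose_incidence(0.3, 0.2, 0.5, 0.3, 1.0, 1.0) == (0.3, 0.3, 0.3)

    def test_all_never(self):
        i_n, i_c, i_f = decompose_incidence(0.02, 1.0, 0.0, 0.0, 10.0, 2.0)
        assert i_n == 0.02

    def test_empty_distribution_gives_zeros(self):
        assert decompose_incidence(0.5, 0.0, 0.0, 0.0, 10.0, 2.0) == (0.0, 0.0, 0.0)

    def test_zero_total(self):
        assert decompose_mortality(0.0, 0.5, 0.3, 0.2, 2.0, 1.5) == (0.0, 0.0, 0.0)

    @settings(deadline=None, derandomize=True, max_examples=150)
    @given(
        total=st.floats(0.0, 0.05),
        p_n=st.floats(0.01, 1.0),
        c_share=st.floats(0.0, 1.0),
        rr_f=st.floats(1.0, 5.0),
        rr_extra=st.floats(0.0, 15.0),
    )
    def test_weighted_average_reproduces_total(self, total, p_n, c_share, rr_f, rr_extra):
        p_c = (1 - p_n) * c_share
        p_f = 1 - p_n - p_c
        rr_c = rr_f + rr_extra
        i_n, i_c, i_f = decompose_incidence(total, p_n, p_c, p_f, rr_c, rr_f)
        assert p_n * i_n + p_c * i_c + p_f * i_f == pytest.approx(total, abs=1e-12)


class TestCalibration:
    def test_state_rates_aggregate_back_to_inputs(self, bundle1):
        rates = build_state_rates(bundle1)
        stack = bundle1.smoking.as_stack()
        agg_inc = (stack * rates.incidence_by_smoking).sum(axis=-1)
        agg_mort = (stack * rates.mortality_by_smoking).sum(axis=-1)
        assert np.abs(agg_inc - bundle1.disease.copd_incidence).max() < 1e-12
        assert np.abs(agg_mort - bundle1.mortality.all_cause).max() < 1e-12

    def test_rates_frozen_from_reference(self, bundle1):
        """Intervention runs reuse reference rates: year-0 incidence drops."""
        ref = run_simulation(bundle1, Scenario(price_increase_percent=0.0))
        interv = run_simulation(bundle1, Scenario(price_increase_percent=20.0))
        assert interv.incident_cases[0].sum() < ref.incident_cases[0].sum()

    def test_rr_one_makes_scenarios_equivalent(self, bundle1):
        b = bundle1.copy()
        b.disease.rr_copd_current[:] = 1.0
        b.disease.rr_copd_former[:] = 1.0
        b.mortality.rr_mort_current[:] = 1.0
        b.mortality.rr_mort_former[:] = 1.0
        ref = run_simulation(b)
        interv = run_simulation(b, Scenario(price_increase_percent=50.0))
        assert np.allclose(ref.incident_cases.sum(axis=(1, 2)),
                           interv.incident_cases.sum(axis=(1, 2)), rtol=1e-9)
        assert np.allclose(ref.deaths.sum(axis=(1, 2)),
                           interv.deaths.sum(axis=(1, 2)), rtol=1e-9)


class TestStepYear:
    def test_pure_ageing(self, zero_rate_bundle):
        state = initial_state(zero_rate_bundle)
        rates = build_state_rates(zero_rate_bundle)
        trans = zero_rate_bundle.transitions.for_region(zero_rate_bundle.region)
        new, cases, deaths = step_year(state, rates, trans, np.zeros(2))
        assert cases.sum() == 0 and deaths.sum() == 0
        assert np.array_equal(new.counts[:, 1:], state.counts[:, :-1])
        assert np.all(new.counts[:, 0] == 0)

    def test_forced_mortality_arithmetic(self, zero_rate_bundle):
        """Half of a smoking cohort dying leaves exactly half at the next age."""
        b = zero_rate_bundle.copy()
        b.demographics.counts[:] = 0.0
        b.demographics.counts[0, 50] = 1000.0
        b.smoking.p_never[0, 50] = 0.0
        b.smoking.p_current[0, 50] = 1.0
        b.smoking.p_former[0, 50] = 0.0
        b.mortality.all_cause[0, 50] = 0.5
        b.mortality.rr_mort_current[:] = 1.0
        b.mortality.rr_mort_former[:] = 1.0
        state = initial_state(b)
        rates = build_state_rates(b)
        trans = b.transitions.for_region(b.region)
        new, _, deaths = step_year(state, rates, trans, np.zeros(2))
        assert deaths[0, 50] == pytest.approx(500.0)
        assert new.counts[0, 51].sum() == pytest.approx(500.0)

    def test_newborns_enter_as_never_smokers(self, bundle1):
        state = initial_state(bundle1)
        rates = build_state_rates(bundle1)
        trans = bundle1.transitions.for_region(bundle1.region)
        new, _, _ = step_year(state, rates, trans, np.array([100.0, 90.0]))
        assert new.counts[0, 0, 0, 0] == 100.0
        assert new.counts[1, 0, 0, 0] == 90.0
        assert new.counts[:, 0, 1:, :].sum() == 0
        assert new.counts[:, 0, :, 1].sum() == 0


class TestMatrixOracle:
    def _toy_bundle(self, bundle1, ages=(40, 50, 60, 70, 90)):
        b = bundle1.copy()
        counts = np.zeros_like(b.demographics.counts)
        for a in ages:
            counts[:, a] = b.demographics.counts[:, a]
        b.demographics.counts = counts
        b.demographics.newborns = np.zeros_like(b.demographics.newborns)
        return b

    def test_one_step_equals_matrix_product(self, bundle1):
        b = self._toy_bundle(bundle1)
        M = build_one_year_matrix(b)
        traj = run_simulation(b, horizon=1)
        v0 = state_vector(traj.states[0])
        assert np.allclose(state_vector(traj.states[1]), M @ v0, rtol=0, atol=1e-12)

    def test_forty_year_trajectory_equals_matrix_powering(self, bundle1):
        b = self._toy_bundle(bundle1)
        M = build_one_year_matrix(b)
        traj = run_simulation(b, horizon=40)
        v = state_vector(traj.states[0])
        scale = max(v.sum(), 1.0)
        for t in range(1, 41):
            v = M @ v
            assert np.allclose(state_vector(traj.states[t]), v, rtol=0, atol=1e-10 * scale)


class TestRunSimulation:
    def test_reference_equals_no_scenario(self, bundle1, ref_traj):
        explicit = run_simulation(bundle1, Scenario(price_increase_percent=0.0))
        for t in range(ref_traj.horizon + 1):
            assert np.array_equal(explicit.states[t].counts, ref_traj.states[t].counts)

    def test_deterministic(self, bundle1):
        t1 = run_simulation(bundle1, Scenario(price_increase_percent=10.0))
        t2 = run_simulation(bundle1, Scenario(price_increase_percent=10.0))
        assert np.array_equal(t1.incident_cases, t2.incident_cases)

    def test_zero_horizon(self, bundle1):
        traj = run_simulation(bundle1, horizon=0)
        assert traj.horizon == 0
        assert len(traj.states) == 1

    def test_conservation_identity(self, ref_traj):
        for t in range(ref_traj.horizon):
            start = ref_traj.alive(t)
            nxt = ref_traj.alive(t + 1)
            resid = nxt[:, 1:] - (start[:, :-1] - ref_traj.deaths[t][:, :-1])
            assert np.abs(resid).max() <= 1e-9 * start.sum()

    def test_structural_zeros_every_year(self, ref_traj):
        for st_ in ref_traj.states:
            c = st_.counts
            assert c[:, :11, 1, :].sum() == 0   # no current smokers below 11
            assert c[:, :16, 2, :].sum() == 0   # no former smokers below 16
            assert c[:, :40, :, 1].sum() == 0   # no COPD below 40
            assert c.min() >= 0

    def test_cumulative_cases_monotone_in_price(self, traj_by_price):
        prices = sorted(traj_by_price)
        totals = [traj_by_price[p].incident_cases.sum() for p in prices]
        assert all(a > b for a, b in zip(totals, totals[1:]))
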