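"""ODE right-hand sides and the RK4 integrator.

The no-treatment model has the closed-form solution

    x1(t) = V0 * exp((a - n) t)
    x2(t) = (n / (a - n)) * (x1(t) - V0)

used as the analytic oracle for the integrator, alongside an independent
explicit-Euler reference (conftest) for treated runs.
"""

import math

import numpy as np
import pytest

from minpkpd import (
    Channel,
    DoseSchedule,
    ValidationError,
    combined_rhs,
    default_legacy_parameters,
    hill_surface,
    interaction_index,
    legacy_rhs,
    normalize_levels,
    simulate,
    simulate_legacy,
    weekly_schedule,
)
from minpkpd.experiments import protocol_schedules
from minpkpd.surfaces import NormalizedPair


def control_closed_form(params, t):
    x1 = params.V0 * math.exp((params.a - params.n) * t)
    x2 = (params.n / (params.a - params.n)) * (x1 - params.V0)
    return x1, x2


class TestCombinedRHS:
    def test_control_reduction(self, params):
        state = (800.0, 50.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        d = combined_rhs(0.0, state, params, {})
        assert d.x1 == pytest.approx((params.a - params.n) * 800.0)
        assert d.x2 == pytest.approx(params.n * 800.0)
        assert d[2:] == (0.0,) * 6

    def test_total_volume_growth_identity(self, params):
        # dx1 + dx2 = a*x1 exactly: the kill flux cancels between compartments
        rng = np.random.default_rng(7)
        for _ in range(20):
            state = tuple(rng.uniform(0, 5, size=8) * [1000, 500, 1, 1, 1, 1, 10, 10])
            d = combined_rhs(0.5, state, params, {})
            assert d.x1 + d.x2 == pytest.approx(params.a * state[0], rel=1e-12)

    def test_effect_terms_consistent_with_surfaces(self, params):
        state = (params.V0, 0.0, 0.44, 0.22, 0.0, 0.0, 0.0, 0.0)
        schedules = {Channel.AG: weekly_schedule(Channel.AG, 0.171, 30)}
        d = combined_rhs(0.5, state, params, schedules)
        levels = normalize_levels(state, params)
        et_a = hill_surface(
            interaction_index(NormalizedPair(levels["tumor"], levels["AG"]), params.sigma),
            params.gamma,
            params.Emax_a,
        )
        # dxe3 = -c_a*xe3 + Et_a*x3
        assert d.xe3 == pytest.approx(-params.c_a * 0.22 + et_a * 0.44, rel=1e-12)


class TestLegacyRHS:
    def test_zero_drug_limit(self):
        p = default_legacy_parameters()
        d = legacy_rhs(0.0, (1000.0, 0.0, 0.0), p, u_a=0.5)
        assert d[0] == pytest.approx((p.a - p.n_a) * 1000.0)
        assert d[1] == pytest.approx(p.n_a * 1000.0)
        assert d[2] == pytest.approx(0.5)

    def test_saturation_limit_of_inhibition(self):
        p = default_legacy_parameters()
        x3 = 1e6  # far above ED50
        d = legacy_rhs(0.0, (1000.0, 0.0, x3), p, u_a=0.0)
        inhibition = (p.a - p.n_a) * 1000.0 - d[0]
        assert inhibition == pytest.approx(p.b_a * 1000.0, rel=1e-4)

    def test_half_effect_inhibition_hand_value(self):
        p = default_legacy_parameters()
        d = legacy_rhs(0.0, (1000.0, 0.0, p.ED50_a), p, u_a=0.0)
        inhibition = (p.a - p.n_a) * 1000.0 - d[0]
        assert inhibition == pytest.approx(84.25, rel=1e-12)


class TestSimulate:
    def test_control_matches_closed_form(self, params):
        trajectory = simulate(params, None, horizon=30, step=0.01)
        x1_exact, x2_exact = control_closed_form(params, 30.0)
        assert trajectory.states[-1, 0] == pytest.approx(x1_exact, rel=1e-6)
        assert trajectory.states[-1, 1] == pytest.approx(x2_exact, rel=1e-6)

    def test_daily_grid_and_initial_state(self, params):
        trajectory = simulate(params, None, horizon=30)
        assert trajectory.times.tolist() == list(range(31))
        assert trajectory.states[0].tolist() == [params.V0] + [0.0] * 7
        assert (np.diff(trajectory.times) > 0).all()

    def test_total_volume_is_pointwise_sum(self, params):
        trajectory = simulate(params, protocol_schedules(2), horizon=30)
        assert np.allclose(
            trajectory.total_volume,
            trajectory.states[:, 0] + trajectory.states[:, 1],
        )

    def test_step_halving_converges(self, params):
        # with gamma = 2.5 the Hill terms are only C^2 at therapy onset
        # (i**2.5 near zero level), so the step-halving error at treatment
        # start is not full fourth order; it is small and keeps shrinking
        coarse = simulate(params, protocol_schedules(1), step=0.01)
        fine = simulate(params, protocol_schedules(1), step=0.005)
        finest = simulate(params, protocol_schedules(1), step=0.0025)
        rel_1 = abs(coarse.states[-1, 0] - fine.states[-1, 0]) / fine.states[-1, 0]
        rel_2 = abs(fine.states[-1, 0] - finest.states[-1, 0]) / finest.states[-1, 0]
        assert rel_1 < 1e-5
        assert rel_2 < rel_1

    def test_step_halving_on_smooth_control_is_tight(self, params):
        coarse = simulate(params, None, step=0.01)
        fine = simulate(params, None, step=0.005)
        rel = abs(coarse.states[-1, 0] - fine.states[-1, 0]) / fine.states[-1, 0]
        assert rel < 1e-9

    def test_agrees_with_independent_euler_oracle(
        self, params, euler_protocol1_endpoint
    ):
        trajectory = simulate(params, protocol_schedules(1), horizon=30)
        x1 = trajectory.states[-1, 0]
        total = trajectory.total_volume[-1]
        euler_x1 = euler_protocol1_endpoint[0]
        euler_total = euler_protocol1_endpoint[0] + euler_protocol1_endpoint[1]
        assert abs(x1 - euler_x1) / euler_x1 < 1e-3
        assert abs(total - euler_total) / euler_total < 1e-3

    @pytest.mark.parametrize("protocol_id", [1, 2, 3])
    def test_nonnegativity_under_protocols(self, params, protocol_id):
        trajectory = simulate(params, protocol_schedules(protocol_id))
        assert (trajectory.states >= 0.0).all()

    def test_nonnegativity_under_random_schedule(self, params):
        rng = np.random.default_rng(11)
        schedules = {
            channel: DoseSchedule.from_pairs(
                channel,
                [(int(d), float(a)) for d, a in zip(
                    rng.integers(1, 31, size=6),
                    rng.uniform(0, scale, size=6),
                )],
                horizon=30,
            )
            for channel, scale in [(Channel.AG, 0.5), (Channel.IM, 0.5), (Channel.RT, 8.0)]
        }
        trajectory = simulate(params, schedules)
        assert (trajectory.states >= 0.0).all()

    @pytest.mark.parametrize("protocol_id", [1, 2, 3])
    def test_treatment_never_exceeds_control(self, params, protocol_id):
        control = simulate(params, None)
        treated = simulate(params, protocol_schedules(protocol_id))
        assert (treated.states[:, 0] <= control.states[:, 0] + 1e-9).all()

    def test_bit_exact_determinism(self, params):
        first = simulate(params, protocol_schedules(2))
        second = simulate(params, protocol_schedules(2))
        assert np.array_equal(first.states, second.states)
        assert np.array_equal(first.effects, second.effects)

    def test_total_volume_never_decreases(self, params):
        # the kill flux moves volume to necrosis; nothing washes out
        trajectory = simulate(params, protocol_schedules(3))
        assert (np.diff(trajectory.total_volume) >= -1e-9).all()

    def test_mass_growth_identity(self, params):
        # x1(t) + x2(t) - V0 = a * integral of x1, checked by Simpson on the
        # daily grid of a control run where x1 is smooth and exponential
        trajectory = simulate(params, None)
        x1 = trajectory.states[:, 0]
        integral = np.trapezoid(x1, trajectory.times)
        lhs = trajectory.total_volume[-1] - params.V0
        assert lhs == pytest.approx(params.a * integral, rel=5e-3)

    def test_bolus_mode_injects_at_day_start(self, params):
        schedule = DoseSchedule.from_pairs(
            Channel.AG, [(1, 0.171)], horizon=5, mode="bolus"
        )
        trajectory = simulate(params, {Channel.AG: schedule}, horizon=5)
        expected = 0.171 * math.exp(-params.c_a * 1.0)
        assert trajectory.states[1, 2] == pytest.approx(expected, rel=1e-9)

    def test_step_validation(self, params):
        with pytest.raises(ValidationError, match="step"):
            simulate(params, None, step=0.2)

    def test_initial_state_length_validation(self, params):
        with pytest.raises(ValidationError, match="initial_state"):
            simulate(params, None, initial_state=(1.0, 2.0))


class TestSimulateLegacy:
    def test_control_is_exponential(self):
        p = default_legacy_parameters()
        trajectory = simulate_legacy(p, None, horizon=10)
        expected = 1000.0 * math.exp((p.a - p.n_a) * 10.0)
        assert trajectory.states[-1, 0] == pytest.approx(expected, rel=1e-6)

    def test_treatment_slows_growth_and_stays_nonnegative(self):
        p = default_legacy_parameters()
        schedule = weekly_schedule(Channel.AG, 0.171, 30)
        treated = simulate_legacy(p, schedule, horizon=30)
        control = simulate_legacy(p, None, horizon=30)
        assert treated.states[-1, 0] < control.states[-1, 0]
        assert (treated.states >= 0.0).all()
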