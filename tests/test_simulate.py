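import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from triplexsim import (
    ModelState,
    ParameterSet,
    build_protocol,
    default_parameters,
    simulate,
    simulate_batch,
    step_integrate,
    survival_table,
)
from triplexsim.model import STATE_FIELDS

LN2 = math.log(2.0)
CC = STATE_FIELDS.index("cc")


class TestStepIntegrate:
    def test_zero_state_grows_tumor_influx(self, params):
        state = step_integrate(ModelState(), params)
        # exact 1-D solution from the empty state: CC(1) = (p/k)(e^k - 1)
        expected = params.p / params.k * math.expm1(params.k)
        assert state.cc == pytest.approx(expected, rel=1e-6)
        assert state.cc == pytest.approx(params.p, rel=5e-2)
        assert state.vc == state.ab == state.tc == 0.0

    def test_exponential_decay_half_life(self):
        # decoupled: only VC decays, half-life 9 steps
        p = ParameterSet(mu_1=LN2 / 9)
        state = ModelState(vc=100.0)
        for _ in range(9):
            state = step_integrate(state, p)
        assert state.vc == pytest.approx(50.0, abs=1e-6)

    def test_substep_validation(self, params):
        with pytest.raises(ValueError):
            step_integrate(ModelState(), params, n_substeps=0)


class TestClosedFormLimits:
    def test_logistic_plus_influx_against_reference_integrator(self):
        # tumor growth alone: dCC/dt = k(1 - CC/c_max)CC + p, all other
        # populations identically zero
        p = ParameterSet(k=0.0226, p=3.0, c_max=1e7)
        proto = build_protocol("untreated", 0, 30, 0.0)
        traj = simulate(p, proto, end_week=30, stop_at_death=False)

        sol = solve_ivp(
            lambda t, y: p.k * (1 - y / p.c_max) * y + p.p,
            (0.0, 30 * 21.0),
            [0.0],
            t_eval=np.asarray(traj.steps, dtype=float),
            rtol=1e-11,
            atol=1e-12,
            method="DOP853",
        )
        ours = traj.column("cc")
        scale = np.maximum(np.abs(sol.y[0]), 1.0)
        assert np.max(np.abs(ours - sol.y[0]) / scale) < 1e-6

    def test_exponential_decay_trajectory(self):
        p = ParameterSet(mu_9=LN2 / 21)
        proto = build_protocol("untreated", 0, 10, 0.0)
        traj = simulate(p, proto, end_week=10, stop_at_death=False,
                        initial_state=ModelState(tc=1000.0))
        steps = np.asarray(traj.steps, dtype=float)
        expected = 1000.0 * np.exp(-p.mu_9 * steps)
        np.testing.assert_allclose(traj.column("tc"), expected, rtol=1e-6)

    def test_rk4_self_convergence(self, params):
        # smooth (untreated) dynamics: halving the sub-step leaves the
        # trajectory unchanged to well below reporting precision
        proto = build_protocol("untreated", 6, 20, 0.0)
        coarse = simulate(params, proto, end_week=20, stop_at_death=False,
                          n_substeps=8)
        fine = simulate(params, proto, end_week=20, stop_at_death=False,
                        n_substeps=16)
        scale = np.maximum(np.abs(fine.states), 1.0)
        assert np.max(np.abs(coarse.states - fine.states) / scale) < 1e-6

    def test_death_step_robust_to_substep_resolution(self, params, early_traj):
        # treated runs traverse locally stiff antibody phases where the
        # stability guard sets the effective grid; the predicted death
        # step must not depend on the base sub-step count
        proto = build_protocol("early", 6, 57, params.q)
        finer = simulate(params, proto, end_week=57, n_substeps=16)
        assert finer.death_step == early_traj.death_step


class TestSimulate:
    def test_trajectory_invariants(self, early_traj):
        steps = np.asarray(early_traj.steps)
        assert steps[0] == 0
        assert np.all(np.diff(steps) == 1)
        np.testing.assert_array_equal(early_traj.states[0], np.zeros(10))
        assert np.all(early_traj.states >= 0.0)
        assert np.all(np.isfinite(early_traj.states))

    def test_death_step_is_minimal_crossing(self, early_traj):
        cc = early_traj.column("cc")
        crossing = np.nonzero(cc >= early_traj.threshold)[0]
        assert early_traj.death_step == crossing[0]
        assert np.all(cc[: early_traj.death_step] < early_traj.threshold)

    def test_untreated_monotone_growth_to_threshold(self, untreated_traj):
        assert untreated_traj.death_step is not None
        cc = untreated_traj.column("cc")
        assert np.all(np.diff(cc[: untreated_traj.death_step + 1]) > 0)

    def test_determinism(self, params):
        proto = build_protocol("early", 6, 20, params.q)
        a = simulate(params, proto, end_week=20)
        b = simulate(params, proto, end_week=20)
        np.testing.assert_array_equal(a.states, b.states)

    def test_injection_accounting(self, early_traj, params):
        assert len(early_traj.injections_applied) == 12
        assert sum(d for _, d in early_traj.injections_applied) == 12 * params.q

    def test_monotone_vaccine_response(self, params, early_traj):
        proto = build_protocol("early", 6, 57, 100.0)
        boosted = simulate(params.replace(q=100.0), proto, end_week=57)
        assert boosted.death_step >= early_traj.death_step

    def test_threshold_validation(self, params):
        proto = build_protocol("untreated", 6, 57, 0.0)
        with pytest.raises(ValueError):
            simulate(params, proto, threshold=0.0)

    def test_stop_at_death_truncates(self, params):
        proto = build_protocol("untreated", 6, 57, 0.0)
        stopped = simulate(params, proto, end_week=57, stop_at_death=True)
        full = simulate(params, proto, end_week=57, stop_at_death=False)
        assert len(stopped.steps) - 1 == stopped.death_step
        assert len(full.steps) == 57 * 21 + 1
        assert full.death_step == stopped.death_step


class TestBatch:
    def test_batch_matches_scalar_runs(self, params):
        proto = build_protocol("early", 6, 12, params.q)
        grid = np.arange(0, 12 * 21 + 1, 21)
        gammas = np.array([0.05, 0.2, 0.4])
        batch = simulate_batch(params.replace(gamma_91=gammas), proto,
                               end_week=12, record_steps=grid)
        for i, g in enumerate(gammas):
            traj = simulate(params.replace(gamma_91=float(g)), proto,
                            end_week=12, stop_at_death=False)
            # the batch shares one stability-guarded sub-step grid across
            # rows, the scalar run picks its own, so agreement is limited
            # by truncation, not round-off
            np.testing.assert_allclose(batch[i], traj.column("cc")[grid],
                                       rtol=1e-4, atol=1e-6)

    def test_record_steps_validated(self, params):
        proto = build_protocol("untreated", 6, 10, 0.0)
        with pytest.raises(ValueError):
            simulate_batch(params, proto, end_week=10,
                           record_steps=np.array([0, 10 * 21 + 1]))


class TestSurvivalTable:
    def test_protocol_ordering(self, params):
        protos = [build_protocol(k, 6, 57, params.q)
                  for k in ("untreated", "early", "chronic")]
        rows = survival_table(params, protos)
        by_name = {r.protocol: r for r in rows}
        assert by_name["untreated"].death_week < by_name["early"].death_week
        assert by_name["chronic"].censored

    def test_empty_and_duplicate(self, params):
        assert survival_table(params, []) == []
        proto = build_protocol("untreated", 6, 20, 0.0)
        a, b = survival_table(params, [proto, proto], end_week=20)
        assert a == b
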