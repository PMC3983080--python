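"""Tracking objective, target trajectories and objective surrogates."""

import numpy as np
import pytest

from mmpc.model_bank import ModelState, PredictionModel, advance_state
from mmpc.mpc_objective import (
    CASE_STUDY_TARGETS,
    ObjectiveSpec,
    build_objective_surrogates,
    target_trajectory,
    tracking_objective,
)


class TestTargetTrajectory:
    def test_no_turn_off_limit_holds_near_one(self):
        r = target_trajectory(30, 1.0)
        t = np.linspace(5, 30, 60)
        assert np.all(np.abs(r(t) - 1.0) < 0.01)

    def test_full_termination_monotone_after_switch(self):
        r = target_trajectory(8, 0.0)
        t = np.linspace(9, 30, 50)
        assert np.all(np.diff(r(t)) <= 1e-12)

    def test_steady_state_attained_by_experiment_end(self):
        for t_off, p_ss in CASE_STUDY_TARGETS:
            if t_off <= 22:
                r = target_trajectory(t_off, p_ss)
                assert abs(float(r(30.0)) - p_ss) < 0.01

    def test_range_stays_in_unit_band(self):
        t = np.linspace(0, 30, 301)
        for t_off, p_ss in CASE_STUDY_TARGETS:
            r = target_trajectory(t_off, p_ss)(t)
            assert np.all((r >= 0) & (r <= 1.05))

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            target_trajectory(0.0, 0.5)
        with pytest.raises(ValueError):
            target_trajectory(10.0, 1.2)

    def test_preset_has_ten_pairs(self):
        assert len(CASE_STUDY_TARGETS) == 10


def _constant_output_model(level: float) -> PredictionModel:
    """A model whose controlled output is frozen at ``level``."""
    return PredictionModel(
        model_id=f"const{level}",
        n_x=1,
        n_u=2,
        x0=np.array([level]),
        params={},
        rhs=lambda x, u, t, p: np.zeros(1),
        measured_map=lambda x, u, t, p: np.array([x[0]]),
        controlled_map=lambda x, u, t, p: np.array([x[0]]),
        n_params=1,
    )


class TestTrackingObjective:
    def test_perfect_tracking_returns_log_eps(self):
        """Output equal to the target with zero dose: pre-log J = 0."""
        model = _constant_output_model(1.0)
        target = target_trajectory(30, 1.0)

        class Flat:
            t_off, p_ss = 30, 1.0

            def __call__(self, t):
                return np.ones_like(np.asarray(t, dtype=float))

        spec = ObjectiveSpec()
        j = tracking_objective(
            model, model.initial_state(), np.zeros(2), Flat(), spec, (3.0, 8.0)
        )
        assert j == pytest.approx(np.log(spec.log_eps), abs=1e-9)

    def test_single_sample_hand_arithmetic(self):
        """z = 0.5, r = 1, u = 0.2: J = 0.25 + 0.04."""
        model = _constant_output_model(0.5)
        model.n_u = 1

        class R1:
            def __call__(self, t):
                return np.ones_like(np.asarray(t, dtype=float))

        spec = ObjectiveSpec(Q=np.eye(1), R=np.eye(1), sample_dt=1.0)
        j = tracking_objective(
            model,
            ModelState(x=np.array([0.5]), u_standing=np.zeros(1)),
            np.array([0.2]),
            R1(),
            spec,
            (3.0, 4.0),  # one 1-min sample
        )
        assert j == pytest.approx(np.log(0.29 + spec.log_eps), abs=1e-9)

    def test_zero_q_leaves_only_effort(self):
        model = _constant_output_model(0.3)
        target = target_trajectory(8, 0.0)
        spec = ObjectiveSpec(Q=np.zeros((1, 1)), R=np.eye(2))
        u = np.array([0.4, 0.1])
        j = tracking_objective(
            model, model.initial_state(), u, target, spec, (3.0, 8.0)
        )
        assert j == pytest.approx(np.log(u @ u + spec.log_eps), abs=1e-9)

    def test_objective_finite_on_dense_lattice(self, bank, run_config):
        """No NaNs across a 41x41 dose sweep of one interval."""
        m = bank[0]
        spec = run_config.spec(2)
        target = target_trajectory(22, 0.0)
        state = advance_state(m, m.initial_state(), np.zeros(2), 0.0, 13.0)
        for u in run_config.space.lattice(41):
            j = tracking_objective(m, state, u, target, spec, (13.0, 18.0))
            assert np.isfinite(j)

    def test_unreachable_low_target_demands_inhibitor(self, plant, run_config):
        """With an all-zero target from the start, the minimizer applies a
        nonzero dose of the kinase inhibitor (direction sanity)."""

        class Zero:
            def __call__(self, t):
                return np.zeros_like(np.asarray(t, dtype=float))

        spec = run_config.spec(2)
        state = advance_state(plant, plant.initial_state(), np.zeros(2), 0.0, 3.0)
        lat = run_config.space.lattice(21)
        js = [
            tracking_objective(plant, state, u, Zero(), spec, (3.0, 8.0))
            for u in lat
        ]
        best = lat[int(np.argmin(js))]
        assert best[1] > 0.0


class TestObjectiveSurrogates:
    def test_surrogate_matches_direct_at_support_nodes(self, bank, run_config):
        m = bank[1]
        target = target_trajectory(15, 0.5)
        spec = run_config.spec(2)
        state = m.initial_state()
        (sur,) = build_objective_surrogates(
            [m], [state], target, spec, (3.0, 8.0), run_config.space,
            grid_cfg=run_config.surrogate_cfg,
        )
        for node, val in zip(sur.nodes_physical(), sur.fvals):
            assert sur(node) == pytest.approx(val, abs=1e-10)
            direct = tracking_objective(m, state, node, target, spec, (3.0, 8.0))
            assert val == pytest.approx(direct, abs=1e-9)

    def test_lattice_argmin_agrees_with_direct_evaluation(self, bank, run_config):
        """Surrogate and direct objective agree on the best dose over a
        21x21 lattice to within one lattice cell."""
        target = target_trajectory(22, 0.0)
        spec = run_config.spec(2)
        lat = run_config.space.lattice(21)
        cell = (run_config.space.upper - run_config.space.lower) / 20.0
        for m in bank[:2]:
            state = advance_state(m, m.initial_state(), np.zeros(2), 0.0, 8.0)
            (sur,) = build_objective_surrogates(
                [m], [state], target, spec, (8.0, 13.0), run_config.space,
                grid_cfg=run_config.surrogate_cfg,
            )
            direct_vals = np.array(
                [tracking_objective(m, state, u, target, spec, (8.0, 13.0))
                 for u in lat]
            )
            sur_vals = sur(lat)
            u_direct = lat[int(np.argmin(direct_vals))]
            u_sur = lat[int(np.argmin(sur_vals))]
            assert np.all(np.abs(u_direct - u_sur) <= cell + 1e-9)

    def test_disabled_mode_returns_direct_callables(self, bank, run_config):
        m = bank[0]
        target = target_trajectory(8, 0.25)
        spec = run_config.spec(2)
        state = m.initial_state()
        (fn,) = build_objective_surrogates(
            [m], [state], target, spec, (3.0, 8.0), run_config.space,
            use_surrogate=False,
        )
        u = np.array([10.0, 1.0])
        assert fn(u) == pytest.approx(
            tracking_objective(m, state, u, target, spec, (3.0, 8.0)), abs=1e-12
        )
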