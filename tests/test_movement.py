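import numpy as np

from popreach.design import Display, corner_position
from popreach.movement import (
    MovementParams,
    MovementState,
    SimParams,
    calibrate_onset_interval,
    simulate_trial,
    step_movement,
)
from popreach.selection import (
    ColorCompetitionState,
    CompetitionParams,
    FieldParams,
    HistoryModelSpec,
    LocationField,
    bias_array,
    compute_saliency,
    feature_maps,
    gate_and_step_location_field,
    history_bias,
    HistoryStore,
    saliency_array,
    step_color_competition,
)

NO_HISTORY = HistoryModelSpec("M3a", fac_gain=0.0, inh_gain=0.0)


def field_with_bump(center, params=None, height=2.0):
    params = params or FieldParams()
    fld = LocationField.resting(params)
    gx, gy = np.meshgrid(fld.xs, fld.ys)
    fld.a = height * np.exp(
        -((gx - center[0]) ** 2 + (gy - center[1]) ** 2) / (2 * 1.3 ** 2)
    )
    return fld


class TestStepMovement:
    def test_fixed_attractor_gives_straight_line(self):
        target = corner_position("BR")
        fld = field_with_bump(target)
        aim = np.array(fld.readout())   # constant field -> constant aim
        params = MovementParams()
        state = MovementState.at_start()
        xs, ys = [], []
        for _ in range(400):
            state = step_movement(state, fld, params)
            xs.append(state.pos[0])
            ys.append(state.pos[1])
        # all positions collinear with start->aim
        cross = np.abs(np.array(xs) * aim[1] - np.array(ys) * aim[0])
        assert np.max(cross) < 1e-9 * np.linalg.norm(aim)
        assert np.hypot(*(state.pos - aim)) < 1.0
        # the aim itself sits at the bump (edge truncation aside)
        assert np.hypot(*(aim - np.array(target))) < 1.0

    def test_stationary_before_threshold(self):
        fld = field_with_bump(corner_position("BR"), height=0.1)
        params = MovementParams(init_threshold=0.5)
        state = MovementState.at_start()
        state = step_movement(state, fld, params)
        assert not state.initiated
        assert np.allclose(state.pos, (0.0, 0.0))

    def test_zero_gain_never_moves(self):
        fld = field_with_bump(corner_position("BR"))
        params = MovementParams(gain=0.0)
        state = MovementState.at_start()
        for _ in range(100):
            state = step_movement(state, fld, params)
        assert np.allclose(state.pos, (0.0, 0.0))

    def test_speed_capped(self):
        fld = field_with_bump(corner_position("TR"))
        params = MovementParams(speed_cap=30.0, tau_v=2.0)
        state = MovementState.at_start()
        for _ in range(300):
            state = step_movement(state, fld, params)
            assert np.linalg.norm(state.vel) <= 30.0 + 1e-9


class TestSimulateTrial:
    def test_same_seed_identical(self, default_params):
        prev, cur = Display("red", "green", "BR"), Display("green", "red", "BR")
        t1 = simulate_trial(prev, cur, HistoryModelSpec("M3c"), default_params,
                            rng=np.random.default_rng(5))
        t2 = simulate_trial(prev, cur, HistoryModelSpec("M3c"), default_params,
                            rng=np.random.default_rng(5))
        assert np.array_equal(t1.x, t2.x) and np.array_equal(t1.y, t2.y)

    def test_full_repeat_accurate_and_resolved(self, default_params):
        traj = simulate_trial(Display("red", "green", "TL"),
                              Display("red", "green", "TL"),
                              HistoryModelSpec("M3c"), default_params,
                              rng=np.random.default_rng(0))
        assert traj.correct and traj.resolved
        assert traj.condition == "TRDR"

    def test_full_swap_curves_more_than_full_repeat(self, default_params):
        """Paired on the same noise stream, the full-swap trial deviates
        farther toward the distractors than the full-repeat trial."""
        spec = HistoryModelSpec("M3c")
        prev = Display("red", "green", "BR")

        def max_lateral(cur_colors, seed):
            cur = Display(*cur_colors, "BR")
            traj = simulate_trial(prev, cur, spec, default_params,
                                  rng=np.random.default_rng(seed))
            tgt = np.array(corner_position("BR"))
            d = tgt / np.linalg.norm(tgt)
            pos = np.stack([traj.x, traj.y], axis=1)
            lateral = pos @ np.array([-d[1], d[0]])  # + is toward center/left
            return float(np.max(lateral))

        assert max_lateral(("green", "red"), 3) > max_lateral(("red", "green"), 3)

    def test_unresolved_trial_flagged(self, default_params):
        comp = CompetitionParams(noise_sd=0.0, t_max=10.0)
        params = SimParams(competition=comp)
        traj = simulate_trial(None, Display("red", "green", "BR"),
                              NO_HISTORY, params, onset_interval=200.0)
        assert not traj.resolved and not traj.correct

    def test_first_trial_has_no_condition(self, default_params):
        traj = simulate_trial(None, Display("red", "green", "BR"),
                              HistoryModelSpec("M3c"), default_params,
                              rng=np.random.default_rng(1))
        assert traj.condition is None

    def test_fast_path_matches_public_steps(self, default_params):
        """The fused simulation loop reproduces the composition of the
        public step functions exactly (noiseless)."""
        params = SimParams(competition=CompetitionParams(noise_sd=0.0))
        prev = Display("red", "green", "BR")
        cur = Display("green", "red", "BR")
        interval = calibrate_onset_interval(params)
        traj = simulate_trial(prev, cur, HistoryModelSpec("M3c"), params,
                              onset_interval=interval)

        # reference: compose the public step functions
        store = HistoryStore("red", "green")
        spec = HistoryModelSpec("M3c")
        sal = saliency_array(compute_saliency(cur))
        maps = feature_maps(cur, params.field)
        cstate = ColorCompetitionState.resting()
        fld = LocationField.resting(params.field)
        mstate = MovementState.at_start()
        n = min(traj.t.size - 1, 250)
        xs, ys = [0.0], [0.0]
        for _ in range(n):
            bias = bias_array(history_bias(store, spec, cstate.t, interval))
            cstate = step_color_competition(cstate, sal, bias,
                                            params.competition)
            fld = gate_and_step_location_field(fld, maps, cstate.u,
                                               params.competition.dt)
            mstate = step_movement(mstate, fld, params.movement,
                                   t=cstate.t, min_onset=interval)
            xs.append(mstate.pos[0])
            ys.append(mstate.pos[1])
        assert np.allclose(traj.x[:n + 1], xs, atol=1e-9)
        assert np.allclose(traj.y[:n + 1], ys, atol=1e-9)


class TestSimulateExperiment:
    def test_null_history_model_gives_zero_profiles(self, default_params):
        """With both gains zero and no noise every condition reproduces the
        baseline exactly."""
        from popreach.movement import simulate_experiment
        params = SimParams(competition=CompetitionParams(noise_sd=0.0))
        prof = simulate_experiment(HistoryModelSpec("M1", fac_gain=0.0),
                                   params, n_reps=1, seed=0)
        for cond in prof.conditions():
            assert np.max(np.abs(prof.mean_profile(cond))) < 1e-9, cond

    def test_meta_reports_unresolved_and_error_fractions(self, m3c_profiles):
        assert m3c_profiles.meta["unresolved_fraction"] == 0.0
        assert m3c_profiles.meta["error_fraction"] <= 0.05

    def test_endpoint_accuracy(self, m3c_profiles):
        # accuracy constraint: >= 95% of default-parameter trials arrive
        # at the true target
        assert 1.0 - m3c_profiles.meta["error_fraction"] >= 0.95


def test_calibrated_onset_interval_reasonable(default_params):
    interval = calibrate_onset_interval(default_params)
    assert 50.0 < interval < 600.0
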