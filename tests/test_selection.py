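import numpy as np
import pytest

from popreach.design import Display, all_color_pairs
from popreach.selection import (
    ColorCompetitionState,
    CompetitionParams,
    HistoryModelSpec,
    HistoryStore,
    SaliencyConfig,
    compute_saliency,
    feature_maps,
    gate_and_step_location_field,
    history_bias,
    run_color_competition,
    step_color_competition,
    update_history,
    FieldParams,
    LocationField,
)

NOISELESS = CompetitionParams(noise_sd=0.0)
NO_HISTORY = HistoryModelSpec("M3a", fac_gain=0.0, inh_gain=0.0)


class TestSaliency:
    def test_default_values(self):
        s = compute_saliency(Display("red", "green"))
        assert s == {"red": 1.0, "green": 0.4, "blue": 0.0, "purple": 0.0}

    def test_permutation_symmetry(self):
        cfg = SaliencyConfig()
        s1 = compute_saliency(Display("blue", "purple"), cfg)
        s2 = compute_saliency(Display("purple", "blue"), cfg)
        assert s1["blue"] == s2["purple"] == cfg.target
        assert s1["purple"] == s2["blue"] == cfg.distractor

    def test_no_odd_color_is_invalid(self):
        with pytest.raises(ValueError):
            Display("red", "red")


class TestHistoryBias:
    STORE = HistoryStore("red", "green")

    def test_m3c_inhibition_before_switch(self):
        spec = HistoryModelSpec("M3c", fac_gain=0.2, inh_gain=0.5,
                                switch_fraction=0.65)
        b = history_bias(self.STORE, spec, t=0.3 * 100, onset_interval=100)
        assert b == {"red": 0.0, "green": -0.5, "blue": 0.0, "purple": 0.0}

    def test_m3c_facilitation_after_switch(self):
        spec = HistoryModelSpec("M3c", fac_gain=0.2, inh_gain=0.5,
                                switch_fraction=0.65)
        b = history_bias(self.STORE, spec, t=0.8 * 100, onset_interval=100)
        assert b == {"red": 0.2, "green": 0.0, "blue": 0.0, "purple": 0.0}

    def test_m3b_is_time_mirrored_m3c(self):
        m3b = HistoryModelSpec("M3b", fac_gain=0.2, inh_gain=0.5)
        early = history_bias(self.STORE, m3b, t=10, onset_interval=100)
        late = history_bias(self.STORE, m3b, t=90, onset_interval=100)
        assert early["red"] == 0.2 and early["green"] == 0.0
        assert late["red"] == 0.0 and late["green"] == -0.5

    def test_m3a_both_at_all_times(self):
        spec = HistoryModelSpec("M3a", fac_gain=0.2, inh_gain=0.5)
        for t in (0, 50, 400):
            b = history_bias(self.STORE, spec, t=t, onset_interval=100)
            assert b["red"] == 0.2 and b["green"] == -0.5

    def test_empty_store_gives_zeros(self):
        spec = HistoryModelSpec("M3c")
        b = history_bias(HistoryStore(), spec, t=10, onset_interval=100)
        assert all(v == 0.0 for v in b.values())

    def test_single_mechanism_variants_force_gains(self):
        assert HistoryModelSpec("M1", fac_gain=0.3, inh_gain=0.4).inh_gain == 0
        assert HistoryModelSpec("M2", fac_gain=0.3, inh_gain=0.4).fac_gain == 0

    def test_invalid_variant_and_switch(self):
        with pytest.raises(ValueError):
            HistoryModelSpec("M4")
        with pytest.raises(ValueError):
            HistoryModelSpec("M3c", switch_fraction=0.0)


class TestColorCompetition:
    def test_resting_state_is_fixed_point(self):
        state = ColorCompetitionState.resting()
        zero = np.zeros(4)
        nxt = step_color_competition(state, zero, zero, NOISELESS)
        assert np.allclose(nxt.u, 0.0)
        assert nxt.winner is None

    def test_noiseless_odd_color_wins_all_displays(self):
        for (t, d) in all_color_pairs():
            trace = run_color_competition(
                Display(t, d), HistoryStore(), NO_HISTORY, NOISELESS)
            assert trace[-1].winner == t, (t, d)
            assert trace[-1].winner_time < NOISELESS.t_max

    def test_inhibiting_current_target_slows_selection(self):
        """Previous-distractor inhibition on the current target color delays
        the winner relative to a history-free run."""
        disp = Display("green", "blue")
        base = run_color_competition(disp, HistoryStore(), NO_HISTORY,
                                     NOISELESS)
        spec = HistoryModelSpec("M2", inh_gain=0.4)
        slowed = run_color_competition(disp, HistoryStore("red", "green"),
                                       spec, NOISELESS)
        assert slowed[-1].winner_time > base[-1].winner_time

    def test_more_inhibition_never_faster(self):
        disp = Display("green", "blue")
        store = HistoryStore("red", "green")
        times = []
        for inh in (0.1, 0.3, 0.5):
            spec = HistoryModelSpec("M2", inh_gain=inh)
            trace = run_color_competition(disp, store, spec, NOISELESS)
            times.append(trace[-1].winner_time)
        assert times == sorted(times)

    def test_timeout_flags_unresolved(self):
        params = CompetitionParams(noise_sd=0.0, t_max=4.0)
        trace = run_color_competition(Display("red", "green"), HistoryStore(),
                                      NO_HISTORY, params)
        assert trace[-1].winner is None

    def test_activations_bounded(self):
        trace = run_color_competition(Display("red", "green"), HistoryStore(),
                                      NO_HISTORY, NOISELESS)
        u_max = max(float(np.max(st.u)) for st in trace)
        # contractive net: activation cannot exceed drive / (1 - b)
        bound = SaliencyConfig().target / (1.0 - NOISELESS.b)
        assert u_max <= bound


class TestLocationField:
    def test_absent_colors_contribute_zero(self):
        disp = Display("red", "green", "BR")
        params = FieldParams()
        maps = feature_maps(disp, params)
        fld = LocationField.resting(params)
        # only the two absent colors active: input must be exactly zero
        u = np.array([0.0, 0.0, 5.0, 5.0])
        stepped = gate_and_step_location_field(fld, maps, u, dt=2.0)
        expected = fld.a + (-fld.a + params.h) * (2.0 / params.tau)
        assert np.allclose(stepped.a, expected)

    def test_multiplicative_gating_proportional(self):
        disp = Display("red", "green", "BR")
        params = FieldParams()
        maps = feature_maps(disp, params)
        fld = LocationField.resting(params)
        a1 = gate_and_step_location_field(fld, maps,
                                          np.array([1.0, 0, 0, 0]), 2.0).a
        a2 = gate_and_step_location_field(fld, maps,
                                          np.array([2.0, 0, 0, 0]), 2.0).a
        input1 = a1 - fld.a - (-fld.a + params.h) * (2.0 / params.tau)
        input2 = a2 - fld.a - (-fld.a + params.h) * (2.0 / params.tau)
        assert np.allclose(input2, 2.0 * input1)

    def test_equal_activations_drive_all_four_locations(self):
        disp = Display("red", "green", "BR")
        params = FieldParams()
        maps = feature_maps(disp, params)
        fld = LocationField.resting(params)
        u = np.array([1.0, 1.0, 0.0, 0.0])
        for _ in range(50):
            fld = gate_and_step_location_field(fld, maps, u, 2.0)
        from popreach.design import CORNERS, corner_position
        for corner in CORNERS:
            px, py = corner_position(corner)
            ix = int(np.argmin(np.abs(fld.xs - px)))
            iy = int(np.argmin(np.abs(fld.ys - py)))
            assert fld.a[iy, ix] > 0.0, corner

    def test_readout_between_active_bumps(self):
        disp = Display("red", "green", "BR")
        params = FieldParams()
        maps = feature_maps(disp, params)
        fld = LocationField.resting(params)
        u = np.array([1.0, 1.0, 0.0, 0.0])
        for _ in range(100):
            fld = gate_and_step_location_field(fld, maps, u, 2.0)
        x, y = fld.readout()
        # equal drive at all four corners: centroid near the square center
        assert abs(x - 0.0) < 1.5
        assert abs(y - 20.0) < 1.5


class TestHistoryStore:
    def test_update_overwrites(self):
        store = update_history(HistoryStore(), Display("red", "green"))
        assert (store.prev_target, store.prev_distractor) == ("red", "green")
        store = update_history(store, Display("blue", "purple"))
        assert (store.prev_target, store.prev_distractor) == ("blue", "purple")

    def test_empty_then_populated(self):
        store = HistoryStore()
        assert store.empty
        assert not update_history(store, Display("red", "green")).empty
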