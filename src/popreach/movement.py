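"""Movement production: continuous reach trajectories driven by the evolving
location field.

Target selection and movement production run in parallel (interleaved
stepping).  The hand stays at the start position until movement is
initiated; from then on the desired velocity points at the *current* aim
read from the field (the population-vector centroid by default), so
unresolved competition early in the trial leaks into movement curvature.
Velocity relaxes toward the desired velocity with a short time constant
and is capped at a maximum speed; the trial ends when the hand arrives
within ``arrive_radius`` of any item or at the time cap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .design import (
    COLOR_POOL,
    CORNERS,
    Display,
    classify_transition,
    corner_position,
)
from .selection import (
    CompetitionParams,
    FieldParams,
    HistoryModelSpec,
    HistoryStore,
    LocationField,
    SaliencyConfig,
    bias_array,
    compute_saliency,
    conv_matrices,
    feature_maps,
    gate_and_step_location_field,
    history_bias,
    saliency_array,
    step_color_competition,
)

#: Start position of the hand (bottom-center of the workspace), cm.
START_POSITION: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class MovementParams:
    init_threshold: float = 0.4   # field output that triggers movement onset
    gain: float = 4.0             # desired speed per cm of aim-hand error, 1/s
    speed_cap: float = 80.0       # cm/s
    tau_v: float = 40.0           # velocity relaxation time constant, ms
    arrive_radius: float = 1.5    # cm
    dt: float = 2.0               # ms (must match the selection step)
    #: how the aim point is read from the field: "centroid" follows the
    #: activation-weighted population readout (graded leakage), "peak" the
    #: field argmax (all-or-nothing)
    aim: str = "centroid"

    def __post_init__(self) -> None:
        if min(self.init_threshold, self.speed_cap,
               self.tau_v, self.arrive_radius, self.dt) <= 0:
            raise ValueError("movement parameters must be positive")
        if self.gain < 0:
            raise ValueError("gain must be nonnegative")
        if self.aim not in ("centroid", "peak"):
            raise ValueError(f"unknown aim mode {self.aim!r}")


@dataclass
class MovementState:
    pos: np.ndarray
    vel: np.ndarray
    initiated: bool = False

    @classmethod
    def at_start(cls) -> "MovementState":
        return cls(pos=np.array(START_POSITION, dtype=float),
                   vel=np.zeros(2))


@dataclass
class Trajectory:
    """One simulated trial: timed 2D hand positions plus outcome metadata."""

    t: np.ndarray                 # ms
    x: np.ndarray                 # cm
    y: np.ndarray                 # cm
    condition: Optional[str]
    target_corner: str
    resolved: bool                # color competition produced a winner
    correct: bool                 # hand arrived at the true target
    onset_time: Optional[float] = None
    winner_time: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_ms": self.t, "x_cm": self.x, "y_cm": self.y})


def step_movement(
    state: MovementState,
    fld: LocationField,
    params: MovementParams,
    t: float | None = None,
    min_onset: float | None = None,
) -> MovementState:
    """One movement step.  Before initiation the hand is stationary; after,
    velocity relaxes toward ``gain * (aim - pos)`` capped at ``speed_cap``.

    Without ``min_onset``, initiation is the field output crossing
    ``init_threshold`` (this is also how the neutral onset time is
    calibrated).  With ``min_onset`` — the calibrated neutral onset time —
    initiation is time-locked to it, requiring only that the field has a
    defined readout.  The time lock reflects the empirical finding that
    reach initiation latency is essentially constant across inter-trial
    conditions; with a pure threshold rule, history effects that slow
    target selection would delay movement onset by the same amount and
    leave the field state at onset — and hence the trajectory — unchanged.
    """
    if min_onset is None or t is None:
        triggered = fld.max_output >= params.init_threshold
    else:
        triggered = (t >= min_onset
                     and fld.max_output >= fld.params.peak_threshold)
    initiated = state.initiated or triggered
    if not initiated:
        return MovementState(pos=state.pos, vel=state.vel, initiated=False)
    aim = fld.readout() if params.aim == "centroid" else fld.peak()
    vel = state.vel
    if aim is not None:
        v_des = params.gain * (np.array(aim) - state.pos)
        speed = np.linalg.norm(v_des)
        if speed > params.speed_cap:
            v_des *= params.speed_cap / speed
        vel = vel + (v_des - vel) * (params.dt / params.tau_v)
    pos = state.pos + vel * (params.dt / 1000.0)
    return MovementState(pos=pos, vel=vel, initiated=True)


@dataclass(frozen=True)
class SimParams:
    """All tunables of one simulated trial, in one place."""

    saliency: SaliencyConfig = SaliencyConfig()
    competition: CompetitionParams = CompetitionParams()
    field: FieldParams = FieldParams()
    movement: MovementParams = MovementParams()


_ONSET_CACHE: dict[tuple, float] = {}


def calibrate_onset_interval(params: SimParams) -> float:
    """Mean display-onset to movement-onset time over noiseless, history-free
    trials, one per target corner.

    The timed history variants switch at a fraction of the interval between
    display onset and movement onset, which does not exist until a movement
    is produced; a deterministic baseline run breaks that circularity.
    """
    key = (params.saliency, params.competition, params.field, params.movement)
    if key in _ONSET_CACHE:
        return _ONSET_CACHE[key]
    comp = CompetitionParams(**{
        **params.competition.__dict__, "noise_sd": 0.0,
    })
    base = SimParams(saliency=params.saliency, competition=comp,
                     field=params.field, movement=params.movement)
    spec = HistoryModelSpec("M3a", fac_gain=0.0, inh_gain=0.0)
    onsets = []
    for corner in CORNERS:
        traj = simulate_trial(
            prev_display=None,
            cur_display=Display("blue", "purple", corner),
            spec=spec,
            params=base,
            rng=None,
            onset_interval=1.0,
        )
        if traj.onset_time is not None:
            onsets.append(traj.onset_time)
    if not onsets:
        raise RuntimeError("calibration produced no movement onset")
    interval = float(np.mean(onsets))
    _ONSET_CACHE[key] = interval
    return interval


def simulate_trial(
    prev_display: Optional[Display],
    cur_display: Display,
    spec: HistoryModelSpec,
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
    onset_interval: Optional[float] = None,
) -> Trajectory:
    """Simulate one trial: selection and movement stepped in parallel.

    History is taken from ``prev_display`` (None on the first trial).  The
    trial ends when the hand is within ``arrive_radius`` of any item, or at
    the competition time cap, whichever comes first.
    """
    if onset_interval is None:
        onset_interval = calibrate_onset_interval(params)
    store = (HistoryStore() if prev_display is None
             else HistoryStore(prev_display.target_color,
                               prev_display.distractor_color))
    condition = (None if prev_display is None
                 else classify_transition(prev_display, cur_display))

    comp = params.competition
    fp = params.field
    mp = params.movement
    dt = comp.dt
    sal = saliency_array(compute_saliency(cur_display, params.saliency))
    maps = feature_maps(cur_display, fp)

    # the history bias is piecewise constant in time: one array before the
    # switch, one after (identical for the untimed variants)
    t_switch = spec.switch_fraction * onset_interval
    bias_pre = bias_array(history_bias(store, spec, 0.0, onset_interval))
    bias_post = bias_array(
        history_bias(store, spec, t_switch + 1e-9, onset_interval)
    )

    # field geometry and the precomputed smoothing matrices
    fld0 = LocationField.resting(fp)
    gx, gy = np.meshgrid(fld0.xs, fld0.ys)
    Ky, Kx = conv_matrices(fp)

    item_pos = np.array([corner_position(c) for c in CORNERS])
    target_pos = np.array(corner_position(cur_display.target_corner))
    arrive2 = mp.arrive_radius ** 2
    gate = onset_interval if onset_interval > dt else None

    u = np.zeros(len(COLOR_POOL))
    a = fld0.a
    pos = np.array(START_POSITION, dtype=float)
    vel = np.zeros(2)
    initiated = False
    winner = None
    winner_time = None
    onset_time = None
    noise_scale = comp.noise_sd * np.sqrt(dt)

    n_steps = int(round(comp.t_max / dt))
    ts = np.empty(n_steps + 1)
    xs = np.empty(n_steps + 1)
    ys = np.empty(n_steps + 1)
    ts[0], xs[0], ys[0] = 0.0, pos[0], pos[1]
    n_rec = 1
    arrived_at = None
    maps_flat = maps.reshape(len(COLOR_POOL), -1)
    gxf = gx.ravel().copy()
    gyf = gy.ravel().copy()
    shape = a.shape
    dt_tau_u = dt / comp.tau
    dt_tau_a = dt / fp.tau
    dt_tau_v = dt / mp.tau_v
    dt_s = dt / 1000.0
    item_x = item_pos[:, 0]
    item_y = item_pos[:, 1]

    t = 0.0
    for _ in range(n_steps):
        # color competition step (see selection.step_color_competition)
        f = np.maximum(u, 0.0)
        bias = bias_pre if t < t_switch else bias_post
        u = u + (-u + comp.b * f - comp.d * (f.sum() - f)
                 + sal + bias) * dt_tau_u
        if noise_scale > 0.0 and rng is not None:
            u = u + rng.normal(0.0, noise_scale, size=u.shape)
        t += dt
        if winner is None:
            crossed = np.flatnonzero(u >= comp.winner_threshold)
            if crossed.size:
                winner = COLOR_POOL[crossed[np.argmax(u[crossed])]]
                winner_time = t

        # location-field step (see selection.gate_and_step_location_field)
        out = np.maximum(a, 0.0)
        inp = (fp.input_gain * (np.maximum(u, 0.0) @ maps_flat)) \
            .reshape(shape)
        exc = fp.exc_gain * (Ky @ out @ Kx)
        out_sum = float(out.sum())
        a = a + (-a + fp.h + inp + exc - fp.inh_gain * out_sum) * dt_tau_a

        # movement step (see step_movement)
        fmax = float(a.max())
        if not initiated:
            if gate is None:
                initiated = fmax >= mp.init_threshold
            else:
                initiated = t >= gate and fmax >= fp.peak_threshold
            if initiated:
                onset_time = t
        if initiated:
            out_flat = np.maximum(a, 0.0).ravel()
            total = float(out_flat.sum())
            if total > 0.0 and fmax >= fp.peak_threshold:
                if mp.aim == "peak":
                    k_max = int(np.argmax(out_flat))
                    ax_, ay_ = gxf[k_max], gyf[k_max]
                else:
                    ax_ = float(out_flat @ gxf) / total
                    ay_ = float(out_flat @ gyf) / total
                vx = mp.gain * (ax_ - pos[0])
                vy = mp.gain * (ay_ - pos[1])
                speed = (vx * vx + vy * vy) ** 0.5
                if speed > mp.speed_cap:
                    scl = mp.speed_cap / speed
                    vx *= scl
                    vy *= scl
                vel[0] += (vx - vel[0]) * dt_tau_v
                vel[1] += (vy - vel[1]) * dt_tau_v
            pos = pos + vel * dt_s
        ts[n_rec], xs[n_rec], ys[n_rec] = t, pos[0], pos[1]
        n_rec += 1
        if initiated:
            dx_ = item_x - pos[0]
            dy_ = item_y - pos[1]
            d2 = dx_ * dx_ + dy_ * dy_
            k_near = int(np.argmin(d2))
            if d2[k_near] <= arrive2:
                arrived_at = item_pos[k_near]
                break

    correct = bool(
        arrived_at is not None
        and float(((arrived_at - target_pos) ** 2).sum()) <= 1e-12
    )
    return Trajectory(
        t=ts[:n_rec], x=xs[:n_rec], y=ys[:n_rec],
        condition=condition,
        target_corner=cur_display.target_corner,
        resolved=winner is not None,
        correct=correct,
        onset_time=onset_time,
        winner_time=winner_time,
    )


#: Canonical (previous, current) color assignments per condition, the
#: previous display fixed so that its colors match the full-repeat trial.
CONDITION_DISPLAYS: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    "TRDR": (("red", "green"), ("red", "green")),
    "TRDN": (("red", "green"), ("red", "blue")),
    "TNDR": (("red", "green"), ("blue", "green")),
    "TSDN": (("red", "green"), ("green", "blue")),
    "TNDS": (("red", "green"), ("blue", "red")),
    "TSDS": (("red", "green"), ("green", "red")),
    "TNDN": (("red", "green"), ("blue", "purple")),
}


def simulate_condition_trials(
    spec: HistoryModelSpec,
    params: SimParams,
    n_reps: int,
    seed: int,
    conditions: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Simulate ``n_reps`` trials for each condition and return a tidy
    trajectory table (one synthetic participant).

    Target corners cycle deterministically through the four corners across
    repetitions so every corner contributes to the baseline; the competition
    noise stream is seeded per (condition, repetition).
    """
    if conditions is None:
        conditions = list(CONDITION_DISPLAYS)
    onset_interval = calibrate_onset_interval(params)
    rows = []
    for cond in conditions:
        (pt, pd_), (ct, cd) = CONDITION_DISPLAYS[cond]
        for rep in range(n_reps):
            corner = CORNERS[rep % len(CORNERS)]
            cond_id = list(CONDITION_DISPLAYS).index(cond)
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, cond_id, rep])
            )
            traj = simulate_trial(
                Display(pt, pd_, corner),
                Display(ct, cd, corner),
                spec, params, rng=rng, onset_interval=onset_interval,
            )
            df = traj.to_frame()
            df.insert(0, "participant", 1)
            df.insert(1, "trial", rep + 1)
            df.insert(2, "condition", cond)
            df.insert(3, "target_corner", corner)
            df["resolved"] = traj.resolved
            df["correct"] = traj.correct
            rows.append(df)
    return pd.concat(rows, ignore_index=True)


def simulate_experiment(
    spec: HistoryModelSpec,
    params: SimParams,
    n_reps: int = 21,
    seed: int = 0,
):
    """Simulate the seven-condition experiment and run the trajectory
    pipeline, returning per-condition mean attraction profiles.

    Returns an :class:`popreach.analysis.ExperimentProfiles` with the mean
    profile per condition (baseline-subtracted against the simulated
    no-history condition), per-repetition profiles, and the unresolved and
    error fractions in ``meta``.
    """
    from .analysis import AnalysisConfig, analyze_trajectories

    table = simulate_condition_trials(spec, params, n_reps, seed)
    dt_s = params.competition.dt / 1000.0
    cfg = AnalysisConfig(sample_rate_hz=1.0 / dt_s)
    profiles = analyze_trajectories(table, cfg)
    bad = table.groupby(["condition", "trial"]).agg(
        resolved=("resolved", "first"), correct=("correct", "first")
    )
    profiles.meta["unresolved_fraction"] = float(1.0 - bad["resolved"].mean())
    profiles.meta["error_fraction"] = float(1.0 - bad["correct"].mean())
    profiles.meta["n_reps"] = n_reps
    return profiles
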