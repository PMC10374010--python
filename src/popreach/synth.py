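"""Surrogate multi-participant reach datasets with planted condition effects.

No human reach data are distributed with this package, so synthetic
trajectory tables are the test surface for the analysis pipeline.  Each
trial is a straight start-to-target path with a minimum-jerk speed profile,
plus lateral deviations shaped as Gaussian bumps over path fraction (signed
toward the distractors for positive amplitudes), plus per-sample Gaussian
position noise.  Every bump belongs to a named latent *factor*; each
participant draws one scale per factor, shared by all conditions that load
on it.  That between-participant covariance is what lets the principal
component regression recover the planted factor structure.  TNDN trials
always carry zero planted effect: they are the baseline the attraction
score is defined against.

The default sampling rate (240 Hz) and position noise (0.03 cm RMS) match a
typical electromagnetic motion tracker; movement duration 600 ms with 150 ms
of stationary lead-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .design import CONDITIONS, CORNERS, corner_position
from .movement import START_POSITION


@dataclass
class ConditionEffect:
    """One planted lateral-deviation component: a Gaussian bump in the
    path-fraction domain.  Positive amplitude deviates toward the
    distractors, negative toward the target.  ``factor`` names the latent
    participant factor the bump scales with (None: unscaled)."""

    amplitude: float        # cm, peak lateral deviation
    center: float = 0.45    # fraction of path length
    width: float = 0.15     # SD in path fraction
    factor: str | None = None

    def profile(self, frac: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(
            -((frac - self.center) ** 2) / (2.0 * self.width ** 2)
        )


@dataclass
class EffectSpec:
    """Full description of a synthetic dataset.  ``effects`` maps a
    condition label to one bump or a sequence of bumps."""

    effects: dict = dc_field(default_factory=dict)
    n_participants: int = 21
    trials_per_condition: int = 20
    between_participant_sd: float = 0.3   # multiplicative factor scatter
    noise_sd: float = 0.03                # cm per sample
    sample_rate_hz: float = 240.0
    movement_ms: float = 600.0
    lead_in_ms: float = 150.0
    conditions: tuple[str, ...] = CONDITIONS
    seed: int = 0

    def __post_init__(self) -> None:
        normalized = {}
        for cond, eff in self.effects.items():
            effs = (eff,) if isinstance(eff, ConditionEffect) else tuple(eff)
            for e in effs:
                if not np.isfinite(e.amplitude):
                    raise ValueError(f"non-finite amplitude for {cond}")
                if e.width <= 0:
                    raise ValueError(f"non-positive width for {cond}")
            normalized[cond] = effs
        self.effects = normalized

    def factor_names(self) -> list[str]:
        names = []
        for effs in self.effects.values():
            for e in effs:
                if e.factor is not None and e.factor not in names:
                    names.append(e.factor)
        return names


def _min_jerk_fraction(t_frac: np.ndarray) -> np.ndarray:
    """Minimum-jerk position fraction along the path for time fraction
    in [0, 1]."""
    s = np.clip(t_frac, 0.0, 1.0)
    return 10 * s**3 - 15 * s**4 + 6 * s**5


def _lateral_direction(corner: str) -> np.ndarray:
    """Unit vector perpendicular to the straight start-to-corner line,
    oriented toward the centroid of the three distractor corners."""
    start = np.array(START_POSITION)
    tgt = np.array(corner_position(corner))
    direction = tgt - start
    direction /= np.linalg.norm(direction)
    perp = np.array([-direction[1], direction[0]])
    others = [np.array(corner_position(c)) for c in CORNERS if c != corner]
    centroid = np.mean(others, axis=0)
    if perp @ (centroid - (start + tgt) / 2.0) < 0:
        perp = -perp
    return perp


def gen_trajectory_dataset(spec: EffectSpec) -> pd.DataFrame:
    """Generate a tidy trajectory table with the planted effects.

    Columns match the analysis pipeline's input: participant, trial,
    condition, target_corner, t_ms, x_cm, y_cm.
    """
    rng = np.random.default_rng(spec.seed)
    dt_ms = 1000.0 / spec.sample_rate_hz
    n_lead = int(round(spec.lead_in_ms / dt_ms))
    n_move = int(round(spec.movement_ms / dt_ms))
    n_tail = max(4, n_lead // 2)
    n_total = n_lead + n_move + n_tail
    t_ms = np.arange(n_total) * dt_ms
    move_frac = np.zeros(n_total)
    move_frac[n_lead:n_lead + n_move] = _min_jerk_fraction(
        np.arange(n_move) / (n_move - 1.0)
    )
    move_frac[n_lead + n_move:] = 1.0
    factor_names = spec.factor_names()

    # precompute straight base paths and lateral unit vectors per corner
    start = np.array(START_POSITION)
    base_paths = {
        c: start[None, :] + move_frac[:, None]
        * (np.array(corner_position(c)) - start)
        for c in CORNERS
    }
    laterals = {c: _lateral_direction(c) for c in CORNERS}

    cols = {k: [] for k in ("participant", "trial", "condition",
                            "target_corner", "t_ms", "x_cm", "y_cm")}
    for p in range(1, spec.n_participants + 1):
        # one scale per latent factor, shared across this participant's
        # conditions; unnamed bumps are left unscaled
        scales = {
            f: 1.0 + spec.between_participant_sd * rng.standard_normal()
            for f in factor_names
        }
        for ci, cond in enumerate(spec.conditions):
            effs = spec.effects.get(cond, ())
            planted = np.zeros(n_total)
            if cond != "TNDN":
                for e in effs:
                    planted += scales.get(e.factor, 1.0) * e.profile(move_frac)
            for trial in range(1, spec.trials_per_condition + 1):
                corner = CORNERS[(trial - 1) % len(CORNERS)]
                pos = base_paths[corner]
                if effs and cond != "TNDN":
                    pos = pos + planted[:, None] * laterals[corner][None, :]
                pos = pos + rng.normal(0.0, spec.noise_sd, size=pos.shape)
                cols["participant"].append(np.full(n_total, p))
                cols["trial"].append(np.full(
                    n_total, ci * spec.trials_per_condition + trial))
                cols["condition"].append(np.full(n_total, cond, dtype=object))
                cols["target_corner"].append(
                    np.full(n_total, corner, dtype=object))
                cols["t_ms"].append(t_ms)
                cols["x_cm"].append(pos[:, 0])
                cols["y_cm"].append(pos[:, 1])
    return pd.DataFrame({k: np.concatenate(v) for k, v in cols.items()})


def gen_null_dataset(
    n_participants: int = 21,
    n_trials: int = 20,
    noise: float = 0.03,
    seed: int = 0,
    conditions: tuple[str, ...] = CONDITIONS,
) -> pd.DataFrame:
    """Dataset with no planted effect anywhere: all conditions are
    exchangeable.  Used for type-I-error calibration of the cluster test."""
    spec = EffectSpec(
        effects={},
        n_participants=n_participants,
        trials_per_condition=n_trials,
        noise_sd=noise,
        between_participant_sd=0.0,
        conditions=conditions,
        seed=seed,
    )
    return gen_trajectory_dataset(spec)


def two_factor_spec(
    early_amp: float = 0.8,
    late_amp: float = 0.8,
    early_center: float = 0.30,
    late_center: float = 0.60,
    width: float = 0.12,
    n_participants: int = 21,
    trials_per_condition: int = 12,
    between_participant_sd: float = 1.0,
    seed: int = 0,
) -> EffectSpec:
    """The early-inhibition / late-facilitation plant.

    Conditions in which the previous *distractor* color reappears (TSDN
    toward distractors, TNDR toward the target) load on an early factor;
    conditions in which the previous *target* color reappears (TNDS toward
    distractors, TRDN toward the target) load on a late factor.  The full
    conditions carry both bumps, so the pop-out contrast (TSDS - TRDR) is
    driven by the same two participant factors the partial conditions
    expose — the generative analogue of an early distractor-inhibition
    component and a late target-facilitation component.
    """
    def early(amp):
        return ConditionEffect(amp, center=early_center, width=width,
                               factor="early")

    def late(amp):
        return ConditionEffect(amp, center=late_center, width=width,
                               factor="late")

    effects = {
        "TSDN": early(+early_amp),
        "TNDR": early(-early_amp),
        "TNDS": late(+late_amp),
        "TRDN": late(-late_amp),
        "TSDS": (early(+early_amp), late(+late_amp)),
        "TRDR": (early(-early_amp), late(-late_amp)),
    }
    return EffectSpec(
        effects=effects,
        n_participants=n_participants,
        trials_per_condition=trials_per_condition,
        between_participant_sd=between_participant_sd,
        seed=seed,
    )
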