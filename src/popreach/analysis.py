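"""Reach-trajectory preprocessing and the signed attraction score.

The pipeline mirrors standard reach-tracking practice:

1. resultant hand speed by numerical differentiation, smoothed with a
   zero-phase second-order low-pass Butterworth filter (10 Hz cutoff);
2. movement onset/offset at a 15 cm/s speed threshold (with per-trial
   manual overrides for the rare trials the threshold mishandles);
3. spatial (functional) normalization of the onset-offset segment to 100
   points at equal increments of cumulative path length;
4. per-trial horizontal/vertical deviation from the corner-matched mean
   no-history (TNDN) trajectory, signed so that deviation toward the
   distractors is positive and deviation toward the target negative;
5. the combined attraction score: the Euclidean magnitude of the deviation
   carrying the sign of whichever axis deviates more (ties go to the
   horizontal axis).

Condition-level profiles combine the across-trial *mean* horizontal and
vertical deviations, which makes the TNDN profile identically zero by
construction — TNDN is the baseline, not an effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, filtfilt

BASELINE_CONDITION = "TNDN"


@dataclass
class AnalysisConfig:
    filter_order: int = 2
    cutoff_hz: float = 10.0
    onset_speed: float = 15.0       # cm/s
    offset_speed: float = 15.0      # cm/s
    n_points: int = 100
    sample_rate_hz: float = 240.0
    #: minimum time the speed must stay above the onset threshold for a
    #: crossing to count as movement onset; rejects filter edge transients
    #: (a programmatic stand-in for visually inspecting flagged trials)
    min_onset_ms: float = 50.0
    #: per-trial (onset_idx, offset_idx) overrides, keyed by trial id;
    #: stands in for manual inspection of flagged trials.
    manual_overrides: dict = dc_field(default_factory=dict)
    #: trials with a larger fraction of missing samples are excluded
    max_drop_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.cutoff_hz >= self.sample_rate_hz / 2.0:
            raise ValueError("filter cutoff must be below the Nyquist rate")


class NoMovementError(ValueError):
    """Speed never crossed the onset threshold."""


def compute_filtered_speed(
    t_ms: np.ndarray,
    pos: np.ndarray,
    config: AnalysisConfig,
) -> np.ndarray:
    """Resultant speed (cm/s) from timed positions, low-pass filtered.

    ``pos`` is (n, 2) or (n, 3); differentiation is done per axis and the
    resultant is filtered forward-backward (zero phase).
    """
    t_ms = np.asarray(t_ms, dtype=float)
    pos = np.asarray(pos, dtype=float)
    if t_ms.size < 3:
        raise ValueError("need at least 3 samples")
    if np.any(np.diff(t_ms) <= 0):
        raise ValueError("time stamps must be strictly increasing")
    t_s = t_ms / 1000.0
    vel = np.stack([np.gradient(pos[:, i], t_s) for i in range(pos.shape[1])])
    speed = np.linalg.norm(vel, axis=0)
    b, a = _butter_coeffs(config.filter_order, config.cutoff_hz,
                          config.sample_rate_hz)
    padlen = min(3 * (max(len(a), len(b)) - 1), speed.size - 1)
    return filtfilt(b, a, speed, padlen=padlen)


@lru_cache(maxsize=32)
def _butter_coeffs(order: int, cutoff: float, fs: float):
    return butter(order, cutoff, fs=fs)


def detect_movement_bounds(
    speed: np.ndarray,
    config: AnalysisConfig,
    trial_id=None,
) -> tuple[int, int]:
    """First onset-threshold crossing and the first subsequent drop below
    the offset threshold.  A manual override for ``trial_id`` wins.  If the
    speed never drops back below threshold the last sample is the offset.
    """
    if trial_id is not None and trial_id in config.manual_overrides:
        return tuple(config.manual_overrides[trial_id])
    above = speed > config.onset_speed
    min_run = max(1, int(round(config.min_onset_ms
                               * config.sample_rate_hz / 1000.0)))
    onset = None
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= min_run:
            onset = i - min_run + 1
            break
    if onset is None:
        raise NoMovementError(f"trial {trial_id}: no movement detected")
    below = np.flatnonzero(speed[onset + min_run:] < config.offset_speed)
    offset = (int(onset + min_run + below[0]) if below.size
              else speed.size - 1)
    return onset, offset


def spatial_normalize(
    pos: np.ndarray,
    n_points: int = 100,
) -> np.ndarray:
    """Resample an (n, 2) position segment at ``n_points`` equal increments
    of cumulative path length (monotone piecewise-cubic interpolation of
    each coordinate against arc length)."""
    pos = np.asarray(pos, dtype=float)
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(steps)])
    if s[-1] <= 0:
        raise ValueError("zero-length path cannot be normalized")
    # collapse stationary samples so arc length is strictly increasing
    keep = np.concatenate([[True], np.diff(s) > 0])
    s, pos = s[keep], pos[keep]
    targets = np.linspace(0.0, s[-1], n_points)
    if s.size == 2:  # a straight two-point segment: interpolate linearly
        return np.stack(
            [np.interp(targets, s, pos[:, i]) for i in range(pos.shape[1])],
            axis=1,
        )
    return PchipInterpolator(s, pos, axis=0)(targets)


def corner_deviation_signs(corner: str) -> tuple[float, float]:
    """Axis signs mapping raw (dx, dy) deviations to the toward-distractor
    convention.  The positive direction on each axis points from the target
    corner toward the opposite side of the square (e.g. for a top-left
    target, rightward and downward deviations are positive)."""
    sx = 1.0 if corner[1] == "L" else -1.0
    sy = 1.0 if corner[0] == "B" else -1.0
    return sx, sy


def combine_deviation(sdx: np.ndarray, sdy: np.ndarray) -> np.ndarray:
    """Euclidean magnitude of the signed deviations, carrying the sign of
    whichever axis has the larger absolute deviation (ties: horizontal)."""
    sdx = np.asarray(sdx, dtype=float)
    sdy = np.asarray(sdy, dtype=float)
    mag = np.hypot(sdx, sdy)
    sign = np.where(np.abs(sdx) >= np.abs(sdy), np.sign(sdx), np.sign(sdy))
    return mag * sign


@dataclass
class ExperimentProfiles:
    """Attraction-score profiles for one dataset.

    ``participant_scores[cond]`` is an (n_participants, n_points) array of
    per-participant condition profiles (combined from mean deviations);
    ``trial_scores`` holds per-trial combined profiles in wide format.
    """

    distances: np.ndarray
    participants: list
    participant_scores: dict[str, np.ndarray]
    trial_scores: pd.DataFrame
    meta: dict = dc_field(default_factory=dict)

    def mean_profile(self, condition: str) -> np.ndarray:
        return self.participant_scores[condition].mean(axis=0)

    def conditions(self) -> list[str]:
        return list(self.participant_scores)

    def scores_matrix(self, condition: str) -> np.ndarray:
        return self.participant_scores[condition]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cond, mat in self.participant_scores.items():
            for pi, participant in enumerate(self.participants):
                rows.append(pd.DataFrame({
                    "participant": participant,
                    "condition": cond,
                    "distance_pct": self.distances,
                    "attraction_cm": mat[pi],
                }))
        return pd.concat(rows, ignore_index=True)


def _normalize_trial(
    t: np.ndarray, pos: np.ndarray, config: AnalysisConfig, trial_id
) -> Optional[np.ndarray]:
    """Filter, bound and spatially normalize one trial; None if excluded."""
    order = np.argsort(t, kind="stable")
    t, pos = t[order], pos[order]
    drop = np.isnan(pos).any(axis=1)
    if drop.mean() > config.max_drop_fraction:
        return None  # excessive sampling drop
    if drop.any():
        t, pos = t[~drop], pos[~drop]
    try:
        speed = compute_filtered_speed(t, pos, config)
        onset, offset = detect_movement_bounds(speed, config, trial_id)
    except (NoMovementError, ValueError):
        return None
    if offset - onset < 1:
        return None
    try:
        return spatial_normalize(pos[onset:offset + 1, :2], config.n_points)
    except ValueError:
        return None


def analyze_trajectories(
    table: pd.DataFrame,
    config: AnalysisConfig = None,
) -> ExperimentProfiles:
    """Run the full pipeline on a tidy trajectory table.

    The table has one row per sample with columns ``participant``,
    ``trial``, ``condition``, ``target_corner``, ``t_ms``, ``x_cm``,
    ``y_cm`` (optionally ``z_cm``, ``resolved``, ``correct``).  Trials
    flagged unresolved/incorrect, with no detectable movement, or with
    excessive sample drop are excluded, as are trials whose *previous*
    trial was excluded when a ``prev_correct`` column is present.
    """
    if config is None:
        config = AnalysisConfig()
    work = table
    for flag in ("resolved", "correct", "prev_correct"):
        if flag in work.columns:
            work = work[work[flag].astype(bool)]

    # normalize every usable trial; one numpy pass over the sorted table
    pos_cols = ["x_cm", "y_cm"] + (["z_cm"] if "z_cm" in work.columns else [])
    codes, _ = pd.factorize(
        work["participant"].astype(str) + "\x00"
        + work["condition"].astype(str) + "\x00"
        + work["trial"].astype(str)
    )
    order = np.argsort(codes, kind="stable")
    work = work.iloc[order]
    codes = codes[order]
    t_all = work["t_ms"].to_numpy(dtype=float)
    pos_all = work[pos_cols].to_numpy(dtype=float)
    part_all = work["participant"].to_numpy()
    cond_all = work["condition"].to_numpy()
    trial_all = work["trial"].to_numpy()
    corner_all = work["target_corner"].to_numpy()
    bounds = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate([[0], bounds])
    ends = np.concatenate([bounds, [codes.size]])

    norm: dict[tuple, np.ndarray] = {}
    info: dict[tuple, tuple[str, str]] = {}
    n_excluded = 0
    for lo, hi in zip(starts, ends):
        key = (part_all[lo], cond_all[lo], trial_all[lo])
        prof = _normalize_trial(t_all[lo:hi], pos_all[lo:hi], config,
                                trial_id=key)
        if prof is None:
            n_excluded += 1
            continue
        norm[key] = prof
        info[key] = (corner_all[lo], key[1])

    participants = sorted({k[0] for k in norm})
    conditions = sorted({k[1] for k in norm})

    # per-participant, per-corner TNDN baseline
    baseline_acc: dict[tuple, list] = {}
    grouped: dict[tuple, list] = {}
    for key, prof in norm.items():
        p, cond, _ = key
        corner = info[key][0]
        if cond == BASELINE_CONDITION:
            baseline_acc.setdefault((p, corner), []).append(prof)
        grouped.setdefault((p, cond), []).append((key, corner, prof))
    baselines = {k: np.mean(v, axis=0) for k, v in baseline_acc.items()}

    n_pts = config.n_points
    distances = np.arange(1, n_pts + 1)
    part_scores = {
        c: np.zeros((len(participants), n_pts)) for c in conditions
    }
    trial_rows = []
    for cond in conditions:
        for pi, p in enumerate(participants):
            sdx_all, sdy_all = [], []
            for key, corner, prof in grouped.get((p, cond), []):
                if (p, corner) not in baselines:
                    raise ValueError(
                        f"no {BASELINE_CONDITION} baseline for participant "
                        f"{p!r}, corner {corner!r}"
                    )
                base = baselines[(p, corner)]
                sx, sy = corner_deviation_signs(corner)
                sdx = (prof[:, 0] - base[:, 0]) * sx
                sdy = (prof[:, 1] - base[:, 1]) * sy
                sdx_all.append(sdx)
                sdy_all.append(sdy)
                row = {"participant": p, "condition": cond, "trial": key[2]}
                row.update({
                    f"d{d}": v
                    for d, v in zip(distances, combine_deviation(sdx, sdy))
                })
                trial_rows.append(row)
            if sdx_all:
                part_scores[cond][pi] = combine_deviation(
                    np.mean(sdx_all, axis=0), np.mean(sdy_all, axis=0)
                )
    trial_scores = pd.DataFrame(trial_rows)
    return ExperimentProfiles(
        distances=distances,
        participants=participants,
        participant_scores=part_scores,
        trial_scores=trial_scores,
        meta={"n_excluded_trials": n_excluded},
    )
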