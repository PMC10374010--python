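"""Goodness of fit, grid search and five-way history-model comparison.

A candidate history model is scored by simulating the seven-condition
experiment at each grid point and measuring the root-mean-square difference
between its six non-baseline mean attraction profiles and the reference
profiles, over all conditions and distances.  Common random numbers (a
fixed seed ladder reused at every grid point) keep the comparison variance
down.  Per-repetition errors (each repetition's profiles against the
reference mean) provide paired uncertainty across models.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field as dc_field

import numpy as np

from .movement import SimParams, simulate_experiment
from .selection import HistoryModelSpec

#: Conditions entering the fit (everything except the TNDN baseline).
FIT_CONDITIONS: tuple[str, ...] = (
    "TRDR", "TRDN", "TNDR", "TSDN", "TNDS", "TSDS",
)


@dataclass
class FitConfig:
    """Grid-search settings.  ``grid`` maps parameter names (``fac_gain``,
    ``inh_gain``, ``switch_fraction``) to candidate values; only the
    parameters free in a given variant are swept."""

    grid: dict = dc_field(default_factory=lambda: {
        "fac_gain": [0.15, 0.30],
        "inh_gain": [0.30, 0.60],
        "switch_fraction": [0.40, 0.65],
    })
    n_reps: int = 21
    seed: int = 0
    sim_params: SimParams = dc_field(default_factory=SimParams)

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("grid value lists must be nonempty")


@dataclass
class FitResult:
    variant: str
    best_params: dict
    error: float
    table: list                      # (params dict, error) per grid point
    n_reps: int
    rep_errors: np.ndarray | None = None   # per-repetition errors at best fit
    profiles: object = None                # ExperimentProfiles at best fit

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "best_params": self.best_params,
            "error": self.error,
            "n_reps": self.n_reps,
            "table": [
                {"params": p, "error": e} for p, e in self.table
            ],
        }


def profiles_to_reference(profiles) -> dict[str, np.ndarray]:
    """Mean attraction profile per fit condition from an
    ExperimentProfiles."""
    return {c: profiles.mean_profile(c) for c in FIT_CONDITIONS}


def goodness_of_fit(
    sim: dict[str, np.ndarray],
    ref: dict[str, np.ndarray],
) -> float:
    """RMS difference over the six non-baseline conditions and all
    distances, in attraction-score units (cm)."""
    if set(FIT_CONDITIONS) - set(sim) or set(FIT_CONDITIONS) - set(ref):
        raise ValueError("both profile sets must contain all fit conditions")
    sq = 0.0
    n = 0
    for c in FIT_CONDITIONS:
        s, r = np.asarray(sim[c]), np.asarray(ref[c])
        if s.shape != r.shape:
            raise ValueError(f"profile shapes differ for {c}")
        sq += float(((s - r) ** 2).sum())
        n += s.size
    return float(np.sqrt(sq / n))


def _grid_points(variant: str, grid: dict) -> list[dict]:
    free = HistoryModelSpec(variant).free_parameters
    names = [n for n in ("fac_gain", "inh_gain", "switch_fraction")
             if n in free]
    combos = itertools.product(*(grid.get(n, [None]) for n in names))
    points = []
    for combo in combos:
        params = {n: v for n, v in zip(names, combo) if v is not None}
        if params not in points:
            points.append(params)
    return points


def _rep_errors(profiles, ref: dict[str, np.ndarray]) -> np.ndarray:
    """Per-repetition RMS errors against the reference means, using the
    per-trial combined profiles."""
    trial = profiles.trial_scores
    dist_cols = [c for c in trial.columns if c.startswith("d")]
    reps = sorted(trial["trial"].unique())
    errors = []
    for rep in reps:
        sq, n = 0.0, 0
        for c in FIT_CONDITIONS:
            rows = trial[(trial["condition"] == c) & (trial["trial"] == rep)]
            if rows.empty:
                continue
            prof = rows[dist_cols].to_numpy(dtype=float).mean(axis=0)
            sq += float(((prof - ref[c]) ** 2).sum())
            n += prof.size
        if n:
            errors.append(np.sqrt(sq / n))
    return np.array(errors)


def grid_search_fit(
    variant: str,
    ref: dict[str, np.ndarray],
    config: FitConfig,
) -> FitResult:
    """Sweep the variant's free parameters and return the best fit.

    The same seed ladder is used at every grid point (common random
    numbers), so grid points differ only through the parameters.
    """
    table = []
    best = None
    for params in _grid_points(variant, config.grid):
        spec = HistoryModelSpec(variant, **params)
        profiles = simulate_experiment(
            spec, config.sim_params, n_reps=config.n_reps, seed=config.seed
        )
        try:
            sim = profiles_to_reference(profiles)
            err = goodness_of_fit(sim, ref)
        except KeyError:
            # a condition lost every trial to erroneous target selection:
            # this parameterization cannot reproduce the reference at all
            err = float("inf")
        table.append((params, err))
        if best is None or err < best[1]:
            best = (params, err, profiles)
    params, err, profiles = best
    return FitResult(
        variant=variant,
        best_params=params,
        error=err,
        table=table,
        n_reps=config.n_reps,
        rep_errors=_rep_errors(profiles, ref),
        profiles=profiles,
    )


def compare_history_models(
    ref: dict[str, np.ndarray],
    config: FitConfig,
    variants: tuple[str, ...] = HistoryModelSpec.VARIANTS,
) -> list[FitResult]:
    """Grid-search every history variant against the reference and rank
    the results by error (best first)."""
    results = [grid_search_fit(v, ref, config) for v in variants]
    results.sort(key=lambda r: r.error)
    return results
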