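"""Principal component regression across reach distances.

At every distance in the analysis range (11-90% by default) a PCA is run on
the participants x 4 matrix of partial-condition attraction scores (TRDN,
TNDR, TSDN, TNDS; columns centered).  Because the sign of a principal
component is arbitrary, loadings are aligned across distances: sweeping the
range in order, a component's sign is flipped whenever the angle between its
loading vector and the previous distance's exceeds 120 degrees (dot product
below cos 120 = -0.5 on unit-norm loadings).

The component scores are then regressed, per distance and without an
intercept, onto the pop-out effect (the attraction-score difference between
the full-swap and full-repeat conditions).  Components are interpreted via
loading runs: within distances where a component's regression is
significant, a condition counts as loading on the component if its absolute
loading exceeds 0.35 for at least 15% of consecutive distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import statsmodels.api as sm

from .design import PARTIAL_CONDITIONS


@dataclass
class PCRConfig:
    distance_range: tuple[int, int] = (11, 90)   # percent, inclusive
    n_pcs: int = 3
    loading_cutoff: float = 0.35
    min_run_frac: float = 0.15
    flip_angle_deg: float = 120.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        lo, hi = self.distance_range
        if not (1 <= lo < hi <= 100):
            raise ValueError("distance_range must lie within 1-100")
        if not (1 <= self.n_pcs <= 4):
            raise ValueError("n_pcs must be between 1 and 4")

    @property
    def distances(self) -> np.ndarray:
        lo, hi = self.distance_range
        return np.arange(lo, hi + 1)

    @property
    def min_run_points(self) -> int:
        return int(np.ceil(self.min_run_frac * self.distances.size))


@dataclass
class PCRResult:
    distances: np.ndarray            # (D,) percent values analyzed
    loadings: np.ndarray             # (D, 4, n_pcs), unit-norm columns
    scores: np.ndarray               # (D, participants, n_pcs)
    variance_explained: np.ndarray   # (D, n_pcs)
    coef: np.ndarray | None = None   # (D, n_pcs)
    r2: np.ndarray | None = None     # (D,)
    pvalues: np.ndarray | None = None  # (D, n_pcs)
    factors: list = dc_field(default_factory=list)
    conditions: tuple[str, ...] = PARTIAL_CONDITIONS


def pca_over_distances(
    partial_scores: np.ndarray,
    config: PCRConfig = None,
) -> PCRResult:
    """Per-distance PCA of the partial-condition scores with sign alignment.

    ``partial_scores`` is (participants, 4, distances) in
    ``PARTIAL_CONDITIONS`` order over the full 1-100% grid; only the
    configured distance range is analyzed.
    """
    if config is None:
        config = PCRConfig()
    X = np.asarray(partial_scores, dtype=float)
    if X.ndim != 3 or X.shape[1] != len(PARTIAL_CONDITIONS):
        raise ValueError(
            f"expected (participants, {len(PARTIAL_CONDITIONS)}, distances)"
        )
    if X.shape[0] < 5:
        raise ValueError("need at least 5 participants")
    dists = config.distances
    n_p = X.shape[0]
    k = config.n_pcs
    loadings = np.empty((dists.size, 4, k))
    scores = np.empty((dists.size, n_p, k))
    varexp = np.empty((dists.size, k))
    cos_flip = float(np.cos(np.deg2rad(config.flip_angle_deg)))
    for di, d in enumerate(dists):
        M = X[:, :, d - 1]
        Mc = M - M.mean(axis=0, keepdims=True)
        # SVD of the centered matrix: columns of V are the loading vectors
        _, sv, vt = np.linalg.svd(Mc, full_matrices=False)
        var = sv ** 2
        total = var.sum()
        L = vt[:k].T                       # (4, k), unit columns
        S = Mc @ L                         # (participants, k)
        # deterministic within-distance orientation: largest-|.| entry >= 0
        for j in range(k):
            lead = np.argmax(np.abs(L[:, j]))
            if L[lead, j] < 0:
                L[:, j] *= -1.0
                S[:, j] *= -1.0
        loadings[di] = L
        scores[di] = S
        varexp[di] = var[:k] / total if total > 0 else 0.0
    # component tracking: the variance ranking of two latent factors can
    # cross mid-reach, which would splice different factors into one
    # "component"; match each distance's components to the previous
    # distance's by absolute loading similarity before aligning signs
    for di in range(1, dists.size):
        prev = loadings[di - 1]
        sim = np.abs(prev.T @ loadings[di])        # (k_prev, k_cur)
        order = np.full(k, -1)
        taken = set()
        for _ in range(k):
            i, j = np.unravel_index(np.argmax(sim), sim.shape)
            order[i] = j
            taken.add(j)
            sim[i, :] = -1.0
            sim[:, j] = -1.0
        loadings[di] = loadings[di][:, order]
        scores[di] = scores[di][:, order]
        varexp[di] = varexp[di][order]
        # sign alignment across distances
        for j in range(k):
            if float(prev[:, j] @ loadings[di, :, j]) < cos_flip:
                loadings[di, :, j] *= -1.0
                scores[di, :, j] *= -1.0
    return PCRResult(
        distances=dists, loadings=loadings, scores=scores,
        variance_explained=varexp,
    )


def regress_pop(
    result: PCRResult,
    pop_effect: np.ndarray,
    config: PCRConfig = None,
) -> PCRResult:
    """No-intercept regression of the pop-out effect on the component
    scores at every analyzed distance.

    ``pop_effect`` is (participants, distances) over the full 1-100% grid:
    attraction(TSDS) - attraction(TRDR) per participant.  Fills ``coef``,
    ``r2`` (uncentered, as appropriate for a through-origin model) and
    per-component ``pvalues`` on the result.  Collinear score columns are
    dropped from the fit; their coefficient and p are NaN at that distance.
    """
    if config is None:
        config = PCRConfig()
    y_all = np.asarray(pop_effect, dtype=float)
    D = result.distances.size
    k = result.scores.shape[2]
    coef = np.full((D, k), np.nan)
    pvals = np.full((D, k), np.nan)
    r2 = np.full(D, np.nan)
    for di, d in enumerate(result.distances):
        Xd = result.scores[di]
        y = y_all[:, d - 1]
        keep = Xd.std(axis=0) > 1e-12
        # guard against collinearity among retained columns
        if keep.sum() > 1:
            sub = Xd[:, keep]
            rank = np.linalg.matrix_rank(sub)
            while rank < sub.shape[1]:
                idx = np.flatnonzero(keep)
                keep[idx[-1]] = False
                sub = Xd[:, keep]
                rank = np.linalg.matrix_rank(sub) if keep.any() else 0
        if not keep.any():
            continue
        fit = sm.OLS(y, Xd[:, keep]).fit()
        coef[di, keep] = fit.params
        pvals[di, keep] = fit.pvalues
        r2[di] = fit.rsquared
    # orient each component globally so its average coefficient on the
    # pop-out effect is positive: a PC's overall sign is arbitrary, and
    # this convention makes loading signs directly interpretable against
    # the (positive) pop-out contrast
    for j in range(k):
        if np.nanmean(coef[:, j]) < 0:
            coef[:, j] *= -1.0
            result.loadings[:, :, j] *= -1.0
            result.scores[:, :, j] *= -1.0
    result.coef, result.pvalues, result.r2 = coef, pvals, r2
    return result


@dataclass
class FactorRun:
    pc: int                     # 0-based component index
    condition: str
    sign: int                   # +1 / -1
    start_pct: int
    end_pct: int
    mean_loading: float


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) index pairs of maximal True runs."""
    out = []
    start = None
    for i, m in enumerate(list(mask) + [False]):
        if m and start is None:
            start = i
        elif not m and start is not None:
            out.append((start, i - 1))
            start = None
    return out


def loading_runs(result: PCRResult, config: PCRConfig = None) -> list[FactorRun]:
    """Interpret components: conditions whose |loading| exceeds the cutoff
    over a sufficiently long consecutive run of distances at which the
    component's regression coefficient is significant."""
    if config is None:
        config = PCRConfig()
    if result.pvalues is None:
        raise ValueError("run regress_pop before loading_runs")
    min_len = config.min_run_points
    factors: list[FactorRun] = []
    for j in range(result.scores.shape[2]):
        sig = result.pvalues[:, j] < config.alpha
        # loadings are interpreted in the frame where the component's local
        # regression coefficient on the pop-out effect is positive; within
        # significant distances that sign is well determined, and it makes
        # loading signs comparable across components and datasets
        eff = result.loadings[:, :, j] * np.sign(result.coef[:, j])[:, None]
        for ci, cond in enumerate(result.conditions):
            load = eff[:, ci]
            for sign in (1, -1):
                mask = sig & (sign * load >= config.loading_cutoff)
                for start, end in _runs(mask):
                    if end - start + 1 >= min_len:
                        factors.append(FactorRun(
                            pc=j, condition=cond, sign=sign,
                            start_pct=int(result.distances[start]),
                            end_pct=int(result.distances[end]),
                            mean_loading=float(load[start:end + 1].mean()),
                        ))
    result.factors = factors
    return factors


def partial_scores_array(profiles, conditions=PARTIAL_CONDITIONS) -> np.ndarray:
    """(participants, 4, distances) array from an ExperimentProfiles."""
    return np.stack(
        [profiles.participant_scores[c] for c in conditions], axis=1
    )


def pop_effect_array(profiles) -> np.ndarray:
    """(participants, distances) full-swap minus full-repeat attraction."""
    return (profiles.participant_scores["TSDS"]
            - profiles.participant_scores["TRDR"])
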