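"""Cluster-based permutation test over reach distances.

Attraction scores are tested pointwise (one-sample t against zero, or a
paired t between conditions) at each of the 100 normalized distances.
Maximal consecutive runs of same-signed supra-threshold t values form
clusters whose mass is the sum of t values within the run; the threshold is
the two-sided t critical value at the experiment's degrees of freedom.

Significance of a cluster's mass is assessed against the null distribution
of the maximum absolute cluster mass across permutations.  Two permutation
schemes are provided:

* ``"sign_flip"`` (default): flip the sign of whole participants' score
  profiles and recompute the t series — the conventional scheme for
  one-sample cluster tests.  It is exact under per-participant symmetry of
  the null, whether or not scores are correlated across distances.
* ``"order"``: shuffle the order of the observed t values and re-run the
  cluster search.  This tests whether the observed contiguity of
  supra-threshold points is larger than expected given the same multiset
  of t values.  It is valid only when the t series is exchangeable across
  distances; real attraction profiles are smooth across distances, which
  makes this scheme anti-conservative, so it is not the default.

Reported p values use add-one smoothing, p = (1 + #{null >= obs}) / (1 + n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class ClusterConfig:
    alpha: float = 0.05
    n_perm: int = 100_000
    scheme: str = "sign_flip"        # "sign_flip" | "order"
    #: explicit cluster-forming threshold; None -> two-sided t critical
    #: value at df = n_participants - 1 and the configured alpha
    threshold: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.scheme not in ("order", "sign_flip"):
            raise ValueError(f"unknown permutation scheme {self.scheme!r}")


@dataclass
class Cluster:
    start: int          # distance index of first point (0-based)
    end: int            # distance index of last point (inclusive)
    mass: float         # sum of t values in the run
    p: float | None = None

    @property
    def start_pct(self) -> int:
        return self.start + 1

    @property
    def end_pct(self) -> int:
        return self.end + 1


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    threshold: float
    alpha: float

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p is not None and c.p < self.alpha]


def pointwise_t(scores: np.ndarray, paired_with: np.ndarray | None = None
                ) -> np.ndarray:
    """t series across distances for a (participants x distances) matrix.

    One-sample t against zero, or a paired t on the difference when a
    second matrix is given.  Points with zero variance across participants
    get t = 0 with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    if paired_with is not None:
        scores = scores - np.asarray(paired_with, dtype=float)
    n = scores.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    mean = scores.mean(axis=0)
    sd = scores.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    zero = sd == 0.0
    if zero.any() and np.any(mean[zero] != 0):
        warnings.warn("zero variance at some distances; t set to 0")
    nz = ~zero
    t[nz] = mean[nz] * np.sqrt(n) / sd[nz]
    return t


def find_clusters(t: np.ndarray, threshold: float) -> list[Cluster]:
    """Maximal consecutive runs of |t| >= threshold with constant sign."""
    t = np.asarray(t, dtype=float)
    lab = np.where(t >= threshold, 1, np.where(t <= -threshold, -1, 0))
    clusters: list[Cluster] = []
    start = None
    for i in range(len(lab) + 1):
        cur = lab[i] if i < len(lab) else 0
        prev = lab[i - 1] if i > 0 else 0
        if cur != prev:
            if prev != 0 and start is not None:
                clusters.append(
                    Cluster(start=start, end=i - 1,
                            mass=float(t[start:i].sum()))
                )
            start = i if cur != 0 else None
    return clusters


def _max_masses_rows(mat: np.ndarray, threshold: float) -> np.ndarray:
    """Max absolute same-sign cluster mass per row of a 2D t matrix.

    Vectorized over rows via a running sum with resets, looping only over
    the (short) distance axis.
    """
    n_rows, n_cols = mat.shape
    best = np.zeros(n_rows)
    run_pos = np.zeros(n_rows)
    run_neg = np.zeros(n_rows)
    for j in range(n_cols):
        col = mat[:, j]
        pos = col >= threshold
        neg = col <= -threshold
        run_pos = np.where(pos, run_pos + col, 0.0)
        run_neg = np.where(neg, run_neg + col, 0.0)
        best = np.maximum(best, np.maximum(run_pos, -run_neg))
    return best


def cluster_permutation_test(
    t: np.ndarray,
    config: ClusterConfig,
    seed: int = 0,
    scores: np.ndarray | None = None,
    df: int | None = None,
) -> ClusterResult:
    """Locate clusters in a t series and attach permutation p values.

    ``df`` (defaults to ``scores.shape[0] - 1`` when scores are given) sets
    the cluster-forming threshold unless an explicit one is configured.
    The ``sign_flip`` scheme requires the participant-level ``scores``.
    """
    t = np.asarray(t, dtype=float)
    if config.threshold is not None:
        threshold = config.threshold
    else:
        if df is None:
            if scores is None:
                raise ValueError("need df or scores to set the threshold")
            df = scores.shape[0] - 1
        threshold = float(stats.t.ppf(1.0 - config.alpha / 2.0, df))

    clusters = find_clusters(t, threshold)
    rng = np.random.default_rng(seed)

    if clusters:
        if config.scheme == "order":
            perms = rng.permuted(
                np.broadcast_to(t, (config.n_perm, t.size)).copy(), axis=1
            )
            null_max = _max_masses_rows(perms, threshold)
        else:
            if scores is None:
                raise ValueError("sign_flip scheme needs participant scores")
            scores = np.asarray(scores, dtype=float)
            n = scores.shape[0]
            null_max = np.empty(config.n_perm)
            block = 200
            for lo in range(0, config.n_perm, block):
                hi = min(lo + block, config.n_perm)
                flips = rng.choice([-1.0, 1.0], size=(hi - lo, n))
                # (B, participants, distances) -> t per permutation
                flipped = flips[:, :, None] * scores[None, :, :]
                mean = flipped.mean(axis=1)
                sd = flipped.std(axis=1, ddof=1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    tp = np.where(sd > 0, mean * np.sqrt(n) / sd, 0.0)
                null_max[lo:hi] = _max_masses_rows(tp, threshold)
        for c in clusters:
            exceed = int(np.sum(null_max >= abs(c.mass)))
            c.p = (1 + exceed) / (1 + config.n_perm)
    return ClusterResult(clusters=clusters, threshold=threshold,
                         alpha=config.alpha)


def result_to_dict(result: ClusterResult) -> dict:
    """JSON-ready summary of a cluster test."""
    return {
        "threshold": result.threshold,
        "alpha": result.alpha,
        "clusters": [
            {
                "start_pct": c.start_pct,
                "end_pct": c.end_pct,
                "mass": c.mass,
                "p": c.p,
            }
            for c in result.clusters
        ],
        "significant": [
            {"start_pct": c.start_pct, "end_pct": c.end_pct, "p": c.p}
            for c in result.significant
        ],
    }
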